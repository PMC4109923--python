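"""Concordance of confident predictions with histopathology scores.

Compounds without carcinogenicity annotation are predicted by a
classifier trained on the annotated ones; only confident calls
(probability > 0.66 or < 0.33) are kept and compared against the
data-driven pathology score (positive iff any ordinal pathology
covariate is non-zero), treated as the gold standard.
"""

import numpy as np
import pandas as pd

import carcinogenome as cg
from carcinogenome import classify as cl
from carcinogenome import histopath as hp

spec = cg.CohortSpec(n_genes=500, n_compounds=40, module_size=50, n_moa_modules=1,
                     effect_size=2.0, dose_levels=("high",), dose_response=(1.0,),
                     times=(29.0,), seed=5)
ds, ann, truth = cg.generate_cohort(spec)

# hide the labels of 16 compounds to mimic un-annotated chemicals
rng = np.random.default_rng(6)
hidden = set(rng.choice(ann.compounds, size=16, replace=False))
masked = ann.table.copy()
masked.loc[list(hidden), ["carcinogenic", "genotoxic"]] = "unknown"
ann_masked = cg.CompoundAnnotation(masked)

X = cl.feature_table(ds)
X_train, y_train, _ = cl.sample_labels(X, ds.meta, ann_masked)
feats = cl.variance_filter(X_train, 100)
model = cl.train_rf(X_train[feats], y_train, n_trees=500, seed=0)

unknown_ids = [s for s in X.index if ds.meta.loc[s, "compound"] in hidden]
probs = pd.Series(model.score_samples(X.loc[unknown_ids, feats].to_numpy()), index=unknown_ids)
confident = cl.confidence_filter(probs, hi=0.66, lo=0.33)
print(f"unannotated samples: {len(probs)}; confident calls: {len(confident)}")

table = cg.generate_histopathology(ds, truth, sensitivity=0.95, specificity=0.9, seed=7)
score = hp.h_score_d(table)
report = hp.concordance_report(confident["call"], score.loc[confident.index])
print("\nconcordance with the pathology OR-score (%, Wilson 95% intervals):")
pretty = report.copy()
pretty[["estimate", "ci_low", "ci_high"]] = (pretty[["estimate", "ci_low", "ci_high"]] * 100).round(1)
print(pretty.to_string())
# High sensitivity/accuracy means confident calls agree with pathology.
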