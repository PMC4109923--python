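"""Generate a synthetic toxicogenomic cohort and inspect its design.

The generator emulates a rat short-term exposure compendium: every
compound is profiled at several doses and exposure times in triplicate,
with matched control animals per (tissue, time, batch) stratum, and
carcinogens perturb planted mechanism-of-action gene modules.
"""

import carcinogenome as cg

spec = cg.CohortSpec(n_genes=500, n_compounds=20, module_size=40, n_moa_modules=3,
                     effect_size=2.0, seed=1)
ds, ann, truth = cg.generate_cohort(spec)

print(f"expression matrix: {ds.n_genes} genes x {ds.n_samples} samples")
print(f"treated samples:   {len(ds.treated_ids())}  controls: {len(ds.control_ids())}")
print(f"carcinogens:       {int(truth.labels['carcinogenic'].sum())} of {spec.n_compounds}")
print(f"genotoxic:         {int(truth.labels['genotoxic'].sum())}")
first = ds.treated_ids()[0]
print(f"matched controls of {first}: {cg.match_controls(ds, first)}")

# Each carcinogen activates one mechanism module (genotoxic ones also the
# DNA damage-response module); non-carcinogens activate none.
for cpd, mods in list(truth.compound_modules.items())[:5]:
    label = ann.label(cpd)
    print(f"  {cpd}: carcinogenic={label:8s} active modules={mods}")
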