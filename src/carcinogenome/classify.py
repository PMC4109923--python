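"""Carcinogenicity classification and compound-aware evaluation.

The evaluation backbone is a random resampling (bagging) scheme: the
compounds — never the individual profiles — are split 70/30 into
train/test, stratified by label, and the split is repeated many times to
obtain mean AUC and a normal-approximation 95% confidence interval.
Feature selection (variance or t-score ranking) and classification
threshold choice are carried out strictly within each training split.
The default classifier is a 500-tree random forest whose score is the
probability that the compound is carcinogenic; support-vector-machine
and nearest-shrunken-centroid classifiers are pluggable behind the same
interface for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestCentroid

from carcinogenome.core import (
    CompoundAnnotation,
    ExpressionDataset,
    ProjectionMatrix,
    ValidationError,
)
from carcinogenome.utils import child_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Feature tables and labels
# ---------------------------------------------------------------------------


def feature_table(data) -> pd.DataFrame:
    """Samples x features table from any pipeline carrier.

    Accepts an :class:`ExpressionDataset` (features = genes), a
    :class:`ProjectionMatrix` (features = gene sets; controls already
    excluded), or a samples x features DataFrame as-is.
    """
    if isinstance(data, ExpressionDataset):
        return data.values.T.loc[data.treated_ids()]
    if isinstance(data, ProjectionMatrix):
        return data.es.T
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError(f"unsupported feature carrier {type(data)!r}")


def sample_labels(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    ann: CompoundAnnotation,
    phenotype: str = "carcinogenic",
    dose_specific: bool = False,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Restrict a feature table to samples with known labels.

    Returns (features, boolean labels, compound of each sample). With
    ``dose_specific`` the label may depend on the administered dose.
    """
    rows, labels, compounds = [], [], []
    for sid in features.index:
        cpd = meta.loc[sid, "compound"]
        dose = meta.loc[sid, "dose_level"] if dose_specific else None
        lab = ann.label(cpd, phenotype, dose_level=dose)
        if lab == "unknown":
            continue
        rows.append(sid)
        labels.append(lab == "positive")
        compounds.append(cpd)
    X = features.loc[rows]
    return X, pd.Series(labels, index=rows), pd.Series(compounds, index=rows)


# ---------------------------------------------------------------------------
# Feature selection (train-split only)
# ---------------------------------------------------------------------------


def variance_filter(train: pd.DataFrame, n: int = 500) -> list[str]:
    """The n features of highest variance across training samples.

    Ties break by feature id; asking for more features than exist falls
    back to all of them with a warning.
    """
    if n > train.shape[1]:
        logger.warning("requested %d features but only %d available", n, train.shape[1])
        n = train.shape[1]
    var = train.var(axis=0, ddof=1)
    ranked = var.to_frame("v").reset_index(names="feature")
    ranked = ranked.sort_values(["v", "feature"], ascending=[False, True], kind="stable")
    return list(ranked["feature"].head(n))


def rank_filter_by_t(
    train: pd.DataFrame, labels: pd.Series, n: int = 500, block: int = 0
) -> list[str]:
    """Features ranked by |two-sample t| against the phenotype.

    ``block`` selects the k-th block of n features down the ranking
    (block 0 = top n, block 1 = features n+1..2n, ...).
    """
    y = labels.loc[train.index].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("t-score ranking needs both classes in the training data")
    A, B = train.to_numpy()[y], train.to_numpy()[~y]
    na, nb = len(A), len(B)
    va = A.var(axis=0, ddof=1) if na > 1 else np.zeros(train.shape[1])
    vb = B.var(axis=0, ddof=1) if nb > 1 else np.zeros(train.shape[1])
    dof = max(na + nb - 2, 1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / (sp * np.sqrt(1.0 / na + 1.0 / nb))
    t = np.where(np.isfinite(t), t, 0.0)
    ranked = pd.DataFrame({"feature": train.columns, "score": np.abs(t)})
    ranked = ranked.sort_values(["score", "feature"], ascending=[False, True], kind="stable")
    start = block * n
    chosen = list(ranked["feature"].iloc[start : start + n])
    if not chosen:
        raise ValidationError(f"block {block} of {n} features is beyond the ranking")
    return chosen


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    iteration: int
    train_compounds: list[str]
    test_compounds: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_compounds) & set(self.test_compounds):
            raise ValidationError("train and test compound sets overlap")


def make_split_plans(
    compounds: list[str],
    labels: pd.Series,
    n_iter: int = 200,
    train_frac: float = 0.7,
    seed: int = 0,
) -> list[SplitPlan]:
    """Label-stratified compound-level 70/30 split plans.

    Every compound lands wholly in train or test; per-class test quotas
    follow the global test fraction (largest-remainder rounding, at least
    one test compound per class), the remainder staying in train.
    """
    labels = labels.loc[compounds]
    pos = [c for c in compounds if labels[c]]
    neg = [c for c in compounds if not labels[c]]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need >=2 compounds per class to split")
    n = len(compounds)
    n_test = n - int(round(train_frac * n))
    n_test = max(n_test, 2)
    quota_f = {True: n_test * len(pos) / n, False: n_test * len(neg) / n}
    quota = {k: int(np.floor(v)) for k, v in quota_f.items()}
    remainder = n_test - sum(quota.values())
    for k in sorted(quota_f, key=lambda k: quota_f[k] - quota[k], reverse=True)[:remainder]:
        quota[k] += 1
    for k in quota:
        quota[k] = max(1, quota[k])
    plans = []
    for it in range(n_iter):
        it_seed = child_seed(seed, it)
        rng = np.random.default_rng(it_seed)
        test: list[str] = []
        for side, k in ((pos, quota[True]), (neg, quota[False])):
            picked = rng.choice(len(side), size=k, replace=False)
            test.extend(side[i] for i in picked)
        train = [c for c in compounds if c not in set(test)]
        plans.append(SplitPlan(it, train, sorted(test), it_seed))
    return plans


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


class RandomForestModel:
    """500-tree random forest scoring carcinogenicity probability."""

    def __init__(self, n_trees: int = 500, seed: int = 0):
        self.clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                          oob_score=True)
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestModel":
        if len(set(y)) < 2:
            raise ValidationError("training labels are single-class")
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
            warnings.filterwarnings("ignore", message="invalid value encountered")
            self.clf.fit(X, y.astype(int))
        return self

    def oob_scores(self) -> np.ndarray:
        """Out-of-bag positive-class probabilities for the training samples.

        In-sample probabilities of a forest are overfit and nearly
        separable, which would make any cost-ratio threshold degenerate;
        OOB scores are honest training-data scores. Samples that never
        fell out of bag come back NaN.
        """
        df = self.clf.oob_decision_function_
        return df[:, list(self.clf.classes_).index(1)]

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(X)[:, list(self.clf.classes_).index(1)]

    def permutation_importance(self, X: np.ndarray, y: np.ndarray, n_repeats: int = 1) -> np.ndarray:
        """Increase in error rate when each feature is permuted."""
        rng = np.random.default_rng(self.seed)
        base_err = np.mean((self.score_samples(X) >= 0.5) != y.astype(bool))
        imp = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                err = np.mean((self.score_samples(Xp) >= 0.5) != y.astype(bool))
                imp[j] += (err - base_err) / n_repeats
        return imp


class SVMModel:
    """Linear-kernel SVM; scores are decision-function margins."""

    def __init__(self, seed: int = 0, C: float = 1.0):
        from sklearn.svm import SVC

        self.clf = SVC(kernel="linear", C=C, random_state=seed)

    def fit(self, X, y):
        if len(set(y)) < 2:
            raise ValidationError("training labels are single-class")
        self.clf.fit(X, y.astype(int))
        return self

    def score_samples(self, X):
        return self.clf.decision_function(X)


class ShrunkenCentroidModel:
    """Nearest shrunken centroid; scores are signed centroid-distance margins."""

    def __init__(self, shrink_threshold: float | None = 0.2, seed: int = 0):
        self.clf = NearestCentroid(shrink_threshold=shrink_threshold)

    def fit(self, X, y):
        if len(set(y)) < 2:
            raise ValidationError("training labels are single-class")
        self.clf.fit(X, y.astype(int))
        return self

    def score_samples(self, X):
        c0, c1 = self.clf.centroids_[list(self.clf.classes_).index(0)], self.clf.centroids_[
            list(self.clf.classes_).index(1)
        ]
        d0 = np.linalg.norm(X - c0, axis=1)
        d1 = np.linalg.norm(X - c1, axis=1)
        return d0 - d1


CLASSIFIERS = {
    "rf": RandomForestModel,
    "svm": SVMModel,
    "nsc": ShrunkenCentroidModel,
}


def train_rf(features: pd.DataFrame, labels: pd.Series, n_trees: int = 500, seed: int = 0) -> RandomForestModel:
    """Fit the default random-forest model on a samples x features table."""
    model = RandomForestModel(n_trees=n_trees, seed=seed)
    model.fit(features.to_numpy(dtype=float), labels.loc[features.index].to_numpy())
    return model


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC; tied scores count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: only one class present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


@dataclass
class CostSpec:
    """Misclassification costs used to pick the operating threshold."""

    fp_cost: float = 1.0
    fn_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.fp_cost < 0 or self.fn_cost < 0 or (self.fp_cost == 0 and self.fn_cost == 0):
            raise ValidationError("costs must be non-negative and not both zero")


def choose_threshold(train_scores, train_labels, cost: CostSpec) -> float:
    """Threshold minimizing total misclassification cost on training data.

    A sample is called positive when its score exceeds the threshold;
    candidates are placed below, between and above the observed training
    scores, and ties in cost resolve to the lowest threshold.
    """
    s = np.asarray(train_scores, dtype=float)
    y = np.asarray(train_labels, dtype=bool)
    uniq = np.unique(s)
    candidates = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    best_thr, best_cost = None, np.inf
    for thr in candidates:
        called = s > thr
        fp = np.sum(called & ~y)
        fn = np.sum(~called & y)
        total = cost.fp_cost * fp + cost.fn_cost * fn
        if total < best_cost - 1e-12:
            best_cost, best_thr = total, thr
    return float(best_thr)


def confusion_metrics(called, truth) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / PPV / NPV / FDR from binary
    calls against binary truth; undefined ratios come back NaN."""
    called = np.asarray(called, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    tn = int(np.sum(~called & ~truth))

    def ratio(a, b):
        return a / b if b else np.nan

    ppv = ratio(tp, tp + fp)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ppv,
        "npv": ratio(tn, tn + fn),
        "fdr": 1.0 - ppv if not np.isnan(ppv) else np.nan,
    }


def threshold_metrics(
    train_scores, train_labels, test_scores, test_labels, cost: CostSpec | None = None
) -> dict[str, float]:
    """Pick the cost-optimal threshold on training scores, report the
    confusion-matrix metric suite on the test scores."""
    cost = cost or CostSpec()
    thr = choose_threshold(train_scores, train_labels, cost)
    metrics = confusion_metrics(np.asarray(test_scores) > thr, test_labels)
    metrics["threshold"] = thr
    return metrics


# ---------------------------------------------------------------------------
# Resampling evaluation
# ---------------------------------------------------------------------------


@dataclass
class ResamplingResult:
    """Aggregate of a compound-aware resampling run."""

    auc_per_iteration: np.ndarray
    mean_auc: float
    ci95: tuple[float, float]
    metrics: pd.DataFrame  # per-iteration metric suite
    roc_fpr: np.ndarray
    roc_tpr_mean: np.ndarray
    roc_tpr_q1: np.ndarray
    roc_tpr_q3: np.ndarray
    importance: pd.Series | None = None
    predictions: pd.DataFrame | None = None  # long format: iteration, sample, score, label

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_per_iteration, ddof=1))


def _aggregate_roc(rocs: list[tuple[np.ndarray, np.ndarray]], grid_points: int = 101):
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = np.array([np.interp(grid, fpr, tpr) for fpr, tpr in rocs])
    return grid, tprs.mean(axis=0), np.quantile(tprs, 0.25, axis=0), np.quantile(tprs, 0.75, axis=0)


def run_resampling(
    data,
    meta: pd.DataFrame,
    ann: CompoundAnnotation,
    plans: list[SplitPlan] | None = None,
    n_iter: int = 200,
    phenotype: str = "carcinogenic",
    selector: str = "variance",
    n_features: int = 500,
    cost: CostSpec | None = None,
    classifier: str = "rf",
    n_trees: int = 500,
    per_compound: bool = False,
    compute_importance: bool = False,
    dose_specific: bool = False,
    seed: int = 0,
) -> ResamplingResult:
    """Compound-aware resampling evaluation of a classifier.

    ``data`` is any feature carrier accepted by :func:`feature_table`.
    Per iteration: select features on the training split, fit, score the
    held-out compounds' samples, record AUC (per sample, or per compound
    after averaging replicate scores) and the cost-thresholded metric
    suite. Aggregates mean AUC with a normal 95% CI over iterations, ROC
    quartile bands and (optionally) averaged permutation importances.
    """
    from sklearn.metrics import roc_curve

    cost = cost or CostSpec()
    X_all, y_all, cpd_all = sample_labels(feature_table(data), meta, ann, phenotype, dose_specific)
    if plans is None:
        cpd_labels = y_all.groupby(cpd_all).any()
        plans = make_split_plans(sorted(cpd_labels.index), cpd_labels, n_iter=n_iter, seed=seed)
    aucs, metric_rows, rocs, imps, preds = [], [], [], [], []
    for plan in plans:
        train_ids = [s for s in X_all.index if cpd_all[s] in set(plan.train_compounds)]
        test_ids = [s for s in X_all.index if cpd_all[s] in set(plan.test_compounds)]
        X_train, y_train = X_all.loc[train_ids], y_all.loc[train_ids]
        X_test, y_test = X_all.loc[test_ids], y_all.loc[test_ids]
        if selector == "variance":
            feats = variance_filter(X_train, n_features)
        elif selector == "tscore":
            feats = rank_filter_by_t(X_train, y_train, n_features)
        elif selector == "none":
            feats = list(X_train.columns)
        else:
            raise ValueError(f"unknown selector {selector!r}")
        model = CLASSIFIERS[classifier](seed=plan.seed) if classifier != "rf" else RandomForestModel(
            n_trees=n_trees, seed=plan.seed
        )
        model.fit(X_train[feats].to_numpy(dtype=float), y_train.to_numpy())
        s_train = model.score_samples(X_train[feats].to_numpy(dtype=float))
        s_test = model.score_samples(X_test[feats].to_numpy(dtype=float))
        if per_compound:
            df = pd.DataFrame({"score": s_test, "cpd": cpd_all.loc[test_ids], "y": y_test})
            agg = df.groupby("cpd").agg(score=("score", "mean"), y=("y", "any"))
            auc_scores, auc_labels = agg["score"].to_numpy(), agg["y"].to_numpy()
        else:
            auc_scores, auc_labels = s_test, y_test.to_numpy()
        if len(set(auc_labels)) < 2:
            logger.warning("iteration %d: one-class test split, skipped", plan.iteration)
            continue
        aucs.append(compute_auc(auc_scores, auc_labels))
        fpr, tpr, _ = roc_curve(auc_labels.astype(int), auc_scores)
        rocs.append((fpr, tpr))
        thr_scores = s_train
        if isinstance(model, RandomForestModel):
            oob = model.oob_scores()
            thr_scores = np.where(np.isnan(oob), s_train, oob)
        m = threshold_metrics(thr_scores, y_train.to_numpy(), s_test, y_test.to_numpy(), cost)
        m["iteration"] = plan.iteration
        metric_rows.append(m)
        preds.append(
            pd.DataFrame(
                {"iteration": plan.iteration, "sample_id": test_ids, "score": s_test,
                 "label": y_test.to_numpy()}
            )
        )
        if compute_importance and hasattr(model, "permutation_importance"):
            imp = model.permutation_importance(
                X_train[feats].to_numpy(dtype=float), y_train.to_numpy()
            )
            imps.append(pd.Series(imp, index=feats))
    if len(aucs) < 2:
        raise ValidationError("fewer than 2 usable iterations")
    aucs = np.array(aucs)
    mean_auc = float(aucs.mean())
    half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs))
    grid, tpr_mean, tpr_q1, tpr_q3 = _aggregate_roc(rocs)
    importance = None
    if imps:
        importance = pd.concat(imps, axis=1).mean(axis=1).sort_values(ascending=False)
    return ResamplingResult(
        auc_per_iteration=aucs,
        mean_auc=mean_auc,
        ci95=(mean_auc - half, mean_auc + half),
        metrics=pd.DataFrame(metric_rows).set_index("iteration"),
        roc_fpr=grid,
        roc_tpr_mean=tpr_mean,
        roc_tpr_q1=tpr_q1,
        roc_tpr_q3=tpr_q3,
        importance=importance,
        predictions=pd.concat(preds, ignore_index=True) if preds else None,
    )


# ---------------------------------------------------------------------------
# External validation, strata, learning curves, sweeps
# ---------------------------------------------------------------------------


def external_validation(
    train_data,
    test_data,
    train_meta: pd.DataFrame,
    test_meta: pd.DataFrame,
    ann_train: CompoundAnnotation,
    ann_test: CompoundAnnotation,
    exclude_shared_compounds: bool = True,
    phenotype: str = "carcinogenic",
    selector: str = "variance",
    n_features: int = 500,
    n_trees: int = 500,
    seed: int = 0,
) -> dict:
    """Train one model on a full discovery cohort, test on a validation cohort.

    Feature universes are intersected; compounds present in both cohorts
    are excluded from the test side when requested. Returns per-sample
    and replicate-averaged per-compound probabilities with their AUCs.
    """
    X_train_all = feature_table(train_data)
    X_test_all = feature_table(test_data)
    shared_features = [f for f in X_train_all.columns if f in set(X_test_all.columns)]
    if not shared_features:
        raise ValidationError("no shared features between cohorts")
    X_train_all = X_train_all[shared_features]
    X_test_all = X_test_all[shared_features]
    X_train, y_train, cpd_train = sample_labels(X_train_all, train_meta, ann_train, phenotype)
    X_test, y_test, cpd_test = sample_labels(X_test_all, test_meta, ann_test, phenotype)
    if exclude_shared_compounds:
        shared = set(cpd_train) & set(cpd_test)
        keep = [s for s in X_test.index if cpd_test[s] not in shared]
        X_test, y_test, cpd_test = X_test.loc[keep], y_test.loc[keep], cpd_test.loc[keep]
    if selector == "variance":
        feats = variance_filter(X_train, n_features)
    elif selector == "tscore":
        feats = rank_filter_by_t(X_train, y_train, n_features)
    else:
        feats = list(X_train.columns)
    model = RandomForestModel(n_trees=n_trees, seed=seed)
    model.fit(X_train[feats].to_numpy(dtype=float), y_train.to_numpy())
    s_test = pd.Series(model.score_samples(X_test[feats].to_numpy(dtype=float)), index=X_test.index)
    per_cpd = pd.DataFrame({"score": s_test, "cpd": cpd_test, "y": y_test}).groupby("cpd").agg(
        score=("score", "mean"), y=("y", "any")
    )
    return {
        "model": model,
        "features": feats,
        "sample_scores": s_test,
        "sample_labels": y_test,
        "auc_per_sample": compute_auc(s_test.to_numpy(), y_test.to_numpy()),
        "compound_scores": per_cpd,
        "auc_per_compound": compute_auc(per_cpd["score"].to_numpy(), per_cpd["y"].to_numpy()),
    }


def stratified_auc_grid(
    data,
    meta: pd.DataFrame,
    ann: CompoundAnnotation,
    n_iter: int = 200,
    seed: int = 0,
    **resampling_kwargs,
) -> pd.DataFrame:
    """Resampling AUC per (time, dose) stratum.

    Strata whose compounds are single-class are skipped with a flag in
    the returned table (NaN AUC).
    """
    X_all = feature_table(data)
    rows = []
    strata = meta.loc[X_all.index].groupby(["time", "dose_level"], dropna=True).groups
    for (t, dose), idx in sorted(strata.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ids = list(idx)
        X = X_all.loc[ids]
        _, y, cpds = sample_labels(X, meta, ann)
        cpd_labels = y.groupby(cpds).any()
        row = {"time": t, "dose_level": dose, "n_samples": len(ids)}
        if cpd_labels.nunique() < 2 or cpd_labels.sum() < 2 or (~cpd_labels).sum() < 2:
            row.update({"mean_auc": np.nan, "ci_half": np.nan, "flag": "single-class"})
        else:
            res = run_resampling(X, meta, ann, n_iter=n_iter, seed=seed, **resampling_kwargs)
            row.update(
                {
                    "mean_auc": res.mean_auc,
                    "ci_half": (res.ci95[1] - res.ci95[0]) / 2.0,
                    "flag": "",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def learning_curve(
    data,
    meta: pd.DataFrame,
    ann: CompoundAnnotation,
    start: int = 70,
    step: int = 10,
    n_iter: int = 200,
    seed: int = 0,
    **resampling_kwargs,
) -> dict:
    """Resampling AUC as a function of the number of compounds.

    Compounds are down-sampled (label-stratified) to each size before the
    70/30 resampling; an ordinary least-squares line is fitted on the
    (size, mean AUC) pairs. Returns the series and the fitted slope.
    """
    X_all = feature_table(data)
    _, y_all, cpd_all = sample_labels(X_all, meta, ann)
    cpd_labels = y_all.groupby(cpd_all).any()
    total = len(cpd_labels)
    if start > total:
        raise ValidationError(f"start={start} exceeds the {total} available compounds")
    sizes = list(range(start, total + 1, step))
    rows = []
    for si, size in enumerate(sizes):
        rng = np.random.default_rng(child_seed(seed, 10_000 + si))
        pos = sorted(cpd_labels.index[cpd_labels])
        neg = sorted(cpd_labels.index[~cpd_labels])
        n_pos = max(2, int(round(size * len(pos) / total)))
        n_pos = min(n_pos, len(pos), size - 2)
        n_neg = size - n_pos
        chosen = list(rng.choice(pos, size=n_pos, replace=False)) + list(
            rng.choice(neg, size=min(n_neg, len(neg)), replace=False)
        )
        keep = [s for s in X_all.index if cpd_all[s] in set(chosen)]
        res = run_resampling(
            X_all.loc[keep], meta, ann, n_iter=n_iter, seed=child_seed(seed, 20_000 + si),
            **resampling_kwargs,
        )
        rows.append({"n_compounds": len(chosen), "mean_auc": res.mean_auc,
                     "ci_half": (res.ci95[1] - res.ci95[0]) / 2.0})
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(table["n_compounds"], table["mean_auc"], 1)
    return {"table": table, "slope": float(slope), "intercept": float(intercept)}


def confidence_filter(probabilities: pd.Series, hi: float = 0.66, lo: float = 0.33) -> pd.DataFrame:
    """Keep only confident calls: p > hi positive, p < lo negative.

    The middle band is dropped; returns a table of retained samples with
    their boolean call.
    """
    if hi <= lo:
        raise ValidationError("hi threshold must exceed lo threshold")
    p = probabilities.astype(float)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    keep = p[(p > hi) | (p < lo)]
    return pd.DataFrame({"probability": keep, "call": keep > hi})


def feature_sweep(
    data,
    meta: pd.DataFrame,
    ann: CompoundAnnotation,
    sizes: list[int],
    selector: str = "variance",
    n_iter: int = 50,
    seed: int = 0,
    importance_ranking: pd.Series | None = None,
    **resampling_kwargs,
) -> pd.DataFrame:
    """Resampling AUC as a function of the number of features.

    With ``importance_ranking`` the top features come from a supplied
    (e.g. variable-importance) ordering and selection is 'none' within
    splits; otherwise the per-split selector ranks features. Sizes beyond
    the available features are truncated with a warning.
    """
    if sizes != sorted(sizes):
        raise ValidationError("sizes must be ascending")
    X_all = feature_table(data)
    rows = []
    for si, size in enumerate(sizes):
        if size > X_all.shape[1]:
            logger.warning("size %d truncated to %d features", size, X_all.shape[1])
            size = X_all.shape[1]
        if importance_ranking is not None:
            feats = list(importance_ranking.sort_values(ascending=False).index[:size])
            res = run_resampling(
                X_all[feats], meta, ann, selector="none", n_features=size,
                n_iter=n_iter, seed=child_seed(seed, 30_000 + si), **resampling_kwargs,
            )
        else:
            res = run_resampling(
                X_all, meta, ann, selector=selector, n_features=size,
                n_iter=n_iter, seed=child_seed(seed, 30_000 + si), **resampling_kwargs,
            )
        rows.append({"n_features": size, "mean_auc": res.mean_auc,
                     "ci_half": (res.ci95[1] - res.ci95[0]) / 2.0})
    return pd.DataFrame(rows)
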