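"""Perturbational transcriptome: per-compound differential response.

For every compound instance (compound, or compound@dose when a compound
was profiled at several dose levels) a treatment-vs-control t-score is
computed per gene from a linear model with exposure time as a categorical
covariate, pooling treated samples across times against their matched
controls. The resulting genes x instances t-score matrix is the
substrate for responsiveness filtering, per-gene phenotype enrichment,
and compound clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from carcinogenome.core import (
    CompoundAnnotation,
    ExpressionDataset,
    TScoreMatrix,
    ValidationError,
    match_controls,
)
from carcinogenome.utils import bh_q

logger = logging.getLogger(__name__)


def _instance_keys(ds: ExpressionDataset) -> list[tuple[str, str | None]]:
    """(compound, dose) instance keys; dose collapses to None for
    compounds profiled at a single dose level."""
    treated = ds.meta[~ds.meta["is_control"]]
    keys = []
    for cpd, sub in treated.groupby("compound", sort=True):
        doses = sorted({str(d) for d in sub["dose_level"] if d is not None})
        if len(doses) > 1:
            keys.extend((cpd, d) for d in doses)
        else:
            keys.append((cpd, doses[0] if doses else None))
    return keys


def _fit_instance(Y: np.ndarray, treat: np.ndarray, times: np.ndarray):
    """Per-gene Wald t of the treatment indicator in expression ~ treatment
    + C(time), with two-sided p. Returns (t, p) or None on singular design."""
    n = Y.shape[1]
    levels = sorted(set(times))
    X = [np.ones(n), treat.astype(float)]
    for lev in levels[1:]:
        X.append((times == lev).astype(float))
    X = np.column_stack(X)
    p_params = X.shape[1]
    if np.linalg.matrix_rank(X) < p_params or n - p_params < 1:
        return None
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T  # p_params x genes
    resid = Y.T - X @ beta
    dof = n - p_params
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p


def compound_tscores(ds: ExpressionDataset, ann: CompoundAnnotation | None = None) -> TScoreMatrix:
    """Treatment-vs-control t-score matrix across compound instances.

    Treated samples of an instance are pooled across exposure times
    against the union of their matched controls; the reported statistic is
    the treatment coefficient's Wald t adjusted for time. q-values are BH
    across genes within each instance; fold change is 2^(treated mean -
    control mean). Instances with a singular design (e.g. time perfectly
    confounded with treatment) yield an all-NaN column and a logged
    warning.
    """
    genes = ds.gene_ids
    t_cols, q_cols, fc_cols, meta_rows = {}, {}, {}, []
    V = ds.values
    for cpd, dose in _instance_keys(ds):
        mask = (ds.meta["compound"] == cpd) & ~ds.meta["is_control"]
        if dose is not None:
            mask &= ds.meta["dose_level"].astype(str) == str(dose)
        treated_ids = list(ds.meta.index[mask])
        ctrl_ids: list[str] = []
        for sid in treated_ids:
            for c in match_controls(ds, sid):
                if c not in ctrl_ids:
                    ctrl_ids.append(c)
        multi_dose = (
            len({str(d) for d in ds.meta.loc[(ds.meta["compound"] == cpd) & ~ds.meta["is_control"], "dose_level"]}) > 1
        )
        name = f"{cpd}@{dose}" if multi_dose else cpd
        if len(treated_ids) < 2 or len(ctrl_ids) < 2:
            raise ValidationError(
                f"instance {name!r} needs >=2 treated and >=2 control samples"
            )
        ids = ctrl_ids + treated_ids
        Y = V[ids].to_numpy().astype(float)
        treat = np.array([0] * len(ctrl_ids) + [1] * len(treated_ids))
        times = ds.meta.loc[ids, "time"].to_numpy()
        fit = _fit_instance(Y, treat, times)
        if fit is None:
            logger.warning("instance %s: singular design, column flagged undefined", name)
            t_cols[name] = np.full(len(genes), np.nan)
            q_cols[name] = np.full(len(genes), np.nan)
            fc_cols[name] = np.full(len(genes), np.nan)
        else:
            t, p = fit
            diff = V[treated_ids].mean(axis=1).to_numpy() - V[ctrl_ids].mean(axis=1).to_numpy()
            t_cols[name] = t
            q_cols[name] = bh_q(p)
            fc_cols[name] = np.power(2.0, diff)
        meta_rows.append({"instance": name, "compound": cpd, "dose_level": dose})
    idx = pd.Index(genes, name="gene_id")
    return TScoreMatrix(
        t=pd.DataFrame(t_cols, index=idx),
        q=pd.DataFrame(q_cols, index=idx),
        fc=pd.DataFrame(fc_cols, index=idx),
        instance_meta=pd.DataFrame(meta_rows).set_index("instance"),
    )


def significant_mask(tm: TScoreMatrix, q_max: float = 0.01, fc_min: float = 1.5) -> pd.DataFrame:
    """Boolean genes x instances matrix of significant responses.

    Significance requires q <= q_max and a two-sided fold change
    (fc >= fc_min or fc <= 1/fc_min).
    """
    if q_max <= 0 or fc_min <= 0:
        raise ValidationError("thresholds must be positive")
    fc_hit = (tm.fc >= fc_min) | (tm.fc <= 1.0 / fc_min)
    return (tm.q <= q_max) & fc_hit


def select_responsive_genes(
    tm: TScoreMatrix,
    q_max: float = 0.01,
    fc_min: float = 1.5,
    min_compounds: int = 5,
    count_distinct_compounds: bool = False,
) -> pd.DataFrame:
    """Genes significantly up-/down-regulated in >= min_compounds instances.

    Returns a table with up/down/significant instance counts per retained
    gene, sorted by total count descending. By default compound@dose
    instances are counted; ``count_distinct_compounds`` counts each
    compound once.
    """
    sig = significant_mask(tm, q_max, fc_min)
    up = sig & (tm.t > 0)
    down = sig & (tm.t < 0)
    if count_distinct_compounds:
        cpd_of = tm.instance_meta["compound"]
        up = up.T.groupby(cpd_of).any().T
        down = down.T.groupby(cpd_of).any().T
        sig = sig.T.groupby(cpd_of).any().T
    tab = pd.DataFrame(
        {
            "n_compounds_up": up.sum(axis=1),
            "n_compounds_down": down.sum(axis=1),
            "n_compounds_significant": sig.sum(axis=1),
        }
    )
    tab = tab[tab["n_compounds_significant"] >= min_compounds]
    return tab.sort_values("n_compounds_significant", ascending=False)


def gene_phenotype_enrichment(
    tm: TScoreMatrix,
    responsive: pd.DataFrame,
    ann: CompoundAnnotation,
    phenotype: str = "carcinogenic",
    q_max: float = 0.01,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Fisher association of per-gene differential status with a compound
    phenotype.

    For each responsive gene a 2x2 table (differentially expressed x
    phenotype positive) is built over compounds with known labels; the
    two-sided Fisher exact p is BH-corrected across genes. Direction is
    the sign of the (Haldane-smoothed) log odds ratio.
    """
    known = ann.known(phenotype)
    cpd_of = tm.instance_meta["compound"]
    keep = [i for i in tm.instances if cpd_of[i] in known.index]
    if len(set(known.loc[[cpd_of[i] for i in keep]])) < 2 or known.sum() < 2 or (~known).sum() < 2:
        raise ValidationError(f"need >=2 compounds in each {phenotype} class")
    sig = significant_mask(tm, q_max, fc_min)[keep]
    pos = np.array([bool(known[cpd_of[i]]) for i in keep])
    rows = []
    for g in responsive.index:
        de = sig.loc[g].to_numpy()
        a = int((de & pos).sum())
        b = int((de & ~pos).sum())
        c = int((~de & pos).sum())
        d = int((~de & ~pos).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = np.sign(np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))))
        rows.append({"gene_id": g, "fisher_p": p, "direction": direction})
    out = pd.DataFrame(rows, columns=["gene_id", "fisher_p", "direction"]).set_index("gene_id")
    out["fisher_q"] = bh_q(out["fisher_p"].to_numpy())
    return out


def cluster_compounds(tm: TScoreMatrix, k: int = 2) -> pd.Series:
    """Agglomerative clustering of compound instances on their t-score
    profiles (average linkage, 1 - Pearson correlation), cut at k."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    cols = [c for c in tm.instances if np.isfinite(tm.t[c]).all()]
    if len(cols) < k:
        raise ValidationError("fewer defined instances than clusters")
    X = tm.t[cols].to_numpy().T  # instances x genes
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(cols, name="instance"), name="cluster")


def cluster_phenotype_association(
    clusters: pd.Series,
    tm: TScoreMatrix,
    ann: CompoundAnnotation,
    phenotype: str = "carcinogenic",
) -> float:
    """Two-sided Fisher exact p for cluster membership vs phenotype."""
    if clusters.nunique() != 2:
        raise ValidationError("exactly two clusters required")
    known = ann.known(phenotype)
    cpd_of = tm.instance_meta["compound"]
    table = np.zeros((2, 2), dtype=int)
    counted = 0
    for inst, cl in clusters.items():
        cpd = cpd_of[inst]
        if cpd not in known.index:
            continue
        table[int(cl == clusters.max()), int(bool(known[cpd]))] += 1
        counted += 1
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValidationError("a cluster or phenotype class is empty after label filtering")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def cluster_deg_count_test(
    tm: TScoreMatrix,
    clusters: pd.Series,
    q_max: float = 0.01,
    fc_min: float = 1.5,
) -> tuple[float, float, pd.Series]:
    """Two-sample KS test comparing per-instance counts of significantly
    regulated genes between the two clusters. Returns (statistic, p, counts)."""
    counts = significant_mask(tm, q_max, fc_min)[list(clusters.index)].sum(axis=0)
    groups = [counts[clusters == c].to_numpy() for c in sorted(clusters.unique())]
    if len(groups) != 2 or min(len(g) for g in groups) < 2:
        raise ValidationError("both clusters must have >=2 instances")
    res = stats.ks_2samp(groups[0], groups[1])
    return float(res.statistic), float(res.pvalue), counts
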