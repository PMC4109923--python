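"""Phenotype-contrast differential signatures and gene-set enrichment.

The differential statistic is an empirical-Bayes moderated t: per-gene
residual variances are shrunk toward a pooled prior variance s0^2 with
prior degrees of freedom d0, both estimated by method-of-moments on the
log sample variances (matching the classical moderated-t construction).
Pre-ranked gene-set enrichment uses the weighted Kolmogorov-Smirnov
statistic of :mod:`carcinogenome.projection` with a gene-permutation
null; hyper-enrichment is a one-sided hypergeometric over-representation
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from carcinogenome.core import (
    CompoundAnnotation,
    ExpressionDataset,
    GeneSetCollection,
    ValidationError,
    collapse_replicates,
)
from carcinogenome.projection import RankedProfile, _es_walk, ks_enrichment_score
from carcinogenome.utils import bh_q

#: The four standard binary contrasts (carcinogenicity CG, genotoxicity GT).
DEFAULT_CONTRASTS = (
    "CG_vs_nonCG",
    "GT_vs_nonGT",
    "GTCG_vs_nonGTCG",
    "nonGTCG_vs_nonGTnonCG",
)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (trigamma is strictly decreasing)."""
    if x <= 0:
        return np.inf
    f = lambda y: special.polygamma(1, y) - x
    lo, hi = 1e-8, 1e8
    if f(lo) < 0:  # even tiny y gives trigamma < x: no finite solution needed
        return lo
    if f(hi) > 0:
        return hi
    return optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def estimate_prior(s2: np.ndarray, dof: int) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from gene-wise variances.

    Works on z = log(s2): E[z] = log(sigma^2) + psi(d/2) - log(d/2) and
    Var[z] adds psi'(d/2); the excess spread of z over its chi-square
    expectation identifies the prior df d0 via the trigamma function.
    Returns d0 = inf when the variances are no more dispersed than
    chi-square sampling alone (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValidationError("need >=2 positive gene variances to estimate the prior")
    z = np.log(positive)
    e = z - special.digamma(dof / 2.0) + np.log(dof / 2.0)
    excess = np.var(z, ddof=1) - special.polygamma(1, dof / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    half_d0 = _trigamma_inverse(float(excess))
    d0 = 2.0 * half_d0
    s0_sq = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0_sq)


def moderated_ttest(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene (A minus B).

    ``group_a`` and ``group_b`` are genes x samples matrices sharing a
    gene index. The prior (d0, s0^2) is estimated from the data unless
    supplied (d0=0 degenerates to the ordinary pooled t; d0=inf applies
    the pooled prior variance to every gene). Returns a per-gene table of
    moderated t, two-sided p, BH q and log2 fold change.
    """
    if list(group_a.index) != list(group_b.index):
        raise ValidationError("groups must share the gene index")
    na, nb = group_a.shape[1], group_b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("each group needs >=2 columns")
    dof = na + nb - 2
    A, B = group_a.to_numpy(dtype=float), group_b.to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / dof
    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_prior(s2, dof)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + dof * s2) / (d0 + dof)
        df_total = d0 + dof
    diff = mean_a - mean_b
    denom = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "moderated_t": t,
            "p": p,
            "q": bh_q(p),
            "log2_fc": diff,
        },
        index=group_a.index,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    return out


def _contrast_groups(meta: pd.DataFrame, ann: CompoundAnnotation, contrast: str):
    carc = meta["compound"].map(lambda c: ann.label(c, "carcinogenic"))
    geno = meta["compound"].map(lambda c: ann.label(c, "genotoxic"))
    if contrast == "CG_vs_nonCG":
        a = carc == "positive"
        b = carc == "negative"
    elif contrast == "GT_vs_nonGT":
        a = geno == "positive"
        b = geno == "negative"
    elif contrast == "GTCG_vs_nonGTCG":
        a = (carc == "positive") & (geno == "positive")
        b = (carc == "positive") & (geno == "negative")
    elif contrast == "nonGTCG_vs_nonGTnonCG":
        a = (carc == "positive") & (geno == "negative")
        b = (carc == "negative") & (geno == "negative")
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return list(meta.index[a]), list(meta.index[b])


def build_signatures(
    ds: ExpressionDataset,
    ann: CompoundAnnotation,
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
    collapse: bool = True,
) -> dict[str, pd.DataFrame]:
    """Moderated-t signatures for the standard binary phenotype contrasts.

    Replicates of the same condition are averaged first so repeated
    profiles do not inflate significance. Controls are excluded; compounds
    with unknown labels drop out of the affected contrast.
    """
    work = collapse_replicates(ds) if collapse else ds
    treated_ids = work.treated_ids()
    values, meta = work.values[treated_ids], work.meta.loc[treated_ids]
    out: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        ids_a, ids_b = _contrast_groups(meta, ann, contrast)
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValidationError(f"contrast {contrast}: needs >=2 conditions per side")
        sig = moderated_ttest(values[ids_a], values[ids_b])
        sig.attrs["contrast"] = contrast
        out[contrast] = sig
    return out


def top_table(signature: pd.DataFrame, q_max: float = 0.05, fc_min: float = 1.2) -> pd.DataFrame:
    """Heatmap selection rule: q <= q_max and |fold change| >= fc_min."""
    fc = np.power(2.0, signature["log2_fc"].abs())
    return signature[(signature["q"] <= q_max) & (fc >= fc_min)].sort_values("q")


def preranked_enrichment(
    scores: pd.Series,
    gsc: GeneSetCollection,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked weighted-KS enrichment with a gene-permutation null.

    ``scores`` maps every gene in the universe to a finite differential
    score; genes are ranked by descending score with |score| weights. Per
    set, the null is built from ``n_perm`` random same-size gene subsets,
    p = (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm), with BH correction
    across sets. Sets that do not intersect the universe are skipped.
    """
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("scores must be finite")
    rng = np.random.default_rng(seed)
    order = scores.sort_values(ascending=False, kind="stable")
    # deterministic tie handling: within equal scores, order by gene id
    order = order.to_frame("s").reset_index().sort_values(["s", "index"], ascending=[False, True])
    genes = order["index"].to_numpy()
    weights = np.abs(order["s"].to_numpy(dtype=float))
    rp = RankedProfile(gene_ids=list(genes), weights=weights)
    universe = set(genes)
    n = len(genes)
    rows = []
    for name in gsc.names:
        members = [g for g in gsc[name] if g in universe]
        if not members or len(members) >= n:
            continue
        es = ks_enrichment_score(rp, members)
        size = len(members)
        perm_es = np.empty(n_perm)
        hit = np.zeros(n, dtype=bool)
        for i in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            hit[:] = False
            hit[idx] = True
            perm_es[i] = _es_walk(hit, weights)
        p = (1.0 + np.sum(np.abs(perm_es) >= abs(es) - 1e-12)) / (1.0 + n_perm)
        rows.append({"set_name": name, "size": size, "es": es, "p": p})
    out = pd.DataFrame(rows, columns=["set_name", "size", "es", "p"]).set_index("set_name")
    out["q"] = bh_q(out["p"].to_numpy())
    return out


def hyper_enrichment(
    top_genes: list[str],
    gsc: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of top genes per set."""
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    top = set(top_genes)
    if not top <= uni:
        raise ValidationError("top genes must be a subset of the universe")
    M, n_draw = len(uni), len(top)
    rows = []
    for name in gsc.names:
        members = set(gsc[name]) & uni
        if not members:
            continue
        k = len(members & top)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_draw))
        rows.append({"set_name": name, "set_size": len(members), "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"]).set_index("set_name")
    out["q"] = bh_q(out["p"].to_numpy())
    return out


@dataclass
class PCASummary:
    variance_fraction: np.ndarray  # per component, sums to 1
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components


def pca_summary(ds: ExpressionDataset, n_components: int | None = None) -> PCASummary:
    """Centered PCA over samples with deterministic component signs.

    Components are the right singular vectors of the gene-centered
    samples x genes matrix; each component's sign is fixed by making its
    largest-magnitude gene loading positive.
    """
    if ds.n_samples < 2:
        raise ValidationError("PCA needs >=2 samples")
    X = ds.values.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0)
    if np.allclose(X, 0):
        raise ValidationError("constant matrix: variance fractions undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    frac = (s**2) / (s**2).sum()
    # sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=ds.values.columns, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=ds.values.index, columns=comps)
    return PCASummary(variance_fraction=frac[:k], scores=scores, loadings=loadings)


def group_pc_variance(summary: PCASummary, groups: pd.Series, component: str = "PC1") -> pd.Series:
    """Variance of one component's scores within each sample group.

    Used to compare the spread of, e.g., genotoxic vs carcinogenic
    exposures along the leading principal axis.
    """
    scores = summary.scores[component]
    return scores.groupby(groups.loc[scores.index]).var(ddof=1)
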