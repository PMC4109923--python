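"""Matched-control gene-set projection.

Each treated sample is scored against its matched control samples: genes
are ranked by a control-referenced z-score and every gene set receives a
weighted Kolmogorov-Smirnov enrichment score (ES) on that ranking. The
projection maps a genes x samples matrix to a gene-set x samples matrix
whose entries reflect per-sample pathway activation relative to matched
controls. Because every sample is normalized against controls from its
own batch, the projected representation damps additive batch shifts.

This is deliberately not the rank-weighted single-sample GSEA variant:
the ranking statistic is true treatment-vs-control differential
expression, and the ES is the signed extremum of the running hit-miss
deviation with weight exponent 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from carcinogenome.core import (
    ExpressionDataset,
    GeneSetCollection,
    ProjectionMatrix,
    ValidationError,
    match_controls,
)

logger = logging.getLogger(__name__)

#: Stabilizer added to the control standard deviation.
EPSILON = 1e-6


@dataclass
class RankedProfile:
    """Gene ranking with non-negative weights, ordered best-to-worst."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) != self.weights.size:
            raise ValidationError("gene ids and weights must align")
        if not np.isfinite(self.weights).all() or (self.weights < 0).any():
            raise ValidationError("weights must be finite and non-negative")


def control_z_scores(
    ds: ExpressionDataset, sample_id: str, epsilon: float = EPSILON
) -> pd.Series:
    """Control-referenced differential score per gene for one treated sample.

    z_g = (x_g - mean(controls_g)) / (sd(controls_g) + epsilon). With a
    single matched control the per-gene spread is undefined and a scalar
    fallback is used: the standard deviation across genes of the
    treated-minus-control differences.
    """
    controls = match_controls(ds, sample_id)
    x = ds.values[sample_id].to_numpy(dtype=float)
    C = ds.values[controls].to_numpy(dtype=float)
    mu = C.mean(axis=1)
    if C.shape[1] >= 2:
        sd = C.std(axis=1, ddof=1)
    else:
        sd = np.full(len(x), np.std(x - mu))
    z = (x - mu) / (sd + epsilon)
    return pd.Series(z, index=ds.values.index)


def sample_vs_control_ranking(
    ds: ExpressionDataset, sample_id: str, epsilon: float = EPSILON
) -> RankedProfile:
    """Rank all genes by descending control-referenced z; weights are |z|.

    Ties in z are broken by gene id (lexicographic) for determinism; an
    all-zero score vector therefore degrades to plain gene-id order.
    """
    z = control_z_scores(ds, sample_id, epsilon)
    frame = z.to_frame("z").reset_index(names="gene_id")
    frame = frame.sort_values(["z", "gene_id"], ascending=[False, True], kind="stable")
    return RankedProfile(gene_ids=list(frame["gene_id"]), weights=np.abs(frame["z"].to_numpy()))


def _es_walk(hit: np.ndarray, weights: np.ndarray) -> float:
    """ES of a boolean hit vector (in rank order) with matching weights."""
    n = hit.size
    n_hit = int(hit.sum())
    if weights.sum() == 0:
        return 0.0
    w_sum = weights[hit].sum()
    if w_sum == 0:
        # set genes carry no weight: pure miss walk, maximal deviation is -1
        return -1.0 if n > n_hit else 0.0
    p_hit = np.cumsum(np.where(hit, weights, 0.0)) / w_sum
    p_miss = np.cumsum(~hit) / (n - n_hit)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def ks_enrichment_score(rp: RankedProfile, gene_set: Sequence[str]) -> float:
    """Weighted KS enrichment score of a gene set on a ranked profile.

    Walking the ranking, the hit curve climbs by weight_g / sum(set
    weights) at member genes and the miss curve by 1/(N - |set|)
    elsewhere; the ES is the running difference of maximal absolute
    value, signed. When every weight is zero the ES is 0 by convention.
    """
    members = set(gene_set) & set(rp.gene_ids)
    n = len(rp.gene_ids)
    if not members:
        raise ValidationError("gene set does not intersect the ranked universe")
    if len(members) >= n:
        raise ValidationError("gene set covers the whole universe")
    hit = np.fromiter((g in members for g in rp.gene_ids), dtype=bool, count=n)
    return _es_walk(hit, rp.weights)


def _es_for_sets(order_idx: np.ndarray, weights: np.ndarray, set_masks: np.ndarray) -> np.ndarray:
    """Vectorized ES over many sets for one ranking.

    ``set_masks`` is sets x genes (in unranked gene index space); rows
    with all-zero weight sums fall back to the scalar routine's
    conventions.
    """
    n = order_idx.size
    masks = set_masks[:, order_idx]  # sets x genes in rank order
    w = weights[np.newaxis, :]
    sizes = masks.sum(axis=1)
    w_sums = (masks * w).sum(axis=1)
    es = np.zeros(set_masks.shape[0])
    total_w = weights.sum()
    valid = (sizes > 0) & (sizes < n)
    if total_w == 0:
        return es
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hit = np.cumsum(masks * w, axis=1) / w_sums[:, None]
        p_miss = np.cumsum(~masks, axis=1) / (n - sizes)[:, None]
        dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    es_all = dev[np.arange(dev.shape[0]), idx]
    es[valid & (w_sums > 0)] = es_all[valid & (w_sums > 0)]
    es[valid & (w_sums == 0)] = -1.0
    return es


def project_dataset(
    ds: ExpressionDataset,
    gsc: GeneSetCollection,
    epsilon: float = EPSILON,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> ProjectionMatrix:
    """Project every treated sample onto gene-set space.

    Entry (s, j) is the weighted-KS ES of set s on sample j's matched
    control ranking. Control samples are excluded from the columns; sets
    that do not intersect the gene universe (or fall outside the size
    bounds) are skipped with a warning.
    """
    genes = ds.gene_ids
    restricted = gsc.restricted(genes, min_size=max(1, min_set_size), max_size=max_set_size)
    names = [s for s in restricted.names if len(restricted[s]) < len(genes)]
    dropped = set(restricted.names) - set(names)
    if dropped:
        logger.warning("sets covering the whole universe skipped: %s", sorted(dropped))
    if not names:
        raise ValidationError("no usable gene sets after restriction")
    gene_pos = {g: i for i, g in enumerate(genes)}
    set_masks = np.zeros((len(names), len(genes)), dtype=bool)
    for i, name in enumerate(names):
        for g in restricted[name]:
            set_masks[i, gene_pos[g]] = True
    treated = ds.treated_ids()
    es = np.empty((len(names), len(treated)))
    gene_arr = np.array(genes)
    for j, sid in enumerate(treated):
        z = control_z_scores(ds, sid, epsilon).to_numpy()
        # descending z, gene-id tie-break
        order = np.lexsort((gene_arr, -z))
        es[:, j] = _es_for_sets(order, np.abs(z[order]), set_masks)
    return ProjectionMatrix(
        es=pd.DataFrame(es, index=pd.Index(names, name="set_name"), columns=treated)
    )
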