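"""Synthetic toxicogenomic cohorts with known ground truth.

The generator emulates the design of large rat exposure compendia: each
compound is profiled at several dose levels and exposure times, in
triplicate, with matched control animals per (tissue, time, batch)
stratum. Carcinogenic compounds perturb one or more planted
mechanism-of-action gene modules with a dose- and time-dependent log2
shift; genotoxic carcinogens additionally activate a designated DNA
damage-response module. Additive gene-wise batch shifts emulate
dataset-to-dataset microarray bias. The returned ``SyntheticTruth``
records every planted parameter for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from carcinogenome.core import (
    CONTROL,
    CompoundAnnotation,
    ExpressionDataset,
    GeneSetCollection,
    ValidationError,
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; the seed fully determines output.

    Defaults mirror a desk-scale rendition of the study design: ~40
    compounds (a third carcinogenic, of which 40% genotoxic), triplicates
    at three dose levels and four exposure times, five mechanism modules
    of 50 genes, and unit-variance log2 noise around gene baselines.
    """

    n_genes: int = 1000
    n_compounds: int = 40
    frac_carcinogenic: float = 0.32
    frac_genotoxic_of_carcinogens: float = 0.4
    n_moa_modules: int = 5
    module_size: int = 50
    effect_size: float = 1.0
    dose_levels: tuple[str, ...] = ("low", "middle", "high")
    times: tuple[float, ...] = (4.0, 8.0, 15.0, 29.0)  # days
    n_replicates: int = 3
    n_controls_per_group: int = 3
    noise_sd: float = 0.4
    batch_ids: tuple[str, ...] = ("A",)
    batch_shift_sd: float = 0.0
    dose_response: tuple[float, ...] = (0.3, 0.6, 1.0)
    off_target_fraction: float = 0.0
    tissue: str = "liver"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_compounds", "n_moa_modules", "module_size",
                     "n_replicates", "n_controls_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.frac_carcinogenic < 1:
            raise ValidationError("frac_carcinogenic must be in (0, 1)")
        if not 0 <= self.frac_genotoxic_of_carcinogens <= 1:
            raise ValidationError("frac_genotoxic_of_carcinogens must be in [0, 1]")
        if self.module_size * self.n_moa_modules > self.n_genes:
            raise ValidationError("modules exceed the gene universe")
        if len(self.dose_response) != len(self.dose_levels):
            raise ValidationError("dose_response must match dose_levels")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    labels: pd.DataFrame  # index compound; carcinogenic, genotoxic (bool), batch_id
    module_genes: dict[int, list[str]]
    module_direction: dict[int, int]  # +1 up-regulated, -1 down-regulated
    compound_modules: dict[str, list[int]]
    batch_shift: dict[str, np.ndarray]
    damage_module: int
    gene_ids: list[str] = field(default_factory=list)

    def carcinogens(self) -> list[str]:
        return list(self.labels.index[self.labels["carcinogenic"]])

    def active_genes(self) -> set[str]:
        """Union of module genes activated by at least one compound."""
        active: set[str] = set()
        for mods in self.compound_modules.values():
            for m in mods:
                active.update(self.module_genes[m])
        return active


def time_ramp(times: Sequence[float]) -> dict[float, float]:
    """Linear multiplier from 0.5 at the shortest time to 1.0 at the longest."""
    lo, hi = min(times), max(times)
    if hi == lo:
        return {float(lo): 1.0}
    return {float(t): 0.5 + 0.5 * (t - lo) / (hi - lo) for t in times}


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionDataset, CompoundAnnotation, SyntheticTruth]:
    """Generate one cohort (expression + annotation + truth) from a spec."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    baseline = rng.normal(8.0, 2.0, size=spec.n_genes)

    # modules: disjoint gene blocks with a fixed direction each
    module_genes: dict[int, list[str]] = {}
    perm = rng.permutation(spec.n_genes)
    for m in range(spec.n_moa_modules):
        idx = perm[m * spec.module_size : (m + 1) * spec.module_size]
        module_genes[m] = [genes[i] for i in sorted(idx)]
    module_direction = {m: (1 if rng.random() < 0.7 else -1) for m in module_genes}
    damage_module = 0

    # compounds, labels and batch assignment (labels balanced across batches)
    compounds = [f"cpd{i:03d}" for i in range(spec.n_compounds)]
    n_carc = max(1, round(spec.frac_carcinogenic * spec.n_compounds))
    carc_flags = np.zeros(spec.n_compounds, dtype=bool)
    carc_flags[rng.choice(spec.n_compounds, size=n_carc, replace=False)] = True
    geno_flags = np.zeros(spec.n_compounds, dtype=bool)
    carc_idx = np.flatnonzero(carc_flags)
    n_gt = round(spec.frac_genotoxic_of_carcinogens * n_carc)
    if n_gt:
        geno_flags[rng.choice(carc_idx, size=n_gt, replace=False)] = True

    batch_of: dict[str, str] = {}
    for flags in (carc_idx, np.flatnonzero(~carc_flags)):
        for j, ci in enumerate(flags):
            batch_of[compounds[ci]] = spec.batch_ids[j % len(spec.batch_ids)]

    # round-robin over a shuffled order keeps every mechanism represented
    # by a comparable number of carcinogens without confounding the
    # module assignment with the (also round-robin) batch assignment
    mechanism_modules = [m for m in module_genes if m != damage_module] or [damage_module]
    module_order = rng.permutation(carc_idx)
    module_of = {
        compounds[ci]: mechanism_modules[j % len(mechanism_modules)]
        for j, ci in enumerate(module_order)
    }
    compound_modules: dict[str, list[int]] = {}
    for i, cpd in enumerate(compounds):
        mods: list[int] = []
        if carc_flags[i]:
            mods.append(int(module_of[cpd]))
            if geno_flags[i] and damage_module not in mods:
                mods.append(damage_module)
        elif spec.off_target_fraction and rng.random() < spec.off_target_fraction:
            mods.append(int(rng.choice(mechanism_modules)))
        compound_modules[cpd] = mods

    batch_shift = {
        b: rng.normal(0.0, spec.batch_shift_sd, size=spec.n_genes) if spec.batch_shift_sd > 0
        else np.zeros(spec.n_genes)
        for b in spec.batch_ids
    }
    ramp = time_ramp(spec.times)
    dose_mult = dict(zip(spec.dose_levels, spec.dose_response))
    gene_pos = {g: i for i, g in enumerate(genes)}

    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    def add_sample(sid, compound, dose, t, rep, batch, is_control, shift):
        x = baseline + batch_shift[batch] + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
        if shift is not None:
            x = x + shift
        cols[sid] = x
        meta_rows.append(
            dict(
                sample_id=sid, compound=compound, dose_level=dose, time=t,
                replicate=rep, tissue=spec.tissue, is_control=is_control,
                batch_id=batch,
                control_group_id=f"{spec.tissue}|{t}|{batch}",
            )
        )

    for cpd in compounds:
        batch = batch_of[cpd]
        mods = compound_modules[cpd]
        for dose in spec.dose_levels:
            for t in spec.times:
                shift = np.zeros(spec.n_genes)
                for m in mods:
                    amp = spec.effect_size * dose_mult[dose] * ramp[float(t)] * module_direction[m]
                    for g in module_genes[m]:
                        shift[gene_pos[g]] += amp
                for rep in range(1, spec.n_replicates + 1):
                    sid = f"{cpd}_{dose}_{t:g}_{rep}"
                    add_sample(sid, cpd, dose, float(t), rep, batch, False, shift)

    for batch in spec.batch_ids:
        for t in spec.times:
            for rep in range(1, spec.n_controls_per_group + 1):
                sid = f"CTRL_{batch}_{t:g}_{rep}"
                add_sample(sid, CONTROL, None, float(t), rep, batch, True, None)

    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    ds = ExpressionDataset(values, meta)

    ann_tab = pd.DataFrame(
        {
            "carcinogenic": ["positive" if f else "negative" for f in carc_flags],
            "genotoxic": ["positive" if f else "negative" for f in geno_flags],
        },
        index=pd.Index(compounds, name="compound"),
    )
    ann = CompoundAnnotation(ann_tab)

    truth = SyntheticTruth(
        labels=pd.DataFrame(
            {
                "carcinogenic": carc_flags,
                "genotoxic": geno_flags,
                "batch_id": [batch_of[c] for c in compounds],
            },
            index=pd.Index(compounds, name="compound"),
        ),
        module_genes=module_genes,
        module_direction=module_direction,
        compound_modules=compound_modules,
        batch_shift=batch_shift,
        damage_module=damage_module,
        gene_ids=genes,
    )
    return ds, ann, truth


def generate_gmt(
    truth: SyntheticTruth,
    n_decoy_sets: int = 20,
    set_size_range: tuple[int, int] = (20, 80),
    seed: int = 0,
) -> GeneSetCollection:
    """True-module gene sets plus random decoy sets over the same universe.

    Set names flag provenance: ``TRUE_MODULE_<m>`` holds exactly the
    planted module membership; ``DECOY_<i>`` is a uniform random draw.
    """
    if n_decoy_sets < 0:
        raise ValidationError("n_decoy_sets must be >= 0")
    lo, hi = set_size_range
    if hi > len(truth.gene_ids):
        raise ValidationError("decoy set size range exceeds the gene universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {
        f"TRUE_MODULE_{m}": list(genes) for m, genes in truth.module_genes.items()
    }
    genes = np.array(truth.gene_ids)
    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"DECOY_{i:04d}"] = list(genes[rng.choice(len(genes), size=size, replace=False)])
    return GeneSetCollection(sets, source="synthetic")


def generate_histopathology(
    ds: ExpressionDataset,
    truth: SyntheticTruth,
    n_covariates: int = 133,
    sensitivity: float = 0.9,
    specificity: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal (0-4) histopathology covariates per sample.

    Per-covariate nonzero probabilities are calibrated so a
    carcinogen-treated sample shows any finding with probability
    ``sensitivity`` and any other sample (non-carcinogen-treated or
    control) stays all-zero with probability ``specificity``. Severities
    are uniform on {1..4}.
    """
    if n_covariates < 1:
        raise ValidationError("n_covariates must be >= 1")
    if not (0 < sensitivity <= 1 and 0 < specificity <= 1):
        raise ValidationError("sensitivity and specificity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    carcinogens = set(truth.carcinogens())
    p_pos = 1.0 - (1.0 - sensitivity) ** (1.0 / n_covariates)
    p_neg = 1.0 - specificity ** (1.0 / n_covariates)
    rows = []
    for sid in ds.sample_ids:
        cpd = ds.meta.loc[sid, "compound"]
        p = p_pos if cpd in carcinogens else p_neg
        nonzero = rng.random(n_covariates) < p
        sev = rng.integers(1, 5, size=n_covariates)
        rows.append(np.where(nonzero, sev, 0))
    cols = [f"path{i:03d}" for i in range(n_covariates)]
    return pd.DataFrame(rows, index=pd.Index(ds.sample_ids, name="sample_id"), columns=cols)


def generate_structural_features(
    truth: SyntheticTruth,
    n_features: int = 64,
    informative_fraction: float = 0.25,
    flip_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary chemical-structure-like features per compound.

    A fraction of features tracks the carcinogenicity label through
    label-flip noise at ``flip_rate``; the rest are Bernoulli(0.5).
    """
    if not (0 <= informative_fraction <= 1 and 0 <= flip_rate <= 1):
        raise ValidationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    compounds = list(truth.labels.index)
    y = truth.labels["carcinogenic"].to_numpy().astype(int)
    n_inf = round(informative_fraction * n_features)
    feats = np.empty((len(compounds), n_features), dtype=int)
    for j in range(n_features):
        if j < n_inf:
            flips = rng.random(len(compounds)) < flip_rate
            feats[:, j] = np.where(flips, 1 - y, y)
        else:
            feats[:, j] = rng.integers(0, 2, size=len(compounds))
    cols = [f"struct{i:03d}" for i in range(n_features)]
    return pd.DataFrame(feats, index=pd.Index(compounds, name="compound"), columns=cols)
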