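"""Domain containers and tab-delimited I/O for the analysis pipeline.

All matrices are pandas DataFrames: expression values are genes x samples
on a log2 scale; derived matrices (t-scores, projections) keep the same
orientation. Sample metadata travels with the expression matrix inside an
:class:`ExpressionDataset` and is validated on construction, so downstream
stages can rely on matched controls being resolvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel compound name carried by control samples.
CONTROL = "CONTROL"

#: Metadata columns every dataset carries (control_group_id is derived when absent).
META_COLUMNS = [
    "compound",
    "dose_level",
    "time",
    "replicate",
    "tissue",
    "is_control",
    "batch_id",
    "control_group_id",
]

LABELS = ("positive", "negative", "unknown")


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what}: {dup!r}")


def default_control_group(meta: pd.DataFrame) -> pd.Series:
    """Control-group key: the (tissue, time, batch) stratum of each sample."""
    return (
        meta["tissue"].astype(str)
        + "|"
        + meta["time"].astype(str)
        + "|"
        + meta["batch_id"].astype(str)
    )


@dataclass
class ExpressionDataset:
    """Genes x samples log2 abundance matrix bound to per-sample metadata.

    ``values`` is indexed by gene id with one column per sample id;
    ``meta`` is indexed by sample id in the same order as the columns.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression values must all be finite")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns and c != "control_group_id"]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if "control_group_id" not in self.meta.columns:
            self.meta = self.meta.copy()
            self.meta["control_group_id"] = default_control_group(self.meta)
        in_matrix = set(self.values.columns)
        in_meta = set(self.meta.index)
        if in_matrix != in_meta:
            odd = sorted(in_matrix ^ in_meta)
            raise ValidationError(f"sample ids differ between matrix and metadata: {odd}")
        self.meta = self.meta.loc[self.values.columns]
        bad_ctrl = self.meta.loc[self.meta["is_control"] & (self.meta["compound"] != CONTROL)]
        if len(bad_ctrl):
            raise ValidationError(
                f"control samples must carry compound={CONTROL!r}: {list(bad_ctrl.index[:3])}"
            )
        self._validate_control_links()

    def _validate_control_links(self) -> None:
        ctrl = self.meta[self.meta["is_control"]]
        groups = ctrl.groupby(["control_group_id", "tissue", "batch_id"]).size()
        available = set(groups.index)
        treated = self.meta[~self.meta["is_control"]]
        for sid, row in treated.iterrows():
            key = (row["control_group_id"], row["tissue"], row["batch_id"])
            if key not in available:
                raise ValidationError(
                    f"treated sample {sid!r} has no matched controls in group "
                    f"{row['control_group_id']!r} (tissue/batch must agree)"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def treated_ids(self) -> list[str]:
        return list(self.meta.index[~self.meta["is_control"]])

    def control_ids(self) -> list[str]:
        return list(self.meta.index[self.meta["is_control"]])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        sample_ids = list(sample_ids)
        return ExpressionDataset(self.values[sample_ids], self.meta.loc[sample_ids])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(gene_ids)], self.meta)


@dataclass
class CompoundAnnotation:
    """Per-compound carcinogenicity / genotoxicity labels.

    ``table`` is indexed by compound with columns ``carcinogenic`` and
    ``genotoxic`` taking values in {positive, negative, unknown}.
    ``dose_specific`` optionally maps (compound, dose_level) to a
    carcinogenicity label, for cohorts annotated per administered dose.
    """

    table: pd.DataFrame
    dose_specific: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "compound")
        for col in ("carcinogenic", "genotoxic"):
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")
            bad = set(self.table[col]) - set(LABELS)
            if bad:
                raise ValidationError(f"invalid {col} labels: {sorted(bad)}")
        for (cpd, dose), lab in self.dose_specific.items():
            if lab not in LABELS:
                raise ValidationError(f"invalid dose-specific label {lab!r} for {cpd}@{dose}")

    @property
    def compounds(self) -> list[str]:
        return list(self.table.index)

    def label(self, compound: str, phenotype: str = "carcinogenic", dose_level: str | None = None) -> str:
        """Three-valued label for a compound, dose-specific when available."""
        if phenotype not in ("carcinogenic", "genotoxic"):
            raise ValueError(f"unknown phenotype {phenotype!r}")
        if phenotype == "carcinogenic" and dose_level is not None:
            key = (compound, dose_level)
            if key in self.dose_specific:
                return self.dose_specific[key]
        if compound not in self.table.index:
            return "unknown"
        return str(self.table.loc[compound, phenotype])

    def known(self, phenotype: str = "carcinogenic") -> pd.Series:
        """Boolean series (True = positive) over compounds with known labels."""
        col = self.table[phenotype]
        known = col[col != "unknown"]
        return known == "positive"


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. canonical pathways from a GMT file)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.sets.items():
            uniq = list(dict.fromkeys(genes))
            if not uniq:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = uniq
        self.sets = cleaned

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def restricted(self, universe: Sequence[str], min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with a gene universe, dropping sets that fall
        outside the requested size range (with a logged warning)."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in uni]
            if len(inter) < min_size or (max_size is not None and len(inter) > max_size):
                logger.warning("gene set %s dropped after restriction (size %d)", name, len(inter))
                continue
            kept[name] = inter
        return GeneSetCollection(kept, source=self.source)


@dataclass
class TScoreMatrix:
    """Perturbational transcriptome: genes x compound-instance t-scores.

    ``t``, ``q`` and ``fc`` share index (gene ids) and columns (compound or
    ``compound@dose`` instance keys). ``instance_meta`` maps each column to
    its compound and dose level.
    """

    t: pd.DataFrame
    q: pd.DataFrame
    fc: pd.DataFrame
    instance_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.t.shape == self.q.shape == self.fc.shape):
            raise ValidationError("t, q, fc must share shape")
        if not (list(self.t.columns) == list(self.q.columns) == list(self.fc.columns)):
            raise ValidationError("t, q, fc must share columns")
        qv = self.q.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.nanmin(qv) < 0 or np.nanmax(qv) > 1:
                raise ValidationError("q-values must lie in [0, 1]")
        fcv = self.fc.to_numpy()
        if np.nanmin(fcv) <= 0:
            raise ValidationError("fold changes must be positive")

    @property
    def instances(self) -> list[str]:
        return list(self.t.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.t.index)


@dataclass
class ProjectionMatrix:
    """Gene-set x sample matrix of matched-control enrichment scores."""

    es: pd.DataFrame  # set names x treated sample ids

    def __post_init__(self) -> None:
        v = self.es.to_numpy()
        if np.nanmin(v) < -1 - 1e-9 or np.nanmax(v) > 1 + 1e-9:
            raise ValidationError("enrichment scores must lie in [-1, 1]")

    @property
    def set_names(self) -> list[str]:
        return list(self.es.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.es.columns)


# ---------------------------------------------------------------------------
# I/O: everything is UTF-8, tab-delimited, '.' decimal.
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Read a genes x samples TSV plus its companion metadata TSV.

    The matrix header row holds sample ids; the first column holds gene
    ids. The metadata table has one row per sample. Mismatched or
    duplicated ids and non-numeric cells are rejected with the offending
    coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(raw.index, "gene id")
    _check_unique(raw.columns, "sample id")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    for col in raw.columns:
        try:
            # python float() is round-trip exact, unlike the fast csv parser
            converted = raw[col].map(lambda s: float(s) if s is not None else np.nan)
        except (TypeError, ValueError):
            for g, cell in raw[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric cell at gene {g!r}, sample {col!r}"
                    ) from None
            raise
        if converted.isna().any():
            g = converted.index[converted.isna()][0]
            raise ValidationError(f"missing value at gene {g!r}, sample {col!r}")
        values[col] = converted.to_numpy(dtype=float)
    meta = read_metadata(meta_path)
    matrix_only = [s for s in values.columns if s not in meta.index]
    meta_only = [s for s in meta.index if s not in values.columns]
    if matrix_only:
        raise ValidationError(f"sample {matrix_only[0]!r} present in matrix but missing from metadata")
    if meta_only:
        raise ValidationError(f"sample {meta_only[0]!r} present in metadata but missing from matrix")
    # sample order follows the metadata table
    values = values[list(meta.index)]
    return ExpressionDataset(values, meta)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a sample_id column")
    _check_unique(meta["sample_id"], "sample id")
    meta = meta.set_index("sample_id")
    if "is_control" in meta.columns:
        meta["is_control"] = meta["is_control"].map(
            {"True": True, "False": False, "1": True, "0": False, "true": True, "false": False}
        )
    if "replicate" in meta.columns:
        meta["replicate"] = pd.to_numeric(meta["replicate"]).astype(int)
    if "time" in meta.columns:
        meta["time"] = pd.to_numeric(meta["time"])
    if "dose_level" in meta.columns:
        meta["dose_level"] = meta["dose_level"].where(meta["dose_level"].notna(), None)
    return meta


def write_expression(ds: ExpressionDataset, path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix and metadata back out; inverse of :func:`read_expression`."""
    out = ds.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    meta = ds.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, then member genes).

    Duplicate genes within a set are collapsed; empty sets are dropped with
    a warning; duplicate set names and short lines are rejected with their
    line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                logger.warning("GMT line %d: set %s is empty, dropped", lineno, name)
                continue
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gsc.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_annotation(path: str | Path, dose_path: str | Path | None = None) -> CompoundAnnotation:
    """Read a compound annotation TSV (compound, carcinogenic, genotoxic)
    and an optional dose-specific table (compound, dose_level, carcinogenic)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "compound" not in tab.columns:
        raise ValidationError("annotation must have a compound column")
    tab = tab.set_index("compound")
    dose_specific: dict[tuple[str, str], str] = {}
    if dose_path is not None:
        dtab = pd.read_csv(dose_path, sep="\t", dtype=str)
        for _, row in dtab.iterrows():
            dose_specific[(row["compound"], row["dose_level"])] = row["carcinogenic"]
    return CompoundAnnotation(tab, dose_specific)


def write_annotation(ann: CompoundAnnotation, path: str | Path, dose_path: str | Path | None = None) -> None:
    tab = ann.table.copy()
    tab.index.name = "compound"
    tab.to_csv(path, sep="\t")
    if dose_path is not None and ann.dose_specific:
        rows = [
            {"compound": c, "dose_level": d, "carcinogenic": lab}
            for (c, d), lab in ann.dose_specific.items()
        ]
        pd.DataFrame(rows).to_csv(dose_path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def collapse_replicates(
    ds: ExpressionDataset,
    key: Sequence[str] = ("compound", "dose_level", "time", "tissue", "batch_id"),
) -> ExpressionDataset:
    """Average replicate columns of the same condition.

    ``key`` is the tuple of metadata fields defining a condition; one
    output column is produced per distinct key combination, holding the
    arithmetic mean of its replicates. The ``replicate`` field of the
    collapsed metadata records how many columns were averaged.
    """
    allowed = {"compound", "dose_level", "time", "tissue", "batch_id"}
    if not set(key) <= allowed:
        raise ValueError(f"key fields must be within {sorted(allowed)}")
    if ds.n_samples == 0:
        raise ValidationError("cannot collapse an empty dataset")
    # control_group_id participates so controls from different strata never merge
    group_fields = list(key) + ["control_group_id", "is_control"]
    filled = ds.meta[group_fields].astype(object).where(ds.meta[group_fields].notna(), "NA")
    groups = filled.groupby(group_fields, sort=True, dropna=False).groups
    cols, meta_rows = {}, []
    for gkey, idx in sorted(groups.items(), key=lambda kv: tuple(map(str, kv[0]))):
        members = list(idx)
        name = "|".join(str(k) for k in gkey[: len(key) + 1])
        cols[name] = ds.values[members].mean(axis=1)
        row = ds.meta.loc[members[0]].copy()
        row["replicate"] = len(members)
        row.name = name
        meta_rows.append(row)
    values = pd.DataFrame(cols, index=ds.values.index)
    meta = pd.DataFrame(meta_rows)
    return ExpressionDataset(values, meta)


def match_controls(ds: ExpressionDataset, sample_id: str) -> list[str]:
    """Ids of the control samples matched to a treated sample.

    Controls share the sample's ``control_group_id`` (by default the
    (tissue, time, batch) stratum); the order is the dataset's column
    order, hence deterministic.
    """
    if sample_id not in ds.meta.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    row = ds.meta.loc[sample_id]
    if row["is_control"]:
        raise ValidationError(f"sample {sample_id!r} is a control, not a treated sample")
    mask = (
        ds.meta["is_control"]
        & (ds.meta["control_group_id"] == row["control_group_id"])
        & (ds.meta["tissue"] == row["tissue"])
        & (ds.meta["batch_id"] == row["batch_id"])
    )
    matched = list(ds.meta.index[mask])
    if not matched:
        raise ValidationError(f"no matched controls for treated sample {sample_id!r}")
    return matched
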