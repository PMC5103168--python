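"""Data types, TSV readers/writers and design validation.

The experimental layout is a 2x2 factorial: pre-natal treatment crossed with
post-natal treatment, each level either carrier control (C) or corticosterone
(B), profiled in two brain tissues (hippocampus, hypothalamus) with three
pooled biological replicates per treatment group.  Treatment groups are named
by pre-natal letter first: CC, BC, CB, BB.

Canonical on-disk formats are plain TSV: a gene x sample count matrix with
gene identifiers in the first column and a header row of sample identifiers,
and a sample sheet with fixed columns (sample_id, tissue, prenatal, postnatal,
replicate).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TISSUES = ("hippocampus", "hypothalamus")
TREATMENTS = ("C", "B")
#: treatment groups, pre-natal letter first
GROUPS = ("CC", "BC", "CB", "BB")
SAMPLE_SHEET_COLUMNS = ("sample_id", "tissue", "prenatal", "postnatal", "replicate")


class DesignError(ValueError):
    """Inputs violate the factorial design contract."""


class FormatError(ValueError):
    """A file does not conform to the expected TSV layout."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Raw integer read counts, genes in rows, samples in columns.

    ``counts`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  Validation enforces unique, non-empty identifiers and
    non-negative integral counts; the stored frame is an int64 copy.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FormatError("count matrix must have at least one gene and one sample")
        _check_unique(df.index, "gene id")
        _check_unique(df.columns, "sample id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count matrix contains non-numeric values")
        bad = ~np.isfinite(values) | (values < 0) | (np.mod(values, 1) != 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"count for gene {df.index[g]!r}, sample {df.columns[s]!r} is "
                f"{df.iat[g, s]!r}; counts must be non-negative integers"
            )
        clean = df.astype(np.int64)
        clean.index = clean.index.astype(str)
        clean.index.name = "gene_id"
        clean.columns = clean.columns.astype(str)
        object.__setattr__(self, "counts", clean)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise DesignError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise FormatError(f"duplicate {what}: {dup!r}")
    labels = index.astype(str)
    if (labels.str.len() == 0).any():
        raise FormatError(f"empty {what} not allowed")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Raises :class:`FormatError` naming the offending cell or identifier on
    duplicates, negative counts or non-integer counts.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        seen: set[str] = set()
        dup = next(s for s in sample_ids if s in seen or seen.add(s))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate sample id: {dup!r} in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r} in {path}")
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna()][0]
            raise FormatError(
                f"cell (gene {gene!r}, sample {col!r}) in {path} is not numeric: "
                f"{df.loc[gene, col]!r}"
            )
        parsed[col] = numeric
    return CountMatrix(parsed)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_tsv(path)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Per-sample factorial metadata.

    Columns: sample_id, tissue (hippocampus/hypothalamus), prenatal (C/B),
    postnatal (C/B), replicate (positive integer).  The group label is always
    derived as ``prenatal + postnatal`` and never stored.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = df.loc[:, list(SAMPLE_SHEET_COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(pd.Index(df["sample_id"]), "sample id")
        for col, allowed in (("tissue", TISSUES), ("prenatal", TREATMENTS), ("postnatal", TREATMENTS)):
            bad = ~df[col].isin(allowed)
            if bad.any():
                raise FormatError(
                    f"sample sheet column {col!r} has value "
                    f"{df.loc[bad, col].iloc[0]!r}; allowed: {allowed}"
                )
        rep = pd.to_numeric(df["replicate"], errors="coerce")
        if rep.isna().any() or (rep < 1).any() or (rep % 1 != 0).any():
            raise FormatError("replicate must be a positive integer for every sample")
        df["replicate"] = rep.astype(int)
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        """Derived group label per sample (CC/BC/CB/BB), pre-natal letter first."""
        g = self.table["prenatal"] + self.table["postnatal"]
        g.index = self.table["sample_id"]
        return g

    def for_tissue(self, tissue: str) -> "SampleSheet":
        if tissue not in TISSUES:
            raise DesignError(f"unknown tissue {tissue!r}; allowed: {TISSUES}")
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise DesignError(f"no samples for tissue {tissue!r}")
        return SampleSheet(sub)

    def samples_in(self, tissue: str, group: str) -> list[str]:
        """Sample ids of one treatment group within a tissue, ordered by replicate."""
        if group not in GROUPS:
            raise DesignError(f"unknown group {group!r}; allowed: {GROUPS}")
        df = self.table
        mask = (
            (df["tissue"] == tissue)
            & (df["prenatal"] == group[0])
            & (df["postnatal"] == group[1])
        )
        sub = df[mask].sort_values(["replicate", "sample_id"], kind="stable")
        return list(sub["sample_id"])

    def validate_pairing(self, cm: CountMatrix) -> None:
        sheet = set(self.sample_ids)
        matrix = set(cm.sample_ids)
        if sheet != matrix:
            only_sheet = sorted(sheet - matrix)
            only_matrix = sorted(matrix - sheet)
            raise DesignError(
                "sample sheet and count matrix disagree on sample ids; "
                f"only in sheet: {only_sheet}; only in matrix: {only_matrix}"
            )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def equals(self, other: "SampleSheet") -> bool:
        return self.table.equals(other.table)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(ss: SampleSheet, path: str | Path) -> None:
    ss.to_tsv(path)


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSummary:
    """Replicate counts per treatment group within one tissue."""

    tissue: str
    replicates: Mapping[str, int]
    low_replicate_groups: tuple[str, ...]

    def require_groups(self, groups: Sequence[str]) -> None:
        for g in groups:
            if self.replicates.get(g, 0) == 0:
                raise DesignError(
                    f"group {g!r} absent from tissue {self.tissue!r} but required"
                )


def validate_design(cm: CountMatrix, ss: SampleSheet, tissue: str) -> DesignSummary:
    """Summarise the four treatment groups of one tissue.

    Order-insensitive: permuting the rows of either input yields an identical
    summary.  Groups with fewer than two replicates are flagged (the rank
    product permutation scheme needs at least two per class).
    """
    ss.validate_pairing(cm)
    sub = ss.for_tissue(tissue)
    replicates = {g: len(sub.samples_in(tissue, g)) for g in GROUPS}
    low = tuple(g for g in GROUPS if replicates[g] < 2)
    return DesignSummary(tissue=tissue, replicates=replicates, low_replicate_groups=low)


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds and permutation settings.

    Defaults mirror the study cut-offs: significance at pfp (estimated FDR)
    <= 0.10 with 1000 permutations; vector filtering at |Vsum| >= 40 and
    permutation P <= 0.05; log2(x + 32) variance-stabilising transform;
    per-sample 75th-percentile scale factors.

    ``rp_null`` selects the rank-product permutation null: "expression"
    (default) permutes gene labels within each sample and recomputes the
    statistic, preserving the dependence between pairwise comparison columns
    that share a sample; "ranks" assigns each column an independent uniform
    rank permutation (the classical null, anti-conservative for all-pairs
    comparison matrices).
    """

    fdr_threshold: float = 0.10
    vsum_threshold: float = 40.0
    vector_p_threshold: float = 0.05
    n_permutations_rp: int = 1000
    n_permutations_vector: int = 1000
    log_offset: float = 32.0
    quantile: float = 0.75
    rp_null: str = "expression"
    vector_null: str = "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rp_null not in ("expression", "ranks"):
            raise ValueError(
                f"rp_null must be 'expression' or 'ranks', got {self.rp_null!r}"
            )
        if self.vector_null not in ("combined", "whole_design", "per_axis"):
            raise ValueError(
                "vector_null must be 'combined', 'whole_design' or 'per_axis', "
                f"got {self.vector_null!r}"
            )
        for name in ("fdr_threshold", "vector_p_threshold", "quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.vsum_threshold < 0:
            raise ValueError("vsum_threshold must be non-negative")
        if self.n_permutations_rp < 1 or self.n_permutations_vector < 1:
            raise ValueError("permutation counts must be positive")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON (YAML is a superset of JSON); every field optional."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise FormatError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)
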