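"""Seeded negative-binomial count simulator with planted factorial effects.

Emulates the study layout: two brain tissues, four treatment groups
(CC, BC, CB, BB; pre-natal letter first), three pooled biological replicates
per group.  Counts are negative binomial around a per-gene log2 baseline,
multiplied by log-normal per-sample library-size factors.  Genes can be
planted with one of four factorial "behavioural category" effects:

* I   common, non-additive: every B-exposed group shifted equally
      (offsets 0, s, s, s for CC, BC, CB, BB);
* II  cumulative/additive: the doubly exposed group shifted twice
      (0, s, s, 2s);
* III pre-natal-specific: only pre-natally exposed groups shifted
      (0, s, 0, s);
* IV  post-natal-specific (0, 0, s, s);

with s = +delta (up) or -delta (down) in log2 units.  The planted truth is
returned so downstream recovery can be scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import GROUPS, TISSUES, CountMatrix, SampleSheet

CATEGORIES = ("I", "II", "III", "IV")
SIGNS = ("up", "down")

#: multiples of the effect size per group, in (CC, BC, CB, BB) order
CATEGORY_PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "I": (0.0, 1.0, 1.0, 1.0),
    "II": (0.0, 1.0, 1.0, 2.0),
    "III": (0.0, 1.0, 0.0, 1.0),
    "IV": (0.0, 0.0, 1.0, 1.0),
    "none": (0.0, 0.0, 0.0, 0.0),
}


def plant_group_effects(
    category: str, sign: str, delta: float
) -> tuple[float, float, float, float]:
    """log2 group offsets (CC, BC, CB, BB) encoding one planted category."""
    if category not in CATEGORY_PATTERNS:
        raise ValueError(
            f"unknown category {category!r}; allowed: {sorted(CATEGORY_PATTERNS)}"
        )
    if category == "none":
        return (0.0, 0.0, 0.0, 0.0)
    if sign not in SIGNS:
        raise ValueError(f"sign must be 'up' or 'down' for planted genes, got {sign!r}")
    s = float(delta) if sign == "up" else -float(delta)
    return tuple(p * s for p in CATEGORY_PATTERNS[category])  # type: ignore[return-value]


def _default_planting() -> dict[str, int]:
    # 50 planted genes per category per sign at the default sign split
    return {"I": 100, "II": 100, "III": 100, "IV": 100}


def scaled_planting(n_genes: int, reference_genes: int = 15_000) -> dict[str, int]:
    """Default planting scaled proportionally to a non-default gene count."""
    return {
        c: max(1, round(n * n_genes / reference_genes))
        for c, n in _default_planting().items()
    }


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults are the study-scale conditions.

    ``baseline_logmean_mu``/``sd`` set the per-gene log2 expected count
    (mu = 7 puts the typical gene near 128 counts, i.e. a few million
    gene-assigned reads per library over 15 000 genes).  ``dispersion`` is
    the negative-binomial size parameter (scalar or per-gene); large values
    approach Poisson.  The default 25 reflects that each replicate is a pool
    of four birds: an individual-level biological CV of ~0.4 (size ~6)
    drops to ~0.2 when four animals are averaged, i.e. size ~25.
    ``libsize_sd`` is the log-normal sigma of per-sample scale factors.
    ``tissue_logfc_sd`` plants per-gene baseline shifts between tissues so
    the tissues separate on PC1 as real brain regions do.
    """

    n_genes: int = 15_000
    n_replicates: int = 3
    baseline_logmean_mu: float = 7.0
    baseline_logmean_sd: float = 2.0
    dispersion: float | Sequence[float] = 25.0
    libsize_sd: float = 0.25
    effect_size: float = 1.5
    n_per_category: Mapping[str, int] = field(default_factory=_default_planting)
    sign_fraction_up: float = 0.5
    tissue_logfc_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp <= 0).any():
            raise ValueError("dispersion must be positive")
        if disp.size not in (1, self.n_genes):
            raise ValueError("dispersion must be scalar or one value per gene")
        unknown = set(self.n_per_category) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in n_per_category: {sorted(unknown)}")
        if any(v < 0 for v in self.n_per_category.values()):
            raise ValueError("n_per_category values must be non-negative")
        if sum(self.n_per_category.values()) > self.n_genes:
            raise ValueError("sum of planted genes exceeds n_genes")
        if not 0 <= self.sign_fraction_up <= 1:
            raise ValueError("sign_fraction_up must be in [0, 1]")
        if self.libsize_sd < 0 or self.tissue_logfc_sd < 0:
            raise ValueError("libsize_sd and tissue_logfc_sd must be non-negative")


def _plan_truth(params: SimulationParams, rng: np.random.Generator,
                gene_ids: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Pick planted gene positions and build the truth table and offset matrix."""
    n_planted = sum(params.n_per_category.get(c, 0) for c in CATEGORIES)
    positions = rng.choice(params.n_genes, size=n_planted, replace=False)
    offsets = np.zeros((params.n_genes, len(GROUPS)))
    rows = []
    cursor = 0
    for category in CATEGORIES:
        n_cat = params.n_per_category.get(category, 0)
        n_up = int(round(n_cat * params.sign_fraction_up))
        for k in range(n_cat):
            sign = "up" if k < n_up else "down"
            pos = positions[cursor]
            cursor += 1
            offsets[pos, :] = plant_group_effects(category, sign, params.effect_size)
            rows.append(
                {
                    "gene_id": gene_ids[pos],
                    "category": category,
                    "sign": sign,
                    "effect_size": params.effect_size,
                }
            )
    truth = pd.DataFrame(rows, columns=["gene_id", "category", "sign", "effect_size"])
    if not truth.empty:
        truth = truth.sort_values("gene_id", kind="stable").reset_index(drop=True)
    return truth, offsets


def simulate_counts(
    params: SimulationParams,
    tissues: Sequence[str] = TISSUES,
) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Draw a seeded synthetic dataset (counts, sample sheet, planted truth).

    Counts for gene g in sample j of group G(j) are negative binomial with
    mean ``s_j * 2**(m_g + tissue_shift_g + offset[g, G(j)])`` and size
    ``dispersion``, where ``m_g ~ Normal(baseline_logmean_mu, sd)`` and
    ``s_j ~ logNormal(0, libsize_sd)``.  Both tissues share the planted truth
    but are drawn independently; identical params + seed give bit-identical
    output.
    """
    for t in tissues:
        if t not in TISSUES:
            raise ValueError(f"unknown tissue {t!r}; allowed: {TISSUES}")
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    width = max(5, len(str(G)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(G)]
    baseline = rng.normal(params.baseline_logmean_mu, params.baseline_logmean_sd, G)
    truth, offsets = _plan_truth(params, rng, gene_ids)
    disp = np.broadcast_to(np.atleast_1d(np.asarray(params.dispersion, float)), (G,))

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for t_index, tissue in enumerate(tissues):
        shift = (
            np.zeros(G)
            if t_index == 0 or params.tissue_logfc_sd == 0
            else rng.normal(0.0, params.tissue_logfc_sd, G)
        )
        for g_index, group in enumerate(GROUPS):
            for rep in range(1, params.n_replicates + 1):
                sid = f"{tissue[:3]}_{group}_r{rep}"
                libsize = (
                    1.0
                    if params.libsize_sd == 0
                    else float(rng.lognormal(0.0, params.libsize_sd))
                )
                mean = libsize * np.exp2(baseline + shift + offsets[:, g_index])
                p = disp / (disp + mean)
                columns[sid] = rng.negative_binomial(disp, p)
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "tissue": tissue,
                        "prenatal": group[0],
                        "postnatal": group[1],
                        "replicate": rep,
                    }
                )
    cm = CountMatrix(pd.DataFrame(columns, index=gene_ids))
    ss = SampleSheet(pd.DataFrame(sheet_rows))
    return cm, ss, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "category", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return df
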