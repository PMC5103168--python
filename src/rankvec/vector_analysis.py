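"""Per-gene vector summation of paired fold changes and sector classification.

Each gene's response to one developmental exposure is probed in two
background environments and drawn as a 2-D vector: the horizontal axis
(axis 0) is the response in the carrier-only other-stage environment, the
vertical axis (axis 1) the response in the B-exposed other-stage environment.

* ``postnatal_response``: axis0 = CB_vs_CC, axis1 = BB_vs_BC
  (post-natal exposure probed in the two pre-natal environments);
* ``prenatal_response``:  axis0 = BC_vs_CC, axis1 = BB_vs_CB.

With n replicates per group, each axis yields n*n between-replicate log2
differences and the gene's vectors are the full cross product of axis pairs
((n^2)^2 = 81 at n = 3).  The summed vector Vsum measures both effect size
and replicate consistency; significance comes from permuting the group
labels of the 4n involved samples.  Genes pass the filter when
|Vsum| >= vsum_threshold and P <= vector_p_threshold and are then classified
into eight 45-degree sectors centred on the semi-axes and diagonals, or
"unchanged" otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import DesignError, RunConfig, SampleSheet
from .rankprod import ContrastSpec, SixContrastResults, make_contrast


class ClassLabel(str, Enum):
    """Sector label of a summed vector ("0"/"1" are the two environments)."""

    BOTH_UP = "both_up"
    BOTH_DOWN = "both_down"
    OPPOSITE_0UP_1DOWN = "opposite_0up_1down"
    OPPOSITE_0DOWN_1UP = "opposite_0down_1up"
    ONLY0_UP = "only0_up"
    ONLY0_DOWN = "only0_down"
    ONLY1_UP = "only1_up"
    ONLY1_DOWN = "only1_down"
    UNCHANGED = "unchanged"


#: sector labels counterclockwise from the positive x axis; sector i covers
#: angles [-22.5 + 45*i, 22.5 + 45*i) degrees, half-open counterclockwise
_SECTORS = (
    ClassLabel.ONLY0_UP,
    ClassLabel.BOTH_UP,
    ClassLabel.ONLY1_UP,
    ClassLabel.OPPOSITE_0DOWN_1UP,
    ClassLabel.ONLY0_DOWN,
    ClassLabel.BOTH_DOWN,
    ClassLabel.ONLY1_DOWN,
    ClassLabel.OPPOSITE_0UP_1DOWN,
)

ANALYSES = ("postnatal_response", "prenatal_response")
#: (axis0, axis1) contrast groups per analysis
ANALYSIS_AXES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "postnatal_response": (("CB", "CC"), ("BB", "BC")),
    "prenatal_response": (("BC", "CC"), ("BB", "CB")),
}

VECTOR_COLUMNS = ("gene_id", "vsum_x", "vsum_y", "vsum_mag", "p_value", "cls", "n_vectors")


@dataclass(frozen=True)
class VectorAnalysisSpec:
    """The two axis contrasts of one vector analysis."""

    name: str
    axis0_contrast: ContrastSpec
    axis1_contrast: ContrastSpec

    def __post_init__(self) -> None:
        if self.name not in ANALYSES:
            raise ValueError(f"unknown analysis {self.name!r}; allowed: {ANALYSES}")

    @property
    def involved_samples(self) -> tuple[str, ...]:
        return (
            *self.axis0_contrast.class1_samples,
            *self.axis0_contrast.class2_samples,
            *self.axis1_contrast.class1_samples,
            *self.axis1_contrast.class2_samples,
        )


def make_vector_spec(ss: SampleSheet, tissue: str, name: str) -> VectorAnalysisSpec:
    if name not in ANALYSIS_AXES:
        raise ValueError(f"unknown analysis {name!r}; allowed: {ANALYSES}")
    (a1, a2), (b1, b2) = ANALYSIS_AXES[name]
    return VectorAnalysisSpec(
        name=name,
        axis0_contrast=make_contrast(ss, tissue, a1, a2),
        axis1_contrast=make_contrast(ss, tissue, b1, b2),
    )


def gene_universe(six: SixContrastResults, config: RunConfig | None = None) -> list[str]:
    """Genes significant (either direction) in at least one of the six contrasts.

    The pfp filtering already happened inside the contrast results; this is a
    plain union, so a gene significant in several contrasts appears once.
    """
    del config  # threshold applied when the contrast results were built
    universe: set[str] = set()
    for res in six:
        universe.update(res.significant["gene_id"])
    return sorted(universe)


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------

def _axis_differences(em: pd.DataFrame, contrast: ContrastSpec, gene: str) -> np.ndarray:
    for sid in (*contrast.class1_samples, *contrast.class2_samples):
        if sid not in em.columns:
            raise DesignError(f"sample {sid!r} missing from expression matrix")
    a = em.loc[gene, list(contrast.class1_samples)].to_numpy(dtype=float)
    b = em.loc[gene, list(contrast.class2_samples)].to_numpy(dtype=float)
    return (a[:, None] - b[None, :]).ravel()  # class1-major order


def between_replicate_vectors(
    em: pd.DataFrame, spec: VectorAnalysisSpec, gene: str
) -> np.ndarray:
    """All (x, y) fold-change vectors of one gene, shape (Kx * Ky, 2).

    x values are the axis-0 between-replicate differences (Kx = n1*n2 of
    them), y values the axis-1 differences; the vectors are their full cross
    product in x-major order.
    """
    x = _axis_differences(em, spec.axis0_contrast, gene)
    y = _axis_differences(em, spec.axis1_contrast, gene)
    return np.column_stack([np.repeat(x, y.size), np.tile(y, x.size)])


def vector_sum(vectors: np.ndarray) -> tuple[float, float, float]:
    """Componentwise sum and Euclidean magnitude of a vector set."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != 2 or vectors.shape[0] < 1:
        raise ValueError("expected a non-empty (n, 2) array of vectors")
    vx, vy = vectors.sum(axis=0)
    return float(vx), float(vy), float(np.hypot(vx, vy))


def _block_vsums(
    X: np.ndarray, sizes: tuple[int, int, int, int], normalize_vectors: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vsum components for genes x samples block-ordered data.

    Columns of ``X`` hold the four contrast classes consecutively
    (axis0 class1, axis0 class2, axis1 class1, axis1 class2).  The raw sum
    over the (Kx * Ky) cross-product vectors reduces to Ky * sum(x diffs)
    and Kx * sum(y diffs); the unit-normalized variant sums each vector
    scaled to length 1 and needs the explicit cross product.
    """
    n1a, n2a, n1b, n2b = sizes
    stops = np.cumsum((n1a, n2a, n1b, n2b))
    a1, a2, b1, b2 = np.split(X, stops[:-1], axis=1)
    if not normalize_vectors:
        kx, ky = n1a * n2a, n1b * n2b
        sum_x = n2a * a1.sum(axis=1) - n1a * a2.sum(axis=1)
        sum_y = n2b * b1.sum(axis=1) - n1b * b2.sum(axis=1)
        vx, vy = ky * sum_x, kx * sum_y
    else:
        x = (a1[:, :, None] - a2[:, None, :]).reshape(X.shape[0], -1)
        y = (b1[:, :, None] - b2[:, None, :]).reshape(X.shape[0], -1)
        xx = np.repeat(x, y.shape[1], axis=1)
        yy = np.tile(y, (1, x.shape[1]))
        norm = np.hypot(xx, yy)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(norm > 0, xx / norm, 0.0)
            uy = np.where(norm > 0, yy / norm, 0.0)
        vx, vy = ux.sum(axis=1), uy.sum(axis=1)
    return vx, vy, np.hypot(vx, vy)


def _analysis_matrix(
    em: pd.DataFrame, spec: VectorAnalysisSpec, genes: Sequence[str]
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    samples = list(spec.involved_samples)
    if len(samples) != len(set(samples)):
        raise DesignError("vector analysis classes overlap; groups must be disjoint")
    missing = [s for s in samples if s not in em.columns]
    if missing:
        raise DesignError(f"samples missing from expression matrix: {missing}")
    absent = [g for g in genes if g not in em.index]
    if absent:
        raise DesignError(f"genes missing from expression matrix: {absent[:5]}")
    X = em.loc[list(genes), samples].to_numpy(dtype=float)
    sizes = (
        len(spec.axis0_contrast.class1_samples),
        len(spec.axis0_contrast.class2_samples),
        len(spec.axis1_contrast.class1_samples),
        len(spec.axis1_contrast.class2_samples),
    )
    return X, sizes


VECTOR_NULLS = ("combined", "whole_design", "per_axis")


def _permutation_exceedances(
    X: np.ndarray,
    sizes: tuple[int, int, int, int],
    observed: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    scheme: str,
    normalize_vectors: bool,
) -> np.ndarray:
    n_axis0 = sizes[0] + sizes[1]
    n_total = X.shape[1]
    exceed = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(n_permutations):
        if scheme == "whole_design":
            idx = rng.permutation(n_total)
        else:  # per_axis: each axis's samples shuffled among themselves
            idx = np.concatenate(
                [rng.permutation(n_axis0), n_axis0 + rng.permutation(n_total - n_axis0)]
            )
        _, _, mag = _block_vsums(X[:, idx], sizes, normalize_vectors)
        exceed += mag >= observed
    return exceed


def vector_permutation_p(
    em: pd.DataFrame,
    spec: VectorAnalysisSpec,
    genes: Sequence[str],
    n_permutations: int,
    rng: np.random.Generator | int | None = None,
    normalize_vectors: bool = False,
    null_scheme: str = "combined",
) -> pd.Series:
    """Permutation P-values of |Vsum| for a gene set.

    Each scheme runs B label permutations (the same permutation applied to
    every gene within a round) and scores
    p = (1 + #{permuted |Vsum| >= observed}) / (B + 1):

    * ``whole_design`` reassigns the 4n involved samples to the four group
      slots; fine-grained (12!/(3!)^4 arrangements at n = 3) but a purely
      additive gene is never among its own 5% most extreme arrangements, so
      cumulative responses cannot reach p <= 0.05;
    * ``per_axis`` permutes each axis's 2n samples among themselves,
      independently; certifies additive genes but with only C(2n, n) splits
      per axis its p floor at n = 3 (~0.05) truncates single-axis genes;
    * ``combined`` (default) Bonferroni-combines the two,
      p = min(1, 2 min(p_whole, p_axis)); both components are valid tests of
      the same exchangeability null, and together they have power for every
      response geometry the sector classes describe.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if null_scheme not in VECTOR_NULLS:
        raise ValueError(f"null_scheme must be one of {VECTOR_NULLS}, got {null_scheme!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X, sizes = _analysis_matrix(em, spec, genes)
    _, _, observed = _block_vsums(X, sizes, normalize_vectors)
    schemes = (
        ("whole_design", "per_axis") if null_scheme == "combined" else (null_scheme,)
    )
    p_parts = []
    for scheme in schemes:
        exceed = _permutation_exceedances(
            X, sizes, observed, n_permutations, rng, scheme, normalize_vectors
        )
        p_parts.append((1.0 + exceed) / (n_permutations + 1.0))
    p = np.minimum(1.0, len(p_parts) * np.minimum.reduce(p_parts))
    return pd.Series(p, index=list(genes), name="p_value")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_sector(
    vsum_x: float,
    vsum_y: float,
    p_value: float,
    config: RunConfig | None = None,
) -> ClassLabel:
    """Sector label of one summed vector under the magnitude and P filters.

    "unchanged" whenever |Vsum| < vsum_threshold or P > vector_p_threshold;
    otherwise one of eight 45-degree sectors by the angle atan2(y, x), with
    half-open boundaries at odd multiples of 22.5 degrees (a boundary angle
    belongs to the counterclockwise sector).
    """
    config = config or RunConfig()
    mag = float(np.hypot(vsum_x, vsum_y))
    if mag < config.vsum_threshold or p_value > config.vector_p_threshold:
        return ClassLabel.UNCHANGED
    theta = np.degrees(np.arctan2(vsum_y, vsum_x))
    sector = int(((theta + 22.5) % 360.0) // 45.0) % 8
    return _SECTORS[sector]


def _classify_arrays(
    vx: np.ndarray, vy: np.ndarray, mag: np.ndarray, p: np.ndarray, config: RunConfig
) -> list[str]:
    theta = np.degrees(np.arctan2(vy, vx))
    sectors = (((theta + 22.5) % 360.0) // 45.0).astype(int) % 8
    labels = np.array([s.value for s in _SECTORS], dtype=object)[sectors]
    unchanged = (mag < config.vsum_threshold) | (p > config.vector_p_threshold)
    labels[unchanged] = ClassLabel.UNCHANGED.value
    return list(labels)


def run_vector_analysis(
    em: pd.DataFrame,
    ss: SampleSheet,
    tissue: str,
    name: str,
    genes: Sequence[str],
    config: RunConfig | None = None,
    rng: np.random.Generator | int | None = None,
    normalize_vectors: bool = False,
) -> pd.DataFrame:
    """One complete vector analysis over a gene universe.

    Returns one row per gene: summed vector components, magnitude,
    permutation P, sector class and the number of constituent vectors.
    ``normalize_vectors=True`` switches to unit-length per-comparison vectors
    before summation (consistency-only mode; the default raw mode preserves
    fold-change magnitude).
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    spec = make_vector_spec(ss, tissue, name)
    genes = list(genes)
    if not genes:
        return pd.DataFrame(columns=list(VECTOR_COLUMNS))
    X, sizes = _analysis_matrix(em, spec, genes)
    vx, vy, mag = _block_vsums(X, sizes, normalize_vectors)
    p = vector_permutation_p(
        em, spec, genes, config.n_permutations_vector, rng, normalize_vectors,
        null_scheme=config.vector_null,
    ).to_numpy()
    n_vectors = (sizes[0] * sizes[1]) * (sizes[2] * sizes[3])
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "vsum_x": vx,
            "vsum_y": vy,
            "vsum_mag": mag,
            "p_value": p,
            "cls": _classify_arrays(vx, vy, mag, p, config),
            "n_vectors": n_vectors,
        },
        columns=list(VECTOR_COLUMNS),
    )
    return out
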