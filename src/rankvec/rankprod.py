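"""Rank product differential expression with permutation-based pfp.

For a two-class contrast with n1 and n2 samples, every single-origin pairwise
difference (class1 sample minus class2 sample, log2 scale) forms one of
K = n1 * n2 comparison columns.  Within each column genes are ranked with
rank 1 the most extreme in the requested direction (largest difference for
"up", smallest for "down"), and the rank product of a gene is the geometric
mean of its K ranks.  Significance comes from randomisations in which every
column independently receives a uniform random permutation of the ranks
1..G: the e-value of a gene is the expected number of null genes with a rank
product at least as small, and pfp (percentage of false positives, an FDR
estimate) is e-value divided by the gene's rank position.

The six factorial contrasts of the 2x2 design are run in a fixed order:
BC_vs_CC, CB_vs_CC, BB_vs_CC, CB_vs_BC, BB_vs_BC, BB_vs_CB.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import DesignError, RunConfig, SampleSheet

DIRECTIONS = ("up", "down")
#: (class1, class2) pairs in reporting order
CONTRAST_ORDER = (
    ("BC", "CC"),
    ("CB", "CC"),
    ("BB", "CC"),
    ("CB", "BC"),
    ("BB", "BC"),
    ("BB", "CB"),
)

RESULT_COLUMNS = ("gene_id", "direction", "rp", "e_value", "pfp", "mean_log2fc", "rank_position")


@dataclass(frozen=True)
class ContrastSpec:
    """A two-class comparison; class1 is the '1st class' of the summary table."""

    name: str
    class1_samples: tuple[str, ...]
    class2_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        c1, c2 = tuple(self.class1_samples), tuple(self.class2_samples)
        if not c1 or not c2:
            raise DesignError(f"contrast {self.name!r}: both classes must be non-empty")
        if set(c1) & set(c2):
            raise DesignError(f"contrast {self.name!r}: classes overlap")
        object.__setattr__(self, "class1_samples", c1)
        object.__setattr__(self, "class2_samples", c2)

    @property
    def n_comparisons(self) -> int:
        return len(self.class1_samples) * len(self.class2_samples)

    def swapped(self) -> "ContrastSpec":
        g2, _, g1 = self.name.partition("_vs_")
        return ContrastSpec(f"{g1}_vs_{g2}", self.class2_samples, self.class1_samples)


def make_contrast(ss: SampleSheet, tissue: str, group1: str, group2: str) -> ContrastSpec:
    c1 = ss.samples_in(tissue, group1)
    c2 = ss.samples_in(tissue, group2)
    for group, samples in ((group1, c1), (group2, c2)):
        if not samples:
            raise DesignError(
                f"group {group!r} absent from tissue {tissue!r}; cannot form "
                f"contrast {group1}_vs_{group2}"
            )
    return ContrastSpec(f"{group1}_vs_{group2}", tuple(c1), tuple(c2))


def six_contrast_specs(ss: SampleSheet, tissue: str) -> list[ContrastSpec]:
    return [make_contrast(ss, tissue, g1, g2) for g1, g2 in CONTRAST_ORDER]


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def pairwise_log_ratios(em: pd.DataFrame, spec: ContrastSpec) -> pd.DataFrame:
    """All K = n1*n2 single-origin differences, class1-major column order."""
    for sid in (*spec.class1_samples, *spec.class2_samples):
        if sid not in em.columns:
            raise DesignError(f"sample {sid!r} missing from expression matrix")
    cols = {}
    for s1 in spec.class1_samples:
        for s2 in spec.class2_samples:
            cols[f"{s1}-{s2}"] = em[s1] - em[s2]
    return pd.DataFrame(cols, index=em.index)


def _column_ranks(values: np.ndarray, direction: str) -> np.ndarray:
    """Ranks 1..G per column; rank 1 most extreme in ``direction``.

    Ties break deterministically to the lower-index gene (stable sort).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    key = -values if direction == "up" else values
    G = values.shape[0]
    ranks = np.empty(values.shape, dtype=np.float64)
    seq = np.arange(1, G + 1, dtype=np.float64)
    for k in range(values.shape[1]):
        order = np.argsort(key[:, k], kind="stable")
        ranks[order, k] = seq
    return ranks


def _rp_from_ranks(ranks: np.ndarray, axis: int = -1) -> np.ndarray:
    """Geometric mean of ranks along ``axis``.

    Uses the plain product for exactness whenever it cannot overflow, and a
    log-space fallback otherwise; both paths agree to 1 ulp on small inputs.
    """
    K = ranks.shape[axis]
    max_rank = float(np.max(ranks)) if ranks.size else 1.0
    if K * math.log10(max(max_rank, 2.0)) < 250:
        return np.prod(ranks, axis=axis) ** (1.0 / K)
    return np.exp(np.log(ranks).sum(axis=axis) / K)


def rank_product_statistic(ratios: pd.DataFrame, direction: str) -> pd.Series:
    """Per-gene rank product (geometric mean of within-column ranks)."""
    if ratios.shape[0] < 2:
        raise ValueError("rank products need at least 2 genes")
    ranks = _column_ranks(ratios.to_numpy(dtype=float), direction)
    return pd.Series(_rp_from_ranks(ranks, axis=1), index=ratios.index, name="rp")


def null_rank_products(
    n_genes: int, n_cols: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted null rank products from B randomisations.

    Each randomisation assigns every comparison column an independent uniform
    permutation of the ranks 1..G, exactly the null the observed statistic is
    compared against.  Returns B * G values, ascending.
    """
    G, K, B = n_genes, n_cols, n_permutations
    out = np.empty(B * G, dtype=np.float64)
    base = np.arange(1.0, G + 1.0)
    rows_per_chunk = max(1, int(4e6 // max(G, 1)))  # bound working memory
    chunk = max(1, rows_per_chunk // K)
    pos = 0
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        mat = np.tile(base, (b * K, 1))
        rng.permuted(mat, axis=1, out=mat)
        rp = _rp_from_ranks(mat.reshape(b, K, G), axis=1)
        out[pos : pos + b * G] = rp.ravel()
        pos += b * G
    out.sort()
    return out


def _rank_positions(rp: np.ndarray) -> np.ndarray:
    """1..G positions by ascending rp; ties to the lower gene index."""
    order = np.lexsort((np.arange(rp.size), rp))
    positions = np.empty(rp.size, dtype=np.int64)
    positions[order] = np.arange(1, rp.size + 1)
    return positions


def _pfp_table(values: np.ndarray, e_value: np.ndarray, index) -> pd.DataFrame:
    """Assemble rp/e_value/pfp/rank_position with the monotone pfp correction.

    pfp = e_value / rank_position made non-decreasing in rank order by a
    running maximum, so a pfp threshold yields a coherent call set.
    """
    positions = _rank_positions(values)
    pfp_raw = e_value / positions
    order = np.argsort(positions)
    pfp = np.empty_like(pfp_raw)
    pfp[order] = np.maximum.accumulate(pfp_raw[order])
    return pd.DataFrame(
        {
            "rp": values,
            "e_value": e_value,
            "pfp": pfp,
            "rank_position": positions,
        },
        index=index,
    )


def permutation_pfp(
    ratios: pd.DataFrame,
    direction: str,
    n_permutations: int,
    rng: np.random.Generator | int | None = None,
    null_sorted: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene rp, e-value and monotone pfp under the rank-assignment null.

    e_value = (#null gene instances with rp <= observed rp) / B, with the
    null built by independent uniform rank permutations per column (see
    :func:`null_rank_products`); pfp = e_value / rank_position with the
    running-maximum correction.  ``null_sorted`` lets callers share one null
    sample across directions and same-shape contrasts (this null depends
    only on G, K and B).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rp = rank_product_statistic(ratios, direction)
    values = rp.to_numpy()
    if null_sorted is None:
        null_sorted = null_rank_products(
            ratios.shape[0], ratios.shape[1], n_permutations, rng
        )
    e_value = np.searchsorted(null_sorted, values, side="right") / n_permutations
    return _pfp_table(values, e_value, ratios.index)


def expression_permutation_evalues(
    em: pd.DataFrame,
    spec: ContrastSpec,
    rp_up: np.ndarray,
    rp_down: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """e-values under the within-sample expression-permutation null.

    Gene labels are permuted independently within every sample column and the
    rank products recomputed, which preserves the dependence between pairwise
    comparison columns sharing a sample (the property that makes this null
    calibrated where the independent rank-assignment null is not).  The two
    classes are processed in a canonical order so that swapping class1 and
    class2 mirrors the up/down e-values exactly.
    """
    from ._kernels import expression_null_evalues

    flip = tuple(spec.class1_samples) > tuple(spec.class2_samples)
    c1, c2 = (
        (spec.class2_samples, spec.class1_samples)
        if flip
        else (spec.class1_samples, spec.class2_samples)
    )
    block1 = em.loc[:, list(c1)].to_numpy(dtype=float)
    block2 = em.loc[:, list(c2)].to_numpy(dtype=float)
    obs_up, obs_down = (rp_down, rp_up) if flip else (rp_up, rp_down)
    seed = int(rng.integers(2**31))
    e_up, e_down = expression_null_evalues(
        block1, block2, obs_up, obs_down, n_permutations, seed
    )
    return (e_down, e_up) if flip else (e_up, e_down)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """Up and down result tables (one row per gene) plus the significant calls.

    ``up``/``down`` carry gene_id, direction, rp, e_value, pfp, mean_log2fc
    and rank_position, ordered by rank position.  ``significant`` is the
    disjoint union of the two directions' calls at pfp <= fdr_threshold: a
    gene significant in both directions is kept in the direction with the
    smaller pfp (ties to "up").
    """

    contrast: ContrastSpec
    up: pd.DataFrame
    down: pd.DataFrame
    significant: pd.DataFrame

    @property
    def n_up(self) -> int:
        return int((self.significant["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.significant["direction"] == "down").sum())


def _direction_table(
    stats: pd.DataFrame, direction: str, mean_log2fc: pd.Series
) -> pd.DataFrame:
    df = stats.copy()
    df.insert(0, "gene_id", df.index.astype(str))
    df.insert(1, "direction", direction)
    df["mean_log2fc"] = mean_log2fc
    df = df.loc[:, list(RESULT_COLUMNS)]
    return df.sort_values("rank_position", kind="stable").reset_index(drop=True)


def run_contrast(
    em: pd.DataFrame,
    spec: ContrastSpec,
    config: RunConfig | None = None,
    rng: np.random.Generator | int | None = None,
    null_sorted: np.ndarray | None = None,
) -> ContrastResult:
    """Two one-sided rank product analyses of one contrast, sharing one null.

    The null model follows ``config.rp_null``; ``null_sorted`` (a presorted
    rank-assignment null) is only consulted in "ranks" mode.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    ratios = pairwise_log_ratios(em, spec)
    rp = {
        d: rank_product_statistic(ratios, d).to_numpy() for d in DIRECTIONS
    }
    if config.rp_null == "expression":
        e_up, e_down = expression_permutation_evalues(
            em, spec, rp["up"], rp["down"], config.n_permutations_rp, rng
        )
        e_values = {"up": e_up, "down": e_down}
    else:
        if null_sorted is None:
            null_sorted = null_rank_products(
                ratios.shape[0], ratios.shape[1], config.n_permutations_rp, rng
            )
        e_values = {
            d: np.searchsorted(null_sorted, rp[d], side="right")
            / config.n_permutations_rp
            for d in DIRECTIONS
        }
    mean_log2fc = ratios.mean(axis=1)
    tables = {}
    for direction in DIRECTIONS:
        stats = _pfp_table(rp[direction], e_values[direction], ratios.index)
        tables[direction] = _direction_table(stats, direction, mean_log2fc)
    significant = _resolve_significant(tables, config.fdr_threshold)
    return ContrastResult(
        contrast=spec, up=tables["up"], down=tables["down"], significant=significant
    )


def _resolve_significant(
    tables: Mapping[str, pd.DataFrame], fdr_threshold: float
) -> pd.DataFrame:
    calls = pd.concat(
        [t[t["pfp"] <= fdr_threshold] for t in tables.values()], ignore_index=True
    )
    if calls.empty:
        return calls.reindex(columns=list(RESULT_COLUMNS))
    # at most one direction per gene: smaller pfp wins, ties go to "up"
    calls["_dir_order"] = (calls["direction"] == "down").astype(int)
    calls = calls.sort_values(["pfp", "_dir_order"], kind="stable")
    calls = calls.drop_duplicates("gene_id", keep="first").drop(columns="_dir_order")
    return calls.sort_values(["direction", "rank_position"], kind="stable").reset_index(
        drop=True
    )


def linear_fold_changes(normalized: pd.DataFrame, spec: ContrastSpec) -> pd.Series:
    """Signed linear ratio of normalized class means (class1 over class2).

    Reported alongside the log-scale mean_log2fc; computed on the normalized
    (pre-log, no additive offset) scale.  Ratios below 1 are reported as
    negative reciprocals (0.5 -> -2), the usual signed fold-change convention;
    a zero class2 mean with nonzero class1 mean gives +inf.
    """
    m1 = normalized.loc[:, list(spec.class1_samples)].mean(axis=1)
    m2 = normalized.loc[:, list(spec.class2_samples)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m1 / m2
    ratio = ratio.where(~(m1.eq(0) & m2.eq(0)), 1.0)
    signed = ratio.where(ratio >= 1, -1.0 / ratio)
    signed.name = "linear_fc"
    return signed


@dataclass(frozen=True)
class SixContrastResults:
    """Results of the six factorial contrasts of one tissue, in fixed order."""

    tissue: str
    results: Mapping[str, ContrastResult]
    summary: pd.DataFrame  # columns: contrast, n_up, n_down

    def __iter__(self):
        return iter(self.results.values())


def six_contrasts(
    em: pd.DataFrame,
    ss: SampleSheet,
    tissue: str,
    config: RunConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SixContrastResults:
    """Run all six pairwise contrasts of one tissue.

    In "ranks" null mode the sorted null sample is generated once per
    distinct (G, K) shape and shared across contrasts and directions (it
    depends on nothing else); the default "expression" null is data-driven
    and computed per contrast.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    missing = [g for g in ("CC", "BC", "CB", "BB")
               if not ss.for_tissue(tissue).samples_in(tissue, g)]
    if missing:
        raise DesignError(
            f"tissue {tissue!r} is missing group(s) {missing}; all four groups "
            "are required for the six contrasts"
        )
    null_cache: dict[tuple[int, int], np.ndarray] = {}
    results: dict[str, ContrastResult] = {}
    rows = []
    G = em.shape[0]
    for g1, g2 in CONTRAST_ORDER:
        spec = make_contrast(ss, tissue, g1, g2)
        key = (G, spec.n_comparisons)
        if config.rp_null == "ranks" and key not in null_cache:
            null_cache[key] = null_rank_products(
                G, spec.n_comparisons, config.n_permutations_rp, rng
            )
        res = run_contrast(em, spec, config, rng, null_sorted=null_cache.get(key))
        results[spec.name] = res
        rows.append({"contrast": spec.name, "n_up": res.n_up, "n_down": res.n_down})
    summary = pd.DataFrame(rows, columns=["contrast", "n_up", "n_down"])
    return SixContrastResults(tissue=tissue, results=results, summary=summary)
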