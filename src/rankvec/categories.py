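"""Factorial behavioural categories from the paired vector analyses.

Each universe gene carries a sector class from the post-natal-response
analysis and one from the pre-natal-response analysis; their combination
determines the behavioural category:

* I   common non-additive response: a single exposure suffices and the
      already-exposed background shows no further shift, so each analysis
      sees a response only in the carrier-only environment
      (only0_s in both analyses);
* II  cumulative response: all four single-exposure fold changes share one
      sign (both_s in both analyses);
* III pre-natal-specific: no post-natal response in either background,
      consistent pre-natal response in both (unchanged, both_s);
* IV  post-natal-specific: the mirror image (both_s, unchanged);
* every other combination (mixed signs, opposite_* or only1_* labels,
  double unchanged) maps to "none".

The combination table is data, not control flow: it can be replaced or
extended (e.g. from a TSV) without touching code.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io_model import DesignError
from .vector_analysis import ClassLabel

CATEGORY_LEVELS = ("I", "II", "III", "IV", "none")
NOT_IN_UNIVERSE = "not_in_universe"

#: (class in postnatal_response, class in prenatal_response) -> (category, sign)
DEFAULT_CATEGORY_RULES: dict[tuple[str, str], tuple[str, str]] = {
    ("only0_up", "only0_up"): ("I", "up"),
    ("only0_down", "only0_down"): ("I", "down"),
    ("both_up", "both_up"): ("II", "up"),
    ("both_down", "both_down"): ("II", "down"),
    ("unchanged", "both_up"): ("III", "up"),
    ("unchanged", "both_down"): ("III", "down"),
    ("both_up", "unchanged"): ("IV", "up"),
    ("both_down", "unchanged"): ("IV", "down"),
}

_VALID_LABELS = {label.value for label in ClassLabel}

ASSIGNMENT_COLUMNS = (
    "gene_id",
    "tissue",
    "category",
    "sign",
    "class_postnatal",
    "class_prenatal",
)


def assign_category(
    cls_post: str | ClassLabel,
    cls_pre: str | ClassLabel,
    rules: Mapping[tuple[str, str], tuple[str, str]] | None = None,
) -> tuple[str, str]:
    """Map a (postnatal-analysis, prenatal-analysis) class pair to (category, sign).

    Total and deterministic: any pair not in the rule table is ("none", "n/a").
    Unknown class labels are a hard error.
    """
    post = cls_post.value if isinstance(cls_post, ClassLabel) else str(cls_post)
    pre = cls_pre.value if isinstance(cls_pre, ClassLabel) else str(cls_pre)
    for label in (post, pre):
        if label not in _VALID_LABELS:
            raise ValueError(f"unknown class label {label!r}")
    table = DEFAULT_CATEGORY_RULES if rules is None else rules
    return table.get((post, pre), ("none", "n/a"))


def load_category_rules(path) -> dict[tuple[str, str], tuple[str, str]]:
    """Read a rule table TSV (class_postnatal, class_prenatal, category, sign)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"class_postnatal", "class_prenatal", "category", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rule table missing columns: {sorted(missing)}")
    rules = {}
    for row in df.itertuples(index=False):
        if row.category not in CATEGORY_LEVELS:
            raise ValueError(f"unknown category {row.category!r} in rule table")
        rules[(row.class_postnatal, row.class_prenatal)] = (row.category, row.sign)
    return rules


def save_category_rules(
    rules: Mapping[tuple[str, str], tuple[str, str]], path
) -> None:
    rows = [
        {
            "class_postnatal": post,
            "class_prenatal": pre,
            "category": cat,
            "sign": sign,
        }
        for (post, pre), (cat, sign) in rules.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def categorize_tissue(
    vector_results_post: pd.DataFrame,
    vector_results_pre: pd.DataFrame,
    tissue: str,
    rules: Mapping[tuple[str, str], tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every universe gene a behavioural category; count per category.

    Both vector-analysis tables must cover the same gene universe.  Returns
    (assignments, summary); the summary has one row per category I..IV with
    total, up and down gene counts.
    """
    post_genes = set(vector_results_post["gene_id"])
    pre_genes = set(vector_results_pre["gene_id"])
    if post_genes != pre_genes:
        raise DesignError(
            "the two vector analyses cover different gene universes; "
            f"symmetric difference size {len(post_genes ^ pre_genes)}"
        )
    post = vector_results_post.set_index("gene_id")["cls"]
    pre = vector_results_pre.set_index("gene_id")["cls"]
    rows = []
    for gene in sorted(post_genes):
        category, sign = assign_category(post[gene], pre[gene], rules)
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "category": category,
                "sign": sign,
                "class_postnatal": post[gene],
                "class_prenatal": pre[gene],
            }
        )
    assignments = pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS))
    summary_rows = []
    for category in ("I", "II", "III", "IV"):
        sub = assignments[assignments["category"] == category]
        summary_rows.append(
            {
                "category": category,
                "n_genes": len(sub),
                "n_up": int((sub["sign"] == "up").sum()),
                "n_down": int((sub["sign"] == "down").sum()),
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["category", "n_genes", "n_up", "n_down"])
    return assignments, summary


def truth_confusion(
    assignments: pd.DataFrame,
    truth: pd.DataFrame,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Planted-versus-assigned confusion matrix for a synthetic run.

    Rows are planted categories (I..IV plus implicit "none"), columns the
    assigned categories plus "not_in_universe" for planted genes that never
    entered the vector-analysis universe.  Row sums equal planted counts.
    ``gene_ids`` is the full simulated gene list; without it the "none" row
    covers only genes seen in the assignments or truth tables.
    """
    planted = dict(zip(truth["gene_id"], truth["category"]))
    assigned = dict(zip(assignments["gene_id"], assignments["category"]))
    if gene_ids is None:
        universe = set(planted) | set(assigned)
    else:
        universe = set(gene_ids)
        stray = (set(planted) | set(assigned)) - universe
        if stray:
            raise ValueError(f"genes outside the provided gene list: {sorted(stray)[:5]}")
    columns = [*CATEGORY_LEVELS, NOT_IN_UNIVERSE]
    matrix = pd.DataFrame(0, index=list(CATEGORY_LEVELS), columns=columns, dtype=int)
    matrix.index.name = "planted"
    for gene in universe:
        row = planted.get(gene, "none")
        col = assigned.get(gene, NOT_IN_UNIVERSE)
        matrix.loc[row, col] += 1
    return matrix
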