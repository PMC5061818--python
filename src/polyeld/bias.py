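"""Homoeolog expression bias and parental legacy.

For each homoeologous A/C gene pair two three-valued signs are computed: the
*parental* sign (A copy in the A parent vs C copy in the C parent) and the
*hybrid* sign (A copy vs C copy within one hybrid library).  Counts are put
on a common length scale first — each copy's count is rescaled to the pair's
mean gene length — because the two comparisons cross gene models of
different lengths.  The sign pair maps onto nine categories:

====================  ===========  ===========
category              parent sign  hybrid sign
====================  ===========  ===========
parental_equal        0            0
maintained_A_bias     ``+``        ``+``
maintained_C_bias     ``-``        ``-``
lost_A_bias           ``+``        0
lost_C_bias           ``-``        0
novel_A_bias          0            ``+``
novel_C_bias          0            ``-``
reversed_to_C         ``+``        ``-``
reversed_to_A         ``-``        ``+``
====================  ===========  ===========

Overall A-bias in the hybrid is the number of pairs with hybrid sign ``+``
(maintained + novel + reversed-to-A), and likewise for C; a chi-square
goodness-of-fit against a 1:1 split tests subgenome balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountTable, GeneModel, round_half_up, validate_pairs
from .diffexpr import bh_adjust, fisher_exact_two_sided, _fet_vector

__all__ = [
    "BIAS_CATEGORIES",
    "classify_pair",
    "legacy_of",
    "homoeolog_contrast",
    "pair_signs",
    "classify_pairs",
    "summarize_bias",
]

#: (parent_sign, hybrid_sign) -> category name
BIAS_CATEGORIES: dict[tuple[int, int], str] = {
    (0, 0): "parental_equal",
    (1, 1): "maintained_A_bias",
    (-1, -1): "maintained_C_bias",
    (1, 0): "lost_A_bias",
    (-1, 0): "lost_C_bias",
    (0, 1): "novel_A_bias",
    (0, -1): "novel_C_bias",
    (1, -1): "reversed_to_C",
    (-1, 1): "reversed_to_A",
}

CATEGORY_ORDER = [
    "parental_equal",
    "maintained_A_bias",
    "maintained_C_bias",
    "lost_A_bias",
    "lost_C_bias",
    "novel_A_bias",
    "novel_C_bias",
    "reversed_to_A",
    "reversed_to_C",
]

_LEGACY = {
    "parental_equal": "none",
    "maintained_A_bias": "maintained",
    "maintained_C_bias": "maintained",
    "lost_A_bias": "lost",
    "lost_C_bias": "lost",
    "novel_A_bias": "novel",
    "novel_C_bias": "novel",
    "reversed_to_A": "reversed",
    "reversed_to_C": "reversed",
}


def classify_pair(parent_sign, hybrid_sign) -> str:
    """Nine-way category from the parental and within-hybrid bias signs."""
    from .containers import as_sign

    return BIAS_CATEGORIES[(as_sign(parent_sign), as_sign(hybrid_sign))]


def legacy_of(category: str) -> str:
    return _LEGACY[category]


def _length_adjust(count, length, mean_length):
    """Rescale a copy's count to the pair's mean gene length (half-up)."""
    return round_half_up(np.asarray(count, dtype=float)
                         * np.asarray(mean_length, dtype=float)
                         / np.asarray(length, dtype=float))


def homoeolog_contrast(
    count_a, len_a, lib_a, count_c, len_c, lib_c, alpha: float = 0.05
) -> int:
    """Bias sign for a single homoeolog pair (no multiplicity correction).

    Length-adjusts each copy to the pair's mean length, then applies the
    two-sided FET against the two library totals.  Within a genome-wide
    comparison use :func:`pair_signs`, which BH-adjusts across all pairs of
    the family.  A pair with both copies at zero gets sign 0.
    """
    if min(len_a, len_c) <= 0 or min(lib_a, lib_c) <= 0:
        raise ValueError("lengths and library sizes must be positive")
    mean_len = (len_a + len_c) / 2.0
    ca = int(_length_adjust(count_a, len_a, mean_len))
    cc = int(_length_adjust(count_c, len_c, mean_len))
    if ca == 0 and cc == 0:
        return 0
    p = fisher_exact_two_sided(ca, int(round_half_up(lib_a)),
                               cc, int(round_half_up(lib_c)))
    if p >= alpha:
        return 0
    return int(np.sign(ca / lib_a - cc / lib_c))


def pair_signs(
    counts_a: np.ndarray,
    lens_a: np.ndarray,
    lib_a: float,
    counts_c: np.ndarray,
    lens_c: np.ndarray,
    lib_c: float,
    alpha: float = 0.05,
) -> np.ndarray:
    """Vectorized pair bias signs with BH adjustment across the family."""
    mean_len = (np.asarray(lens_a, float) + np.asarray(lens_c, float)) / 2.0
    ca = _length_adjust(counts_a, lens_a, mean_len)
    cc = _length_adjust(counts_c, lens_c, mean_len)
    na, nc = int(round_half_up(lib_a)), int(round_half_up(lib_c))
    p = _fet_vector(ca, na, cc, nc)
    q = bh_adjust(p)
    diff = ca / na - cc / nc
    return np.where(q < alpha, np.sign(diff).astype(int), 0)


def _pair_frame(genes: list[GeneModel]) -> pd.DataFrame:
    pairs = validate_pairs(genes)
    if not pairs:
        raise ValueError("annotation carries no homoeolog pairs")
    lengths = {g.gene_id: g.length for g in genes}
    return pd.DataFrame(
        {
            "a_gene_id": [a for a, _ in pairs],
            "c_gene_id": [c for _, c in pairs],
            "len_a": [lengths[a] for a, _ in pairs],
            "len_c": [lengths[c] for _, c in pairs],
        }
    )


def classify_pairs(
    counts: CountTable,
    genes: list[GeneModel],
    a_sample: str,
    c_sample: str,
    h_sample: str,
    alpha: float = 0.05,
    universe: str = "either",
) -> pd.DataFrame:
    """Classify every homoeolog pair of one parent/parent/hybrid contrast.

    The pair universe keeps pairs whose two copies are both expressed:
    with ``universe='either'`` each copy must be expressed in at least one
    sample of the contrast (its own parent or the hybrid); with
    ``'all-samples'`` each copy must be expressed both in its parent and in
    the hybrid.  The parental comparison uses each parent's own library
    size; the within-hybrid comparison uses the hybrid library total on
    both margins (both copies come from the same sequencing library).
    BH correction is applied per comparison family across the retained
    pairs.
    """
    if universe not in ("either", "all-samples"):
        raise ValueError("universe must be 'either' or 'all-samples'")
    pf = _pair_frame(genes)
    missing = set(pf["a_gene_id"]).union(pf["c_gene_id"]) - set(counts.gene_ids)
    if missing:
        raise ValueError(f"{len(missing)} paired genes absent from count table")

    pa = counts.pooled(a_sample)
    pc = counts.pooled(c_sample)
    ph = counts.pooled(h_sample)
    a_parent = pa.loc[pf["a_gene_id"]].values
    c_parent = pc.loc[pf["c_gene_id"]].values
    a_hyb = ph.loc[pf["a_gene_id"]].values
    c_hyb = ph.loc[pf["c_gene_id"]].values

    if universe == "either":
        keep = ((a_parent > 0) | (a_hyb > 0)) & ((c_parent > 0) | (c_hyb > 0))
    else:
        keep = (a_parent > 0) & (a_hyb > 0) & (c_parent > 0) & (c_hyb > 0)
    pf = pf.loc[keep].reset_index(drop=True)
    if len(pf) == 0:
        raise ValueError("no homoeolog pair survives the expression filter")
    a_parent, c_parent = a_parent[keep], c_parent[keep]
    a_hyb, c_hyb = a_hyb[keep], c_hyb[keep]

    lib_a = counts.library_size(a_sample)
    lib_c = counts.library_size(c_sample)
    lib_h = counts.library_size(h_sample)
    parent = pair_signs(a_parent, pf["len_a"].values, lib_a,
                        c_parent, pf["len_c"].values, lib_c, alpha)
    hybrid = pair_signs(a_hyb, pf["len_a"].values, lib_h,
                        c_hyb, pf["len_c"].values, lib_h, alpha)
    pf["parent_sign"] = parent
    pf["hybrid_sign"] = hybrid
    pf["category"] = [BIAS_CATEGORIES[t] for t in zip(parent, hybrid)]
    pf["legacy"] = [_LEGACY[c] for c in pf["category"]]
    return pf.set_index("a_gene_id")


def summarize_bias(
    pair_calls: pd.DataFrame, other_hybrid_calls: pd.DataFrame | None = None
) -> dict:
    """Category counts, percentages, overall A/C bias and the balance test.

    Percentages use the total number of pairs in the contrast as the
    denominator.  When a second hybrid's calls are supplied, a shared
    column counts pairs present in both contrasts with the same category.
    """
    from .report import percent

    if len(pair_calls) == 0:
        raise ValueError("empty pair-call set")
    total = len(pair_calls)
    counts = {cat: int((pair_calls["category"] == cat).sum())
              for cat in CATEGORY_ORDER}
    pct = {cat: percent(n, total) for cat, n in counts.items()}
    a_bias = int((pair_calls["hybrid_sign"] == 1).sum())
    c_bias = int((pair_calls["hybrid_sign"] == -1).sum())
    if a_bias + c_bias > 0:
        chi2, chi_p = stats.chisquare([a_bias, c_bias])
        chi2, chi_p = float(chi2), float(chi_p)
    else:
        chi2, chi_p = 0.0, 1.0
    out = {
        "total_pairs": total,
        "category_counts": counts,
        "category_percent": pct,
        "overall_A_bias": a_bias,
        "overall_C_bias": c_bias,
        "overall_A_bias_percent": percent(a_bias, total),
        "overall_C_bias_percent": percent(c_bias, total),
        "balance_chi2": chi2,
        "balance_p": chi_p,
    }
    if other_hybrid_calls is not None:
        shared = pair_calls.index.intersection(other_hybrid_calls.index)
        same = pair_calls.loc[shared, "category"] == \
            other_hybrid_calls.loc[shared, "category"]
        out["shared_pairs"] = int(len(shared))
        out["shared_same_category"] = {
            cat: int(((pair_calls.loc[shared, "category"] == cat) & same).sum())
            for cat in CATEGORY_ORDER
        }
    return out
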