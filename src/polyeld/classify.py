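"""Expression-pattern taxonomy for a parent/parent/hybrid trio.

Each gene gets three pairwise significance signs — hybrid vs A parent
(``s_ha``), hybrid vs C parent (``s_hc``), A parent vs C parent (``s_pc``) —
read off confidence-interval logic: a directed sign means the two expression
confidence intervals are disjoint in that order, 0 means they overlap.  Of
the 27 conceivable sign triples only 19 are realizable by three real
intervals; these are the 19 expression patterns (roman numerals I-XIX).  A
fourth sign, hybrid vs the in-silico mid-parent value (``s_h_mpv``), crossed
with ``s_pc`` yields the 9 major categories (letters a-i).

Pattern groups:

* equal to both parents: VII, XI, XVII
* equal to one parent, parents equal: III, IV, V, VI
* expression-level dominance (equal to one parent, parents differ):
  XII (A-dominant, up), XIX (A-dominant, down),
  XVIII (C-dominant, up), XIII (C-dominant, down)
* intermediate between the parents: VIII, XIV
* transgressive up: I, IX, XV; transgressive down: II, X, XVI

Within each group the roman numeral follows the canonical order
``s_pc = +, 0, -`` (a documented convention; only the groupings and the four
dominance numerals are pinned by the taxonomy itself).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountTable, as_sign, sign_symbol
from .diffexpr import contrast_signs, mpv_pseudo_sample

__all__ = [
    "PATTERN_TABLE",
    "ELD_FORM",
    "TRANSGRESSIVE",
    "admissible_triples",
    "interval_admissible_triples",
    "assign_pattern",
    "assign_category",
    "eld_form_of",
    "transgressive_of",
    "classify_all",
    "cross_compare",
]

#: (s_ha, s_hc, s_pc) -> roman numeral, for the 19 admissible triples.
PATTERN_TABLE: dict[tuple[int, int, int], str] = {
    # hybrid equal to both parents
    (0, 0, 1): "VII", (0, 0, 0): "XI", (0, 0, -1): "XVII",
    # equal to one parent, parents equal
    (1, 0, 0): "III", (0, 1, 0): "IV", (-1, 0, 0): "V", (0, -1, 0): "VI",
    # expression level dominance (equal to one parent, parents differ)
    (0, 1, 1): "XII", (-1, 0, 1): "XIII", (1, 0, -1): "XVIII", (0, -1, -1): "XIX",
    # intermediate between the two parents
    (1, -1, -1): "VIII", (-1, 1, 1): "XIV",
    # transgressive up / down
    (1, 1, 1): "I", (1, 1, 0): "IX", (1, 1, -1): "XV",
    (-1, -1, 1): "II", (-1, -1, 0): "X", (-1, -1, -1): "XVI",
}

#: dominance form per pattern: which parent is mimicked, and the direction
#: of the hybrid relative to the *other* parent.
ELD_FORM = {"XII": "A_up", "XIX": "A_down", "XVIII": "C_up", "XIII": "C_down"}

TRANSGRESSIVE = {"I": "up", "IX": "up", "XV": "up",
                 "II": "down", "X": "down", "XVI": "down"}

EQUAL_BOTH = ("VII", "XI", "XVII")
EQUAL_ONE = ("III", "IV", "V", "VI", "XII", "XIII", "XVIII", "XIX")

#: category grid: (s_h_mpv, s_pc) -> letter.  Rows by the hybrid-vs-MPV sign
#: (0 = additive, + = above, - = below), columns by the parental sign.
CATEGORY_GRID = {
    (0, 0): "a", (0, 1): "b", (0, -1): "c",
    (1, 0): "d", (1, 1): "e", (1, -1): "f",
    (-1, 0): "g", (-1, 1): "h", (-1, -1): "i",
}


def admissible_triples() -> set[tuple[int, int, int]]:
    """The 19 sign triples (s_ha, s_hc, s_pc) realizable by three intervals."""
    return set(PATTERN_TABLE)


def interval_admissible_triples(n_grid: int = 8) -> set[tuple[int, int, int]]:
    """Brute-force the admissible triples from interval satisfiability.

    Enumerates all triples of closed intervals with endpoints on a small
    integer grid; for intervals X, Y the comparison sign is + when X lies
    entirely above Y, - when entirely below, 0 when they overlap.  Every
    realizable sign triple is realizable on a coarse grid (only the ordering
    of endpoints matters), so the returned set is exact.
    """
    intervals = [(lo, hi) for lo, hi in
                 itertools.combinations(range(n_grid), 2)]

    def cmp(x, y):
        if x[0] > y[1]:
            return 1
        if x[1] < y[0]:
            return -1
        return 0

    found: set[tuple[int, int, int]] = set()
    for a in intervals:
        for c in intervals:
            s_pc = cmp(a, c)
            for h in intervals:
                found.add((cmp(h, a), cmp(h, c), s_pc))
    return found


def assign_pattern(s_ha, s_hc, s_pc) -> str:
    """Roman numeral for one sign triple; 'INCONSISTENT' if not realizable."""
    key = (as_sign(s_ha), as_sign(s_hc), as_sign(s_pc))
    return PATTERN_TABLE.get(key, "INCONSISTENT")


def assign_category(s_h_mpv, s_pc) -> str:
    """Letter a-i from the hybrid-vs-MPV sign and the parental sign."""
    return CATEGORY_GRID[(as_sign(s_h_mpv), as_sign(s_pc))]


def eld_form_of(pattern: str) -> str:
    return ELD_FORM.get(pattern, "none")


def transgressive_of(pattern: str) -> str:
    return TRANSGRESSIVE.get(pattern, "none")


_ADDITIVE_LABEL = {0: "additive", 1: "up", -1: "down"}


@dataclass
class TrioSummary:
    """Count summary of one trio classification (see classify_all)."""

    n_classified: int
    pattern_counts: dict
    category_counts: dict
    eld_counts: dict
    eld_total: int
    a_dominance: int
    c_dominance: int
    transgressive_up: int
    transgressive_down: int
    additive: int
    non_additive_up: int
    non_additive_down: int
    dominance_balance_p: float
    transgressive_balance_p: float

    def as_dict(self) -> dict:
        return {
            "n_classified": self.n_classified,
            "pattern_counts": dict(self.pattern_counts),
            "category_counts": dict(self.category_counts),
            "eld_counts": dict(self.eld_counts),
            "eld_total": self.eld_total,
            "a_dominance": self.a_dominance,
            "c_dominance": self.c_dominance,
            "transgressive_up": self.transgressive_up,
            "transgressive_down": self.transgressive_down,
            "additive": self.additive,
            "non_additive_up": self.non_additive_up,
            "non_additive_down": self.non_additive_down,
            "dominance_balance_p": self.dominance_balance_p,
            "transgressive_balance_p": self.transgressive_balance_p,
        }


def _binom_balance(k1: int, k2: int) -> float:
    """Two-sided exact binomial test of k1 vs k2 against a 1:1 split."""
    n = k1 + k2
    if n == 0:
        return 1.0
    return float(stats.binomtest(k1, n, 0.5).pvalue)


def classify_all(
    counts: CountTable,
    a_sample: str,
    c_sample: str,
    h_sample: str,
    alpha: float = 0.05,
    require_all_expressed: bool = False,
) -> tuple[pd.DataFrame, TrioSummary]:
    """Classify every gene of an A-parent / C-parent / hybrid trio.

    Four comparison families are tested (parent vs parent, hybrid vs each
    parent, hybrid vs the MPV pseudo-sample), each BH-adjusted across the
    classified gene universe.  The universe is genes expressed (pooled count
    > 0) in at least one of the three samples, or in all three when
    ``require_all_expressed`` is set; genes expressed in a subset are
    classified on their actual counts, zeros included.

    Returns the per-gene assignment frame and a :class:`TrioSummary` with
    pattern/category/dominance/transgressive totals and two-sided exact
    binomial balance tests (A- vs C-dominance, transgressive up vs down).
    """
    for s in (a_sample, c_sample, h_sample):
        if s not in counts.samples:
            raise KeyError(f"sample {s!r} missing from count table")
    expr = pd.concat(
        [counts.expressed(s) for s in (a_sample, c_sample, h_sample)], axis=1
    )
    mask = expr.all(axis=1) if require_all_expressed else expr.any(axis=1)
    universe = counts.gene_ids[mask]
    if len(universe) == 0:
        raise ValueError("no gene expressed in any of the three samples")

    pooled = {s: counts.pooled(s).loc[universe]
              for s in (a_sample, c_sample, h_sample)}
    libs = {s: counts.library_size(s) for s in (a_sample, c_sample, h_sample)}
    mpv_counts, mpv_lib = mpv_pseudo_sample(counts, a_sample, c_sample)

    s_pc = contrast_signs(pooled[a_sample], libs[a_sample],
                          pooled[c_sample], libs[c_sample], alpha)["sign"]
    s_ha = contrast_signs(pooled[h_sample], libs[h_sample],
                          pooled[a_sample], libs[a_sample], alpha)["sign"]
    s_hc = contrast_signs(pooled[h_sample], libs[h_sample],
                          pooled[c_sample], libs[c_sample], alpha)["sign"]
    s_hm = contrast_signs(pooled[h_sample], libs[h_sample],
                          mpv_counts.loc[universe], mpv_lib, alpha)["sign"]

    patterns = [PATTERN_TABLE.get(t, "INCONSISTENT")
                for t in zip(s_ha.values, s_hc.values, s_pc.values)]
    categories = [CATEGORY_GRID[t] for t in zip(s_hm.values, s_pc.values)]
    frame = pd.DataFrame(
        {
            "s_pc": s_pc.values, "s_ha": s_ha.values, "s_hc": s_hc.values,
            "s_h_mpv": s_hm.values,
            "pattern": patterns,
            "category": categories,
            "eld_form": [ELD_FORM.get(p, "none") for p in patterns],
            "transgressive": [TRANSGRESSIVE.get(p, "none") for p in patterns],
            "additive_vs_mpv": [_ADDITIVE_LABEL[s] for s in s_hm.values],
        },
        index=universe,
    )

    pattern_counts = frame["pattern"].value_counts().to_dict()
    category_counts = frame["category"].value_counts().to_dict()
    eld_counts = {form: int((frame["eld_form"] == form).sum())
                  for form in ("A_up", "A_down", "C_up", "C_down")}
    a_dom = eld_counts["A_up"] + eld_counts["A_down"]
    c_dom = eld_counts["C_up"] + eld_counts["C_down"]
    tr_up = int((frame["transgressive"] == "up").sum())
    tr_down = int((frame["transgressive"] == "down").sum())
    summary = TrioSummary(
        n_classified=len(frame),
        pattern_counts=pattern_counts,
        category_counts=category_counts,
        eld_counts=eld_counts,
        eld_total=a_dom + c_dom,
        a_dominance=a_dom,
        c_dominance=c_dom,
        transgressive_up=tr_up,
        transgressive_down=tr_down,
        additive=int((frame["additive_vs_mpv"] == "additive").sum()),
        non_additive_up=int((frame["additive_vs_mpv"] == "up").sum()),
        non_additive_down=int((frame["additive_vs_mpv"] == "down").sum()),
        dominance_balance_p=_binom_balance(a_dom, c_dom),
        transgressive_balance_p=_binom_balance(tr_up, tr_down),
    )
    return frame, summary


def cross_compare(
    assignments_h1: pd.DataFrame, assignments_h2: pd.DataFrame
) -> dict:
    """Compare two hybrids' classifications over their shared gene universe.

    Builds the additive/up/down contingency (hybrid-vs-MPV state) and the
    dominance-form contingency, plus the same / changed / opposite-direction
    partition of the shared genes: *same* keeps the additive state, *opposite*
    flips non-additive direction (up in one hybrid, down in the other),
    *changed* is any other disagreement.
    """
    shared = assignments_h1.index.intersection(assignments_h2.index)
    if len(shared) == 0:
        raise ValueError("the two assignment sets share no genes")
    a1 = assignments_h1.loc[shared, "additive_vs_mpv"]
    a2 = assignments_h2.loc[shared, "additive_vs_mpv"]
    order = ["additive", "up", "down"]
    additive_tab = pd.crosstab(a1, a2).reindex(
        index=order, columns=order, fill_value=0
    )
    e1 = assignments_h1.loc[shared, "eld_form"]
    e2 = assignments_h2.loc[shared, "eld_form"]
    forms = ["A_up", "A_down", "C_up", "C_down", "none"]
    eld_tab = pd.crosstab(e1, e2).reindex(index=forms, columns=forms,
                                          fill_value=0)
    same = int((a1.values == a2.values).sum())
    opposite = int((((a1 == "up") & (a2 == "down"))
                    | ((a1 == "down") & (a2 == "up"))).sum())
    changed = len(shared) - same - opposite
    return {
        "n_shared": len(shared),
        "same": same,
        "changed": changed,
        "opposite": opposite,
        "shared_additive": int(((a1 == "additive") & (a2 == "additive")).sum()),
        "eld_same_form": int(
            ((e1.values == e2.values) & (e1.values != "none")).sum()
        ),
        "additive_contingency": additive_tab,
        "eld_contingency": eld_tab,
    }
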