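"""Model/Results interface over the trio classification and bias analyses.

Two model classes mirror the statsmodels idiom: construct the model from
data, call :meth:`fit`, inspect the returned results object.

>>> model = HybridExpressionModel(counts, "AA1", "CC", "AC1")
>>> res = model.fit(alpha=0.05)
>>> res.assignments.loc["gA00001", "pattern"]
'XII'
>>> print(res.summary())

:class:`HybridExpressionModel` fits the 19-pattern / 9-category taxonomy
(with dominance and transgressive calls) for one A-parent/C-parent/hybrid
trio; :class:`HomoeologBiasModel` fits the nine-way homoeolog-bias
classification over the annotated A/C gene pairs.
"""

from __future__ import annotations

import pandas as pd

from . import bias as bias_mod
from . import classify as classify_mod
from .containers import CountTable
from .report import percent

__all__ = [
    "HybridExpressionModel", "HybridExpressionResults",
    "HomoeologBiasModel", "HomoeologBiasResults",
]

_PATTERN_ORDER = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX",
    "INCONSISTENT",
]


class HybridExpressionModel:
    """Expression-pattern model for one parent/parent/hybrid trio."""

    def __init__(self, counts: CountTable, a_parent: str, c_parent: str,
                 hybrid: str):
        for s in (a_parent, c_parent, hybrid):
            if s not in counts.samples:
                raise KeyError(f"sample {s!r} missing from count table")
        self.counts = counts
        self.a_parent = a_parent
        self.c_parent = c_parent
        self.hybrid = hybrid

    @classmethod
    def from_long_frame(cls, long: pd.DataFrame, a_parent: str,
                        c_parent: str, hybrid: str) -> "HybridExpressionModel":
        """Build from a long gene_id/sample/replicate/count frame."""
        return cls(CountTable.from_long(long), a_parent, c_parent, hybrid)

    def fit(self, alpha: float = 0.05,
            require_all_expressed: bool = False) -> "HybridExpressionResults":
        frame, summary = classify_mod.classify_all(
            self.counts, self.a_parent, self.c_parent, self.hybrid,
            alpha=alpha, require_all_expressed=require_all_expressed,
        )
        return HybridExpressionResults(self, frame, summary, alpha)


class HybridExpressionResults:
    """Per-gene assignments plus trio-level totals and balance tests."""

    def __init__(self, model, assignments, summary_counts, alpha):
        self.model = model
        self.assignments = assignments
        self.counts = summary_counts
        self.alpha = alpha

    @property
    def pattern_counts(self) -> pd.Series:
        return (self.assignments["pattern"].value_counts()
                .reindex(_PATTERN_ORDER, fill_value=0))

    @property
    def category_counts(self) -> pd.Series:
        return (self.assignments["category"].value_counts()
                .reindex(list("abcdefghi"), fill_value=0))

    @property
    def eld_counts(self) -> dict:
        return dict(self.counts.eld_counts)

    def summary(self) -> str:
        s = self.counts
        m = self.model
        n = s.n_classified
        lines = [
            "Hybrid expression classification",
            "=" * 56,
            f"A parent: {m.a_parent}   C parent: {m.c_parent}   "
            f"hybrid: {m.hybrid}",
            f"alpha (BH-adjusted): {self.alpha}   genes classified: {n}",
            "-" * 56,
            f"additive vs MPV:      {s.additive:>8d}  "
            f"({percent(s.additive, n)}%)",
            f"non-additive up:      {s.non_additive_up:>8d}",
            f"non-additive down:    {s.non_additive_down:>8d}",
            f"dominance total:      {s.eld_total:>8d}   "
            f"A {s.a_dominance} (up {s.eld_counts['A_up']}, "
            f"down {s.eld_counts['A_down']}) vs "
            f"C {s.c_dominance} (up {s.eld_counts['C_up']}, "
            f"down {s.eld_counts['C_down']})",
            f"dominance balance p:  {s.dominance_balance_p:>12.4g}",
            f"transgressive up:     {s.transgressive_up:>8d}",
            f"transgressive down:   {s.transgressive_down:>8d}",
            f"transgressive balance p: {s.transgressive_balance_p:>9.4g}",
            "-" * 56,
            "pattern counts: " + "  ".join(
                f"{p}:{c}" for p, c in self.pattern_counts.items() if c),
            "category counts: " + "  ".join(
                f"{p}:{c}" for p, c in self.category_counts.items() if c),
        ]
        return "\n".join(lines)


class HomoeologBiasModel:
    """Nine-way homoeolog-bias model over the annotated A/C gene pairs."""

    def __init__(self, counts: CountTable, genes, a_parent: str,
                 c_parent: str, hybrid: str):
        self.counts = counts
        self.genes = list(genes)
        self.a_parent = a_parent
        self.c_parent = c_parent
        self.hybrid = hybrid

    def fit(self, alpha: float = 0.05,
            universe: str = "either") -> "HomoeologBiasResults":
        calls = bias_mod.classify_pairs(
            self.counts, self.genes, self.a_parent, self.c_parent,
            self.hybrid, alpha=alpha, universe=universe,
        )
        table = bias_mod.summarize_bias(calls)
        return HomoeologBiasResults(self, calls, table, alpha)


class HomoeologBiasResults:
    """Pair calls plus the nine-category table and the balance test."""

    def __init__(self, model, calls, table, alpha):
        self.model = model
        self.calls = calls
        self.table = table
        self.alpha = alpha

    @property
    def category_counts(self) -> pd.Series:
        return pd.Series(self.table["category_counts"]).reindex(
            bias_mod.CATEGORY_ORDER)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Homoeolog expression bias",
            "=" * 56,
            f"hybrid: {self.model.hybrid}   pairs: {t['total_pairs']}   "
            f"alpha: {self.alpha}",
            "-" * 56,
        ]
        for cat in bias_mod.CATEGORY_ORDER:
            lines.append(f"{cat:22s} {t['category_counts'][cat]:>8d}  "
                         f"({t['category_percent'][cat]}%)")
        lines += [
            "-" * 56,
            f"overall A-bias         {t['overall_A_bias']:>8d}  "
            f"({t['overall_A_bias_percent']}%)",
            f"overall C-bias         {t['overall_C_bias']:>8d}  "
            f"({t['overall_C_bias_percent']}%)",
            f"A:C balance chi2={t['balance_chi2']:.4g}  "
            f"p={t['balance_p']:.4g}",
        ]
        return "\n".join(lines)
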