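"""Core data containers shared by every pipeline stage.

The two central objects are :class:`GeneModel` (one annotated gene with an
optional homoeologous partner on the other subgenome) and :class:`CountTable`
(per-gene fragment counts for each sample/replicate, the substrate of all
statistical testing).  Coordinates are stored 0-based half-open internally,
whatever the input dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUBGENOMES = ("A", "C")

#: integer encoding of a three-valued significance sign
SIGN_SYMBOLS = {1: "+", 0: "0", -1: "-"}
SYMBOL_SIGNS = {"+": 1, "0": 0, "-": -1, "−": -1}


def as_sign(value) -> int:
    """Normalize a sign given as int (+1/0/-1) or symbol ('+','0','-')."""
    if isinstance(value, str):
        try:
            return SYMBOL_SIGNS[value]
        except KeyError:
            raise ValueError(f"invalid sign symbol: {value!r}") from None
    iv = int(value)
    if iv not in (-1, 0, 1):
        raise ValueError(f"invalid sign value: {value!r}")
    return iv


def sign_symbol(value) -> str:
    return SIGN_SYMBOLS[as_sign(value)]


def round_half_up(x) -> int | np.ndarray:
    """Round non-negative values half-up to the nearest integer.

    Fractional fragment counts (0.5 contributions from pairs spanning
    adjacent genes) are rounded half-up before any exact test, which
    requires integer cell entries.
    """
    arr = np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)
    if np.ndim(x) == 0:
        return int(arr)
    return arr


@dataclass
class GeneModel:
    """One gene model: coordinates, subgenome label, optional homoeolog link.

    ``start``/``end`` are 0-based half-open; ``length`` is ``end - start``
    (exon-resolved lengths are out of scope).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    subgenome: str = "A"
    partner_id: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.subgenome not in SUBGENOMES:
            raise ValueError(
                f"{self.gene_id}: subgenome must be one of {SUBGENOMES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    rows = [
        (g.gene_id, g.chrom, g.start, g.end, g.strand, g.subgenome,
         g.partner_id, g.length)
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "subgenome",
                 "partner_id", "length"],
    ).set_index("gene_id")


def validate_pairs(genes: Sequence[GeneModel]) -> list[tuple[str, str]]:
    """Check homoeolog links are symmetric and cross-subgenome.

    Returns the undirected pair list as (a_gene_id, c_gene_id) tuples.
    """
    by_id = {g.gene_id: g for g in genes}
    if len(by_id) != len(genes):
        seen, dup = set(), None
        for g in genes:
            if g.gene_id in seen:
                dup = g.gene_id
                break
            seen.add(g.gene_id)
        raise ValueError(f"duplicate gene_id in annotation: {dup}")
    pairs = []
    for g in genes:
        if g.partner_id is None:
            continue
        p = by_id.get(g.partner_id)
        if p is None:
            raise ValueError(f"{g.gene_id}: partner {g.partner_id} not in annotation")
        if p.partner_id != g.gene_id:
            raise ValueError(
                f"asymmetric homoeolog link: {g.gene_id} -> {g.partner_id} "
                f"but {p.gene_id} -> {p.partner_id}"
            )
        if p.subgenome == g.subgenome:
            raise ValueError(
                f"homoeolog pair {g.gene_id}/{p.gene_id} is not cross-subgenome"
            )
        if g.subgenome == "A":
            pairs.append((g.gene_id, p.gene_id))
    return pairs


class CountTable:
    """Per-gene fragment counts indexed by (sample, replicate).

    Wraps a wide :class:`pandas.DataFrame` whose index is ``gene_id`` and
    whose columns are a ``(sample, replicate)`` MultiIndex.  Values may be
    fractional (multiples of 0.5 arise from read pairs spanning adjacent
    genes) but are rounded half-up on the way into any exact test.

    The library size of a column is the sum of accepted fragment
    assignments in that library.  When the table holds every counted gene
    (the SAM-counting path) that is simply the column sum; a table covering
    a subset of the transcriptome (notably the simulator, whose genes sit
    inside a larger configured library) instead declares its library sizes.
    Declared sizes are authoritative exact-test margins; each individual
    count must fit inside its library.
    """

    def __init__(self, frame: pd.DataFrame,
                 library_sizes: Mapping | None = None):
        if not isinstance(frame.columns, pd.MultiIndex) or frame.columns.nlevels != 2:
            raise ValueError("CountTable expects (sample, replicate) columns")
        if frame.size and (frame.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.frame = frame.astype(float)
        self.frame.index.name = "gene_id"
        self.frame.columns.names = ["sample", "replicate"]
        self.declared_library_sizes: dict | None = None
        if library_sizes is not None:
            declared = {tuple(k): float(v) for k, v in library_sizes.items()}
            missing = set(map(tuple, self.frame.columns)) - set(declared)
            if missing:
                raise ValueError(f"library sizes missing for {sorted(missing)}")
            for col in self.frame.columns:
                if self.frame[col].size and \
                        float(self.frame[col].max()) > declared[tuple(col)]:
                    raise ValueError(
                        f"a count in {col} exceeds its declared library size"
                    )
            self.declared_library_sizes = declared

    # ------------------------------------------------------------------ #
    @classmethod
    def from_long(cls, long: pd.DataFrame,
                  library_sizes: Mapping | None = None) -> "CountTable":
        """Build from a long table with columns gene_id/sample/replicate/count."""
        required = {"gene_id", "sample", "replicate", "count"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if len(long) == 0:
            return cls(pd.DataFrame(
                index=pd.Index([], name="gene_id"),
                columns=pd.MultiIndex.from_arrays([[], []],
                                                  names=["sample", "replicate"]),
            ))
        if (pd.to_numeric(long["count"]) < 0).any():
            raise ValueError("counts must be non-negative")
        wide = long.pivot_table(
            index="gene_id", columns=["sample", "replicate"], values="count",
            aggfunc="sum", fill_value=0.0,
        )
        return cls(wide, library_sizes=library_sizes)

    def to_long(self) -> pd.DataFrame:
        long = self.frame.stack(["sample", "replicate"], future_stack=True)
        long = long.rename("count").reset_index()
        return long[["gene_id", "sample", "replicate", "count"]]

    # ------------------------------------------------------------------ #
    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def n_genes(self) -> int:
        return len(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns.get_level_values("sample").unique())

    def replicates(self, sample: str) -> list:
        return list(self.frame[sample].columns)

    def pooled(self, sample: str) -> pd.Series:
        """Replicate-pooled counts for one sample (may be fractional)."""
        if sample not in self.samples:
            raise KeyError(f"sample {sample!r} not in count table")
        return self.frame[sample].sum(axis=1)

    def pooled_int(self, sample: str) -> pd.Series:
        pooled = self.pooled(sample)
        return pd.Series(round_half_up(pooled.values), index=pooled.index)

    def library_size(self, sample: str, replicate=None) -> float:
        """Library size: declared totals when present, else column sums."""
        if self.declared_library_sizes is not None:
            if replicate is None:
                return float(sum(v for (s, _), v in
                                 self.declared_library_sizes.items()
                                 if s == sample))
            return float(self.declared_library_sizes[(sample, replicate)])
        if replicate is None:
            return float(self.pooled(sample).sum())
        return float(self.frame[(sample, replicate)].sum())

    def expressed(self, sample: str) -> pd.Series:
        """Boolean expressed mask: pooled count > 0 (equivalent to FPKM > 0)."""
        return self.pooled(sample) > 0

    def subset_genes(self, gene_ids) -> "CountTable":
        return CountTable(self.frame.loc[gene_ids],
                          library_sizes=self.declared_library_sizes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.frame.sort_index().sort_index(axis=1).equals(
                other.frame.sort_index().sort_index(axis=1))
            and self.declared_library_sizes == other.declared_library_sizes
        )

    def __repr__(self) -> str:
        return (f"CountTable({self.n_genes} genes × "
                f"{self.frame.shape[1]} sample/replicate columns)")
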