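"""Annotation/count I/O and the paired-read acceptance rules.

A read pair contributes to the count table only when

1. both mates are *best unique* alignments — primary (not secondary or
   supplementary), mapped, mapping quality at or above a configurable floor
   (default 1), and carrying no alternative-hit tag (``XA``);
2. both mates overlap the same gene with coherent (opposite-strand, FR/RF)
   orientations — that gene gains 1 fragment; or
3. the two mates overlap two genes *adjacent* in start-coordinate order on
   the same chromosome — each gene gains 0.5.

Pairs with one unmapped or ambiguous mate, a single end on a gene, or both
ends on non-adjacent genes are discarded; every rejection reason is tallied
in the acceptance log.  Adjacency is consecutive rank in start order per
chromosome, irrespective of strand or intergenic distance.  A mate overlaps
a gene when at least 1 bp of its aligned interval intersects the gene
interval; ties go to the larger overlap, then the lexicographically smaller
gene id.

Coordinates are 0-based half-open internally: BED is taken as-is, GFF3
start positions are shifted down by one on input and up by one on output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .containers import CountTable, GeneModel, validate_pairs

__all__ = [
    "read_annotation", "write_bed", "write_gff3", "write_pairs",
    "read_counts", "write_counts", "filter_and_count", "filter_and_count_many",
]

REJECT_REASONS = (
    "missing_mate", "unmapped_mate", "not_best_unique",
    "no_gene_overlap", "single_end_on_gene",
    "incoherent_orientation", "non_adjacent_genes",
)


# --------------------------------------------------------------------- #
# annotation

def _subgenome_of(chrom: str, gene_id: str) -> str:
    initial = chrom[:1].upper()
    if initial not in ("A", "C"):
        raise ValueError(
            f"{gene_id}: cannot infer subgenome from chromosome {chrom!r}"
        )
    return initial


def _read_bed(path) -> list[GeneModel]:
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneModel(row["name"], row["chrom"], int(row["start"]), int(row["end"]),
                  strand=row["strand"],
                  subgenome=_subgenome_of(row["chrom"], row["name"]))
        for _, row in frame.iterrows()
    ]


def _read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        sub = feat.attributes.get("subgenome", [None])[0] \
            or _subgenome_of(feat.seqid, gid)
        partner = feat.attributes.get("partner", [None])[0]
        genes.append(GeneModel(
            gid, feat.seqid, feat.start - 1, feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            subgenome=sub, partner_id=partner,
        ))
    return genes


def _read_pairs_file(path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: pairs file needs two columns")
    frame = frame.iloc[:, :2]
    frame.columns = ["a_gene_id", "c_gene_id"]
    if frame.iloc[0, 0] == "a_gene_id":  # tolerate a header row
        frame = frame.iloc[1:]
    # both orientations of the same link collapse to one undirected pair
    seen, pairs = set(), []
    for a, c in frame.itertuples(index=False):
        key = frozenset((a, c))
        if key not in seen:
            seen.add(key)
            pairs.append((a, c))
    return pairs


def read_annotation(path, fmt: str | None = None,
                    pairs_path=None) -> list[GeneModel]:
    """Read gene models from BED6 or GFF3, optionally linking homoeolog pairs.

    Format is inferred from the suffix unless given.  Pair links (from GFF3
    ``partner`` attributes or the two-column pairs TSV) are validated to be
    symmetric and cross-subgenome; duplicate gene ids are an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "BED" if path.suffix.lower() == ".bed" else "GFF3"
    fmt = fmt.upper()
    if fmt == "BED":
        genes = _read_bed(path)
    elif fmt == "GFF3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    if pairs_path is not None:
        by_id = {g.gene_id: g for g in genes}
        for left, right in _read_pairs_file(pairs_path):
            for gid in (left, right):
                if gid not in by_id:
                    raise ValueError(f"pairs file references unknown gene {gid}")
            by_id[left].partner_id = right
            by_id[right].partner_id = left
    validate_pairs(genes)
    return genes


def write_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};subgenome={g.subgenome}"
            if g.partner_id:
                attrs += f";partner={g.partner_id}"
            fh.write(
                f"{g.chrom}\tpolyeld\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_pairs(genes, path) -> None:
    pairs = validate_pairs(list(genes))
    with open(path, "w") as fh:
        fh.write("a_gene_id\tc_gene_id\n")
        for a, c in pairs:
            fh.write(f"{a}\t{c}\n")


# --------------------------------------------------------------------- #
# counts TSV

def write_counts(counts: CountTable, path) -> None:
    long = counts.to_long()

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    with open(path, "w") as fh:
        if counts.declared_library_sizes is not None:
            for (sample, rep), v in sorted(
                    counts.declared_library_sizes.items()):
                fh.write(f"#library_size\t{sample}\t{rep}\t{fmt(v)}\n")
        fh.write("gene_id\tsample\treplicate\tcount\n")
        for gid, sample, rep, value in long.itertuples(index=False):
            fh.write(f"{gid}\t{sample}\t{rep}\t{fmt(value)}\n")


def read_counts(path) -> CountTable:
    """Read a counts TSV; leading ``#library_size`` lines declare totals.

    Library sizes are recomputed from the counts and, when totals are
    declared, each count is checked to fit inside its declared library
    (enforced by :class:`CountTable`).
    """
    declared = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#library_size" and len(fields) == 4:
                declared[(fields[1], int(fields[2]))] = float(fields[3])
    frame = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"gene_id": str, "sample": str, "replicate": int,
               "count": float},
    )
    return CountTable.from_long(frame, library_sizes=declared or None)


# --------------------------------------------------------------------- #
# SAM filtering and counting

def _gene_index(genes):
    trees: dict[str, IntervalTree] = {}
    rank: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(lst):
            rank[g.gene_id] = (chrom, i)
    return trees, rank


def _best_overlap(tree: IntervalTree | None, start: int, end: int):
    if tree is None:
        return None
    hits = tree.overlap(start, end)
    if not hits:
        return None
    # largest overlap wins; ties break to the smaller gene id
    return min(
        hits,
        key=lambda iv: (-(min(end, iv.end) - max(start, iv.begin)), iv.data),
    ).data


def _is_best_unique(rec, min_mapq: int) -> bool:
    if rec.is_secondary or rec.is_supplementary:
        return False
    if rec.mapping_quality < min_mapq:
        return False
    if rec.has_tag("XA"):
        return False
    return True


def filter_and_count(
    sam_path, genes, min_mapq: int = 1
) -> tuple[pd.Series, dict]:
    """Apply the three acceptance rules to one SAM file.

    Returns per-gene fragment counts (floats; rule-3 pairs contribute 0.5 to
    each adjacent gene) over every annotated gene, and the acceptance log:
    total pairs examined, accepted counts per rule, and one tally per
    rejection reason, with ``accepted + rejected == total``.
    """
    trees, rank = _gene_index(genes)
    counts = pd.Series(0.0, index=pd.Index([g.gene_id for g in genes],
                                           name="gene_id"))
    log = {"total_pairs": 0, "rule2_pairs": 0, "rule3_pairs": 0}
    log.update({f"rejected_{r}": 0 for r in REJECT_REASONS})

    pairs: dict[str, list] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for i, rec in enumerate(fh):
            try:
                slot = 0 if rec.is_read1 else 1
                entry = pairs.setdefault(rec.query_name, [None, None])
                # prefer the primary record when a mate appears repeatedly
                if entry[slot] is None or entry[slot][0]:
                    entry[slot] = (
                        rec.is_secondary or rec.is_supplementary,
                        rec.is_unmapped,
                        rec.reference_name,
                        rec.reference_start if not rec.is_unmapped else -1,
                        (rec.reference_end or 0) if not rec.is_unmapped else -1,
                        rec.is_reverse,
                        rec.mapping_quality,
                        rec.has_tag("XA"),
                    )
            except (ValueError, TypeError) as exc:  # pragma: no cover
                raise ValueError(f"unparseable SAM record #{i + 1} "
                                 f"in {sam_path}: {exc}") from exc

    for qname, (m1, m2) in pairs.items():
        log["total_pairs"] += 1
        if m1 is None or m2 is None:
            log["rejected_missing_mate"] += 1
            continue
        if m1[1] or m2[1]:
            log["rejected_unmapped_mate"] += 1
            continue
        ok1 = not m1[0] and m1[6] >= min_mapq and not m1[7]
        ok2 = not m2[0] and m2[6] >= min_mapq and not m2[7]
        if not (ok1 and ok2):
            log["rejected_not_best_unique"] += 1
            continue
        g1 = _best_overlap(trees.get(m1[2]), m1[3], m1[4])
        g2 = _best_overlap(trees.get(m2[2]), m2[3], m2[4])
        if g1 is None and g2 is None:
            log["rejected_no_gene_overlap"] += 1
            continue
        if g1 is None or g2 is None:
            log["rejected_single_end_on_gene"] += 1
            continue
        if g1 == g2:
            if m1[5] != m2[5]:
                log["rule2_pairs"] += 1
                counts.loc[g1] += 1.0
            else:
                log["rejected_incoherent_orientation"] += 1
            continue
        chrom1, rank1 = rank[g1]
        chrom2, rank2 = rank[g2]
        if chrom1 == chrom2 and abs(rank1 - rank2) == 1:
            log["rule3_pairs"] += 1
            counts.loc[g1] += 0.5
            counts.loc[g2] += 0.5
        else:
            log["rejected_non_adjacent_genes"] += 1
    return counts, log


def filter_and_count_many(
    sam_paths: dict, genes, min_mapq: int = 1
) -> tuple[CountTable, dict]:
    """Count a set of SAM files keyed by (sample, replicate) into one table."""
    columns, data, logs = [], [], {}
    for (sample, rep), path in sorted(sam_paths.items()):
        col, log = filter_and_count(path, genes, min_mapq=min_mapq)
        columns.append((sample, rep))
        data.append(col.values)
        logs[f"{sample}_{rep}"] = log
    frame = pd.DataFrame(
        np.array(data).T,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=pd.MultiIndex.from_tuples(columns,
                                          names=["sample", "replicate"]),
    )
    return CountTable(frame), logs
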