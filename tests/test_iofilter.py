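"""Annotation parsing, coordinate conventions and the pair-acceptance rules."""

import textwrap

import pandas as pd
import pytest

from polyeld import iofilter
from polyeld.containers import GeneModel


# --------------------------------------------------------------------- #
# annotation

def test_gff3_one_based_closed_to_internal_half_open(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n"
                   "A01\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
    (gene,) = iofilter.read_annotation(gff)
    assert (gene.start, gene.end, gene.length) == (100, 200, 100)
    assert gene.subgenome == "A"


def test_bed_round_trip_is_identity(tmp_path):
    genes = [GeneModel("g1", "A01", 100, 200, "+", "A"),
             GeneModel("g2", "C03", 0, 50, "-", "C")]
    bed = tmp_path / "g.bed"
    iofilter.write_bed(genes, bed)
    back = iofilter.read_annotation(bed)
    assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in back] == \
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes]


def test_bed_internal_gff3_round_trip(tmp_path):
    genes = [GeneModel("g1", "A01", 37, 412, "-", "A")]
    gff = tmp_path / "g.gff3"
    iofilter.write_gff3(genes, gff)
    (back,) = iofilter.read_annotation(gff)
    assert (back.start, back.end) == (37, 412)


def test_pairs_both_orientations_collapse(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("A01\t0\t100\tga\t0\t+\nC01\t0\t100\tgc\t0\t+\n")
    pairs = tmp_path / "p.tsv"
    pairs.write_text("ga\tgc\ngc\tga\n")
    genes = iofilter.read_annotation(bed, pairs_path=pairs)
    assert {g.gene_id: g.partner_id for g in genes} == \
        {"ga": "gc", "gc": "ga"}


def test_same_subgenome_pair_rejected(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("A01\t0\t100\tg1\t0\t+\nA02\t0\t100\tg2\t0\t+\n")
    pairs = tmp_path / "p.tsv"
    pairs.write_text("g1\tg2\n")
    with pytest.raises(ValueError, match="cross-subgenome"):
        iofilter.read_annotation(bed, pairs_path=pairs)


def test_asymmetric_partner_attribute_rejected(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "A01\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1;partner=g2\n"
        "C01\tsrc\tgene\t1\t100\t.\t+\t.\tID=g2;partner=g3\n"
        "C02\tsrc\tgene\t1\t100\t.\t+\t.\tID=g3\n"
    )
    with pytest.raises(ValueError, match="asymmetric"):
        iofilter.read_annotation(gff)


def test_duplicate_gene_id_rejected(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("A01\t0\t100\tg1\t0\t+\nA01\t200\t300\tg1\t0\t+\n")
    with pytest.raises(ValueError, match="duplicate"):
        iofilter.read_annotation(bed)


# --------------------------------------------------------------------- #
# counts TSV

def test_read_counts_empty_file(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text("gene_id\tsample\treplicate\tcount\n")
    assert iofilter.read_counts(path).n_genes == 0


def test_read_counts_shape(tmp_path):
    path = tmp_path / "c.tsv"
    rows = ["gene_id\tsample\treplicate\tcount"]
    for g in ("g1", "g2", "g3"):
        for s in ("X", "Y"):
            rows.append(f"{g}\t{s}\t1\t5")
    path.write_text("\n".join(rows) + "\n")
    table = iofilter.read_counts(path)
    assert table.frame.shape == (3, 2)
    assert table.library_size("X") == 15


def test_read_counts_negative_rejected(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text("gene_id\tsample\treplicate\tcount\ng1\tX\t1\t-1\n")
    with pytest.raises(ValueError):
        iofilter.read_counts(path)


# --------------------------------------------------------------------- #
# SAM filtering

HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:A01\tLN:2000\n@SQ\tSN:C01\tLN:2000\n"


def sam_line(qname, flag, chrom, pos, mapq=60, tags=""):
    base = (f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t80M\t=\t1\t0\t*\t*")
    return base + (f"\t{tags}" if tags else "")


@pytest.fixture()
def gene_set():
    return [
        GeneModel("G1", "A01", 100, 300, "+", "A"),
        GeneModel("G2", "A01", 400, 600, "+", "A"),
        GeneModel("G3", "A01", 700, 900, "+", "A"),
        GeneModel("G4", "C01", 100, 300, "+", "C"),
        GeneModel("G5", "C01", 250, 500, "+", "C"),
    ]


def run_filter(tmp_path, gene_set, body_lines, **kwargs):
    sam = tmp_path / "t.sam"
    sam.write_text(HEADER + "".join(line + "\n" for line in body_lines))
    return iofilter.filter_and_count(sam, gene_set, **kwargs)


def test_rule2_same_gene_opposite_strands(tmp_path, gene_set):
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "A01", 101),    # read1 forward in G1
        sam_line("p1", 145, "A01", 221),   # read2 reverse in G1
    ])
    assert counts.loc["G1"] == 1 and log["rule2_pairs"] == 1


def test_rule3_adjacent_genes_half_each(tmp_path, gene_set):
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "A01", 101),    # in G1
        sam_line("p1", 145, "A01", 421),   # in G2, adjacent to G1
    ])
    assert counts.loc["G1"] == 0.5 and counts.loc["G2"] == 0.5
    assert log["rule3_pairs"] == 1


def test_non_adjacent_and_cross_chromosome_rejected(tmp_path, gene_set):
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "A01", 101),    # G1
        sam_line("p1", 145, "A01", 721),   # G3: one gene apart
        sam_line("p2", 97, "A01", 101),    # G1
        sam_line("p2", 145, "C01", 101),   # G4: other chromosome
    ])
    assert counts.sum() == 0
    assert log["rejected_non_adjacent_genes"] == 2


def test_single_end_and_intergenic_rejected(tmp_path, gene_set):
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "A01", 101),     # G1
        sam_line("p1", 145, "A01", 1500),   # intergenic
        sam_line("p2", 97, "A01", 1300),    # intergenic
        sam_line("p2", 145, "A01", 1500),   # intergenic
    ])
    assert counts.sum() == 0
    assert log["rejected_single_end_on_gene"] == 1
    assert log["rejected_no_gene_overlap"] == 1


def test_same_strand_pair_rejected(tmp_path, gene_set):
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 65, "A01", 101),
        sam_line("p1", 129, "A01", 221),
    ])
    assert counts.loc["G1"] == 0
    assert log["rejected_incoherent_orientation"] == 1


def test_best_unique_filters(tmp_path, gene_set):
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "A01", 101, mapq=0),          # below mapq floor
        sam_line("p1", 145, "A01", 221),
        sam_line("p2", 97, "A01", 101, tags="XA:Z:alt,+7,80M,1;"),
        sam_line("p2", 145, "A01", 221),
        sam_line("p3", 97 | 0x100, "A01", 101),          # secondary only
        sam_line("p3", 145, "A01", 221),
        sam_line("p4", 73, "A01", 101),                  # mate unmapped
        sam_line("p4", 133, "*", 0),
        sam_line("p5", 97, "A01", 101),                  # mate record absent
    ])
    assert counts.sum() == 0
    assert log["rejected_not_best_unique"] == 3
    assert log["rejected_unmapped_mate"] == 1
    assert log["rejected_missing_mate"] == 1


def test_mapq_floor_configurable(tmp_path, gene_set):
    counts, _ = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "A01", 101, mapq=0),
        sam_line("p1", 145, "A01", 221, mapq=0),
    ], min_mapq=0)
    assert counts.loc["G1"] == 1


def test_overlap_tie_breaks_to_larger_overlap(tmp_path, gene_set):
    # read at [260, 340) overlaps G4 by 40 bp and G5 by 80 bp -> G5
    counts, log = run_filter(tmp_path, gene_set, [
        sam_line("p1", 97, "C01", 261),
        sam_line("p1", 145, "C01", 401),   # fully inside G5
    ])
    assert counts.loc["G5"] == 1 and counts.loc["G4"] == 0


def test_counting_conservation(tmp_path, gene_set):
    body = [
        sam_line("p1", 97, "A01", 101), sam_line("p1", 145, "A01", 221),
        sam_line("p2", 97, "A01", 101), sam_line("p2", 145, "A01", 421),
        sam_line("p3", 97, "A01", 101), sam_line("p3", 145, "A01", 721),
        sam_line("p4", 97, "A01", 1300),
    ]
    counts, log = run_filter(tmp_path, gene_set, body)
    accepted = log["rule2_pairs"] + log["rule3_pairs"]
    rejected = sum(v for k, v in log.items() if k.startswith("rejected_"))
    assert accepted + rejected == log["total_pairs"] == 4
    # assigned mass: one fragment per accepted pair
    assert counts.sum() == log["rule2_pairs"] + log["rule3_pairs"]
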