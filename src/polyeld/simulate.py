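"""Synthetic parental/hybrid count tables with known per-gene truth.

The generator emulates the statistical structure the downstream analysis
assumes: five libraries (two A-genome parents, one shared C parent, two
hybrids), two biological replicates each, per-gene integer fragment counts
under gamma-Poisson (negative-binomial) noise, with roughly half the genes
organized as A/C homoeologous pairs.  Each gene (or pair) is planted in one
truth class that fixes its mean expression in the A parent, C parent and
hybrid:

==================== ============ ============ ======================
class                 A parent     C parent     hybrid
==================== ============ ============ ======================
additive_equal        m            m            m
additive_parentdiff   m·f / m      m / m·f      mid-parent mean
eld_A_up              m·f          m            m·f   (mimics A)
eld_A_down            m            m·f          m     (mimics A)
eld_C_up              m            m·f          m·f   (mimics C)
eld_C_down            m·f          m            m     (mimics C)
transgressive_up      m            m            m·f
transgressive_down    m            m            m / f
novel_bias            m            m            one homoeolog at m·f
silent                0            0            0
==================== ============ ============ ======================

with m = ``mean_expression`` and f = ``effect_fold``.  Replicates of a
sample share the gene-level mean (no extra biological variance term), since
replicates are pooled into a single exact test downstream; the dispersion
knob defaults to 0 (pure Poisson) accordingly.  Truth labels are assigned
before noise; genes whose sampled counts are all zero are relabelled
``silent`` post hoc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, GeneModel, genes_to_frame

__all__ = ["CLASS_NAMES", "SimulationConfig", "SyntheticDataset",
           "generate_dataset", "write_fixture"]

CLASS_NAMES = (
    "additive_equal", "additive_parentdiff",
    "eld_A_up", "eld_A_down", "eld_C_up", "eld_C_down",
    "transgressive_up", "transgressive_down",
    "novel_bias", "silent",
)

A_PARENTS = ("AA1", "AA2")
C_PARENT = "CC"
HYBRIDS = ("AC1", "AC2")
SAMPLES = A_PARENTS + (C_PARENT,) + HYBRIDS

#: default mixture, loosely shaped like a leaf transcriptome: a little under
#: half the gene models silent in all libraries, parental divergence for
#: roughly half of the expressed genes, dominance split evenly over its four
#: forms, more transgressive-up than -down, and a small novel-bias fraction.
DEFAULT_MIX = {
    "additive_equal": 0.30,
    "additive_parentdiff": 0.20,
    "eld_A_up": 0.02,
    "eld_A_down": 0.02,
    "eld_C_up": 0.02,
    "eld_C_down": 0.02,
    "transgressive_up": 0.005,
    "transgressive_down": 0.002,
    "novel_bias": 0.013,
    "silent": 0.40,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic transcriptome.

    ``lib_size_per_sample`` is either one integer (all libraries equal) or a
    mapping sample -> fragments; replicates of a sample share its size.
    ``nb_dispersion`` is the negative-binomial dispersion phi in
    var = mu + phi * mu^2; 0 degrades to Poisson.
    """

    n_genes: int = 20000
    frac_paired: float = 0.5
    lib_size_per_sample: int | dict = 1_000_000
    mean_expression: float = 50.0
    nb_dispersion: float = 0.0
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    effect_fold: float = 4.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0 <= self.frac_paired <= 1:
            raise ValueError("frac_paired must lie in [0, 1]")
        if self.mean_expression < 0:
            raise ValueError("mean_expression must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must exceed 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        unknown = set(self.class_mix) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown truth classes: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total!r})")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        for lib in self._lib_sizes().values():
            if lib <= 0:
                raise ValueError("library sizes must be strictly positive")

    def _lib_sizes(self) -> dict:
        if isinstance(self.lib_size_per_sample, dict):
            missing = set(SAMPLES) - set(self.lib_size_per_sample)
            if missing:
                raise ValueError(f"lib_size_per_sample missing {sorted(missing)}")
            return {s: int(self.lib_size_per_sample[s]) for s in SAMPLES}
        return {s: int(self.lib_size_per_sample) for s in SAMPLES}


@dataclass
class SyntheticDataset:
    counts: CountTable
    genes: list
    truth: pd.DataFrame
    config: SimulationConfig

    def __iter__(self):
        return iter((self.counts, self.genes, self.truth))


def _class_means(name: str, m: float, f: float, a_high: bool):
    """(mu_A, mu_C, mu_H) recipe for one non-pair-specific truth class."""
    if name == "additive_equal":
        return (m, m, m)
    if name == "additive_parentdiff":
        hi, lo = m * f, m
        mid = (hi + lo) / 2.0
        return (hi, lo, mid) if a_high else (lo, hi, mid)
    if name == "eld_A_up":
        return (m * f, m, m * f)
    if name == "eld_A_down":
        return (m, m * f, m)
    if name == "eld_C_up":
        return (m, m * f, m * f)
    if name == "eld_C_down":
        return (m * f, m, m)
    if name == "transgressive_up":
        return (m, m, m * f)
    if name == "transgressive_down":
        return (m, m, m / f)
    if name == "silent":
        return (0.0, 0.0, 0.0)
    raise ValueError(name)


def _cmp(x: float, y: float) -> int:
    return 0 if math.isclose(x, y, rel_tol=1e-12, abs_tol=1e-12) else (
        1 if x > y else -1)


def _pattern_group(mu_a: float, mu_c: float, mu_h: float) -> str:
    s_ha, s_hc = _cmp(mu_h, mu_a), _cmp(mu_h, mu_c)
    if s_ha == 0 and s_hc == 0:
        return "equal_both"
    if s_ha == 0 or s_hc == 0:
        return "equal_one_parent"
    if s_ha == s_hc:
        return "transgressive_up" if s_ha > 0 else "transgressive_down"
    return "intermediate"


def _layout_genes(rng, n_pairs: int, n_single: int):
    """Gene models: pairs gA*/gC*, singletons uA*/uC*, laid out on A/C chromosomes.

    Homoeolog partners share the gene length (homoeologs have near-identical
    gene models), so the pair-mean length adjustment downstream is exact on
    simulated data.
    """
    pair_len = rng.integers(300, 3001, size=n_pairs)
    single_len = rng.integers(300, 3001, size=n_single)
    entries = []  # (gene_id, subgenome, length, partner)
    for i in range(n_pairs):
        entries.append((f"gA{i:05d}", "A", int(pair_len[i]), f"gC{i:05d}"))
        entries.append((f"gC{i:05d}", "C", int(pair_len[i]), f"gA{i:05d}"))
    for i in range(n_single):
        sub = "A" if i % 2 == 0 else "C"
        entries.append((f"u{sub}{i:05d}", sub, int(single_len[i]), None))

    n_chrom = {"A": 10, "C": 9}
    genes = []
    for sub in ("A", "C"):
        sub_entries = [e for e in entries if e[1] == sub]
        per = max(1, math.ceil(len(sub_entries) / n_chrom[sub]))
        cursor: dict[str, int] = {}
        for j, (gid, _, length, partner) in enumerate(sub_entries):
            chrom = f"{sub}{j // per + 1:02d}"
            start = cursor.get(chrom, 0) + 500
            genes.append(GeneModel(gid, chrom, start, start + length,
                                   strand="+" if j % 2 == 0 else "-",
                                   subgenome=sub, partner_id=partner))
            cursor[chrom] = start + length
    order = {e[0]: k for k, e in enumerate(entries)}
    genes.sort(key=lambda g: order[g.gene_id])
    return genes


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; identical config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_paired = 2 * int(n * config.frac_paired / 2)
    n_pairs, n_single = n_paired // 2, n - n_paired
    genes = _layout_genes(rng, n_pairs, n_single)

    mix_names = list(CLASS_NAMES)
    probs = np.array([config.class_mix.get(k, 0.0) for k in mix_names])
    # novel bias needs a partner; for singleton units its mass folds into
    # additive_equal so the per-unit draw stays a proper distribution.
    probs_single = probs.copy()
    probs_single[mix_names.index("additive_equal")] += \
        probs_single[mix_names.index("novel_bias")]
    probs_single[mix_names.index("novel_bias")] = 0.0

    pair_classes = rng.choice(mix_names, size=n_pairs, p=probs) \
        if n_pairs else np.array([], dtype=object)
    single_classes = rng.choice(mix_names, size=n_single, p=probs_single) \
        if n_single else np.array([], dtype=object)

    m, f = config.mean_expression, config.effect_fold
    mu = {}  # gene_id -> (mu_A, mu_C, mu_H)
    truth_rows = []
    for i, cls in enumerate(pair_classes):
        a_id, c_id = f"gA{i:05d}", f"gC{i:05d}"
        a_dir = i % 2 == 0  # alternate planted direction for symmetry
        if cls == "novel_bias":
            mu[a_id] = (m, m, m * f) if a_dir else (m, m, m)
            mu[c_id] = (m, m, m) if a_dir else (m, m, m * f)
        else:
            triple = _class_means(cls, m, f, a_high=a_dir)
            mu[a_id] = mu[c_id] = triple
        bias = _cmp(mu[a_id][2], mu[c_id][2])
        bias_label = {1: "A_bias", -1: "C_bias", 0: "none"}[bias]
        for gid in (a_id, c_id):
            truth_rows.append((gid, cls, _pattern_group(*mu[gid]), bias_label))
    for i, cls in enumerate(single_classes):
        sub = "A" if i % 2 == 0 else "C"
        gid = f"u{sub}{i:05d}"
        mu[gid] = _class_means(cls, m, f, a_high=i % 2 == 0)
        truth_rows.append((gid, cls, _pattern_group(*mu[gid]), "none"))

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "true_class", "true_pattern_group", "true_bias"],
    ).set_index("gene_id")

    gene_ids = [g.gene_id for g in genes]
    mu_arr = np.array([mu[g] for g in gene_ids], dtype=float) if gene_ids \
        else np.zeros((0, 3))
    sample_mu = {"AA1": mu_arr[:, 0], "AA2": mu_arr[:, 0],
                 "CC": mu_arr[:, 1], "AC1": mu_arr[:, 2], "AC2": mu_arr[:, 2]}
    libs = config._lib_sizes()
    ref_lib = float(np.mean(list(libs.values())))

    columns, data = [], []
    for s in SAMPLES:
        scale = libs[s] / ref_lib
        for rep in range(1, config.n_replicates + 1):
            mean_vec = sample_mu[s] * scale
            if config.nb_dispersion == 0:
                draw = rng.poisson(mean_vec)
            else:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mean_vec * config.nb_dispersion)
                draw = rng.poisson(lam)
            columns.append((s, rep))
            data.append(draw)
    frame = pd.DataFrame(
        np.array(data, dtype=float).T if data else np.zeros((0, 0)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["sample", "replicate"])
        if columns else pd.MultiIndex.from_arrays([[], []],
                                                  names=["sample", "replicate"]),
    )
    # the simulated genes sit inside a larger transcriptome: the configured
    # per-library fragment totals are the exact-test margins downstream
    counts = CountTable(frame, library_sizes={
        (s, rep): libs[s] for (s, rep) in columns})

    if counts.n_genes:
        all_zero = counts.frame.sum(axis=1) == 0
        truth.loc[truth.index[all_zero.reindex(truth.index).values],
                  "true_class"] = "silent"
    return SyntheticDataset(counts, genes, truth.reset_index(), config)


# --------------------------------------------------------------------- #
# fixture writing

def write_fixture(
    dataset: SyntheticDataset,
    dir_path,
    sam: bool = False,
    sam_decoys: int = 0,
    sam_rule3_pairs: int = 0,
) -> dict:
    """Write counts/annotation/pairs/truth (and optionally SAM) fixtures.

    Returns a dict of written paths; when SAM output is requested it also
    carries ``expected_sam_counts``, the per-column counts a correct
    pair-filter must recover from the SAM files (the planted counts plus
    0.5/0.5 contributions from any requested adjacent-gene pairs — decoy
    records are constructed to be rejected and contribute nothing).
    """
    from . import iofilter

    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "bed": out / "genes.bed",
        "gff3": out / "genes.gff3",
        "pairs": out / "pairs.tsv",
        "truth": out / "truth.tsv",
    }
    iofilter.write_counts(dataset.counts, paths["counts"])
    iofilter.write_bed(dataset.genes, paths["bed"])
    iofilter.write_gff3(dataset.genes, paths["gff3"])
    iofilter.write_pairs(dataset.genes, paths["pairs"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    if sam:
        sam_dir = out / "sam"
        sam_dir.mkdir(exist_ok=True)
        expected = _write_sam_fixtures(
            dataset, sam_dir, sam_decoys, sam_rule3_pairs)
        paths["sam_dir"] = sam_dir
        paths["expected_sam_counts"] = expected
    return paths


def _adjacent_gene_runs(genes):
    """Consecutive (gene, next_gene) pairs in start order per chromosome."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    runs = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        runs.extend(zip(ordered, ordered[1:]))
    return runs


def _write_sam_fixtures(dataset, sam_dir: Path, n_decoys: int,
                        n_rule3: int) -> pd.DataFrame:
    import pysam

    genes = dataset.genes
    counts = dataset.counts
    chrom_len: dict[str, int] = {}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.end + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in sorted(chrom_len)],
    }
    tid = {c: i for i, c in enumerate(sorted(chrom_len))}
    adjacents = _adjacent_gene_runs(genes)
    expected = counts.frame.copy()
    read_len = 80

    def segment(qname, flag, chrom, pos, mate_chrom, mate_pos, tlen,
                mapq=60, tags=()):
        seg = pysam.AlignedSegment()
        seg.query_name = qname
        seg.flag = flag
        if chrom is not None:
            seg.reference_id = tid[chrom]
            seg.reference_start = pos
            seg.mapping_quality = mapq
            seg.cigartuples = [(0, read_len)]
        if mate_chrom is not None:
            seg.next_reference_id = tid[mate_chrom]
            seg.next_reference_start = mate_pos
        seg.template_length = tlen
        seg.query_sequence = "A" * read_len
        for tag, value in tags:
            seg.set_tag(tag, value)
        return seg

    def proper_pair(qname, chrom, p1, p2):
        """FR pair: mate1 forward at p1, mate2 reverse ending at p2+read_len."""
        tlen = p2 + read_len - p1
        return (
            segment(qname, 99, chrom, p1, chrom, p2, tlen),
            segment(qname, 147, chrom, p2, chrom, p1, -tlen),
        )

    for sample, rep in counts.frame.columns:
        path = sam_dir / f"{sample}_{rep}.sam"
        col = counts.frame[(sample, rep)]
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for g in genes:
                k = int(col.loc[g.gene_id])
                for j in range(k):
                    p1 = g.start
                    p2 = g.end - read_len
                    for seg in proper_pair(
                            f"{sample}.{rep}.{g.gene_id}.{j}", g.chrom, p1, p2):
                        fh.write(seg)
            for j in range(n_rule3):
                g1, g2 = adjacents[j % len(adjacents)]
                q = f"{sample}.{rep}.rule3.{j}"
                p1, p2 = g1.start, g2.end - read_len
                for seg in proper_pair(q, g1.chrom, p1, p2):
                    fh.write(seg)
                expected.loc[g1.gene_id, (sample, rep)] += 0.5
                expected.loc[g2.gene_id, (sample, rep)] += 0.5
            for j in range(n_decoys):
                _write_decoys(fh, segment, genes, adjacents,
                              f"{sample}.{rep}.decoy{j}", read_len)
    return expected


def _write_decoys(fh, segment, genes, adjacents, prefix, read_len):
    """Records that a correct filter rejects: one per rejection reason."""
    g = genes[0]
    chrom = g.chrom
    inter = g.end + 100  # intergenic: generator leaves 500 bp between genes
    # one mate on a gene, the other intergenic
    fh.write(segment(f"{prefix}.single", 99, chrom, g.start, chrom, inter,
                     inter - g.start + read_len))
    fh.write(segment(f"{prefix}.single", 147, chrom, inter, chrom, g.start,
                     -(inter - g.start + read_len)))
    # mate unmapped
    fh.write(segment(f"{prefix}.unmapped", 73, chrom, g.start, chrom,
                     g.start, 0))
    fh.write(segment(f"{prefix}.unmapped", 133, None, None, chrom, g.start, 0))
    # same gene, incoherent (same-strand) orientation
    fh.write(segment(f"{prefix}.ff", 65, chrom, g.start, chrom,
                     g.end - read_len, 0))
    fh.write(segment(f"{prefix}.ff", 129, chrom, g.end - read_len, chrom,
                     g.start, 0))
    # not best-unique: secondary alignment flag on one mate
    fh.write(segment(f"{prefix}.secondary", 99 | 0x100, chrom, g.start, chrom,
                     g.end - read_len, 0))
    fh.write(segment(f"{prefix}.secondary", 147, chrom, g.end - read_len,
                     chrom, g.start, 0))
    # alternative-hit tag (multi-mapper)
    fh.write(segment(f"{prefix}.xa", 99, chrom, g.start, chrom,
                     g.end - read_len, 0, tags=(("XA", "alt,+100,80M,0;"),)))
    fh.write(segment(f"{prefix}.xa", 147, chrom, g.end - read_len, chrom,
                     g.start, 0))
    # non-adjacent genes on one chromosome, if the layout offers them
    by_chrom = [x for x in genes if x.chrom == chrom]
    by_chrom.sort(key=lambda x: x.start)
    if len(by_chrom) >= 3:
        g1, g3 = by_chrom[0], by_chrom[2]
        fh.write(segment(f"{prefix}.nonadj", 99, chrom, g1.start, chrom,
                         g3.end - read_len, 0))
        fh.write(segment(f"{prefix}.nonadj", 147, chrom, g3.end - read_len,
                         chrom, g1.start, 0))
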