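# Methods

## Design and statistical model

`polyeld` analyses a parent/parent/hybrid RNA-seq design: an A-genome
diploid parent, a C-genome diploid parent, and their hybrid (or
allopolyploid), each with replicate libraries.  All inference is on
per-gene fragment counts against library totals.

**Differential testing.**  For a contrast between samples *x* and *y*,
replicates are pooled by summation and each gene is tested with a
two-sided Fisher's exact test on

```
[[ c_x , N_x − c_x ],
 [ c_y , N_y − c_y ]]
```

where *N* is the library size (total accepted fragments of the library).
The two-sided p-value sums hypergeometric probabilities no larger than the
observed table's (minimum-likelihood rule; ties tolerated at ~1e-7
relative).  P-values are Benjamini–Hochberg adjusted per comparison family
(all genes of one contrast), and a gene is called at adjusted *P* < alpha
(default 0.05), with sign from the library-normalized count difference.
Pooling replicates into one exact test per contrast assumes counting
(Poisson-like) noise only; no dispersion parameter is estimated.  This is
the classical FET mode of count-based DE tools, not a negative-binomial
GLM, and it is deliberate: the classification framework downstream is
defined on single significance calls per contrast.

**Library sizes.**  A count table built from SAM filtering defines each
library size as its column sum (the accepted fragments).  A table covering
only a subset of the transcriptome — notably simulated tables — instead
declares its library totals, which become the exact-test margins; each
individual count must fit inside its library.  The counts TSV carries
declared totals in `#library_size` header lines.

**Mid-parent value.**  The additivity null needs an MPV "sample" with
integer counts for the exact test.  Per gene, each parent's pooled count
is rescaled to the common reference library size L* = (N_A + N_C)/2, the
two rescaled counts are averaged and rounded half-up; the MPV library size
is L*.  Rounding half-up keeps the pseudo-counts unbiased to first order.

**Pattern taxonomy.**  Three signs are read per gene — hybrid vs A parent,
hybrid vs C parent, A vs C — where a directed sign means the two
confidence intervals are disjoint in that order and 0 means overlap.  Of
the 27 sign triples, exactly 19 are realizable by three real intervals
(the package verifies this by brute-force enumeration over interval
endpoint grids; a coarse integer grid is exhaustive because only the
ordering of endpoints matters).  The 19 patterns group into: equal to both
parents (VII, XI, XVII); equal to one parent with parents equal (III–VI);
expression level dominance (XII = A-dominant up, XIX = A-dominant down,
XVIII = C-dominant up, XIII = C-dominant down); intermediate (VIII, XIV);
transgressive up (I, IX, XV) and down (II, X, XVI).  Within groups the
numeral follows the canonical order s_pc = +, 0, −; only the groupings and
the four dominance numerals are pinned by the taxonomy, the rest is a
documented convention.  The 9 categories (a–i) are the grid of
hybrid-vs-MPV sign (rows: 0, +, −) by parental sign (columns: 0, +, −).
Dominance by construction requires parental difference (s_pc ≠ 0).

Genes expressed in at least one of the three samples are classified on
their actual counts (zeros included); a flag restricts the universe to
genes expressed in all three.

**Balance tests.**  A-dominance vs C-dominance counts, and transgressive
up vs down counts, are compared with a two-sided exact binomial test
against a 1:1 split; the raw counts are always reported alongside.  (A
t-test on two totals is not well defined; the exact binomial is the
natural test of a two-category count split.)

**Homoeolog bias.**  For each annotated A/C gene pair, the parental sign
compares the A copy in the A parent with the C copy in the C parent; the
hybrid sign compares the two copies within one hybrid library (same
library total on both margins).  Because these comparisons cross gene
models of different lengths, each copy's count is first rescaled to the
pair's mean length (rounded half-up); a pair with both adjusted counts
zero gets sign 0.  BH correction is applied per comparison family (all
pairs of one contrast), never globally across contrasts.  The sign pair
maps to nine categories (parental equal; maintained A/C bias; bias lost;
novel A/C bias; reversed), overall A-/C-bias totals (all pairs with hybrid
sign +/−), and a chi-square goodness-of-fit against 1:1 for subgenome
balance.  The pair universe keeps pairs whose copies are both expressed in
at least one sample of the contrast (`either`, default) or in every
sample (`all-samples`).

## Read filtering

The SAM filter joins mates by read name and accepts a pair only when both
mates are *best unique*: primary (not secondary/supplementary), mapped,
mapping quality ≥ a floor (default 1) and without an `XA` alternative-hit
tag.  Accepted pairs contribute:

- **rule 2** — both mates overlap the same gene with opposite strands
  (FR/RF): +1 to that gene;
- **rule 3** — the mates overlap two genes adjacent in start-coordinate
  order on one chromosome: +0.5 to each (the half-split avoids double
  counting; whether such pairs should instead count once per gene is not
  determined by the filter's definition, so the convention is surfaced in
  the acceptance log).

Everything else — single end on a gene, both ends intergenic, same-strand
same-gene pairs, non-adjacent genes, cross-chromosome pairs — is rejected
with a per-reason tally, and accepted + rejected = pairs examined.
Adjacency ignores strand and intergenic distance.  A mate overlaps a gene
at ≥ 1 bp intersection; ties go to the larger overlap, then the smaller
gene id.  Fractional counts (multiples of 0.5) are rounded half-up before
any exact test.  Coordinates are 0-based half-open internally; GFF3 input
and output shift by one base, BED is native.  Subgenome labels come from a
`subgenome` GFF3 attribute or the chromosome initial (A01…/C01…).

## Synthetic data

The generator emulates the design the analysis assumes: samples AA1, AA2,
CC, AC1, AC2 (two A parents crossed to one shared C parent), n replicates
each (default 2), ~half the genes organized as homoeologous A/C pairs with
symmetric cross-subgenome links.  Each gene or pair draws one truth class
fixing its mean in (A parent, C parent, hybrid):

| class               | A      | C      | hybrid           |
|---------------------|--------|--------|------------------|
| additive_equal      | m      | m      | m                |
| additive_parentdiff | m·f/m  | m/m·f  | (m·f + m)/2      |
| eld_A_up            | m·f    | m      | m·f              |
| eld_A_down          | m      | m·f    | m                |
| eld_C_up            | m      | m·f    | m·f              |
| eld_C_down          | m·f    | m      | m                |
| transgressive_up    | m      | m      | m·f              |
| transgressive_down  | m      | m      | m/f              |
| novel_bias          | m      | m      | one copy at m·f  |
| silent              | 0      | 0      | 0                |

with m = `mean_expression`, f = `effect_fold`, directions alternating
deterministically for the symmetric classes.  Counts are gamma-Poisson
(negative binomial, var = μ + φμ²); φ defaults to 0 (pure Poisson) because
replicates are pooled into a single exact test whose null assumes counting
noise only — φ is an explicit knob for studying the consequences of
overdispersion, not part of the default conditions.  Replicates share the
gene-level mean (no biological-variance term).  Means scale with each
library's configured size relative to the mean configured size.  Truth
labels are assigned before sampling; genes whose sampled counts are all
zero are relabelled `silent` post hoc.  `novel_bias` requires a partner,
so singleton genes fold that mass into `additive_equal`.

Defaults: 20 000 genes, 50 % paired, libraries of 10⁶ fragments, mean 50,
fold 4, seed 0, and a mixture (40 % silent, 30 % additive-equal, 20 %
parental-difference additive, 2 % per dominance form, 0.5 %/0.2 %
transgressive up/down, 1.3 % novel bias) shaped like a leaf transcriptome
in which roughly half the expressed genes diverge between parents,
dominance is balanced across forms, and transgressive-up exceeds
transgressive-down.  Tests and the acceptance suite use smaller gene
counts (10³–10⁴) chosen so each check completes in seconds to a couple of
minutes while keeping binomial standard errors far below the tested
margins.

What the generator does **not** emulate: biological replicate variance,
subgenome-of-origin read assignment (each gene has a mean in every sample;
cross-mapping and homoeologous exchange are out of scope), length-biased
fragment sampling (homoeolog partners share their gene length, so the
pair-mean length adjustment is exactly the identity on simulated pairs),
and maintained parental bias in the hybrid (both pair members share the
gene-level hybrid mean, so planted parental divergence surfaces as bias
*lost*; within-hybrid bias is planted only through `novel_bias`).  Passing
recovery tests therefore show correctness of the inference machinery under
the stated noise model, not robustness to overdispersion or mapping
artifacts.

The SAM fixtures realize each planted count as rule-2 pairs fully inside
the gene; optional extra records add adjacent-gene (rule-3) pairs, whose
0.5/0.5 contributions are returned to the caller, and decoy records that a
correct filter must reject (unmapped mate, secondary-only mate, `XA`
multi-mapper, same-strand pair, single end on gene, non-adjacent genes).

## Numerical choices and degenerate inputs

- Exact tests delegate to `scipy.stats.fisher_exact`; BH to
  `statsmodels.stats.multitest.multipletests`.  Both are cross-checked in
  the test suite against independent oracles (exhaustive fixed-margin
  enumeration; the literal step-up formula).
- Per-contrast FET results are memoized on the count pair, which collapses
  the many low-count repeats of a transcriptome.
- `percent` rounds half-up at one decimal (configurable); integer averages
  use the floor.  Raw ratios are kept alongside rounded percentages in the
  report so rounding never compounds.
- A contrast in which no gene is expressed is an error; a gene expressed
  in neither sample of a contrast is excluded from that family.
- `c₁ = c₂ = 0` short-circuits to p = 1.
- Report JSON is byte-deterministic for a fixed configuration; stage
  timings go to a separate `timings.json`.

## Known limitations

- The FET-on-pooled-counts model understates variability whenever true
  biological dispersion is present; calls on real replicated data are
  anti-conservative compared to NB-GLM tools.  This mirrors the analysis
  framework the package implements rather than a recommendation.
- Gene length is annotation span, not exonic length; FPKM values shift
  accordingly.
- BAM/CRAM, spliced-alignment awareness, duplicate marking and
  SNP-aware homoeolog read phasing are out of scope; counts are assumed
  already per-subgenome-copy.
- The within-group numbering of patterns beyond the pinned dominance
  numerals is a convention of this package; comparisons with other
  implementations should use the groupings, not raw numerals.
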