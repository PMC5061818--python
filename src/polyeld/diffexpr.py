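"""FPKM quantification and Fisher's-exact differential testing.

Differential expression between two libraries is assessed per gene with a
two-sided Fisher's exact test on the 2x2 table

    [[count_x, lib_x - count_x],
     [count_y, lib_y - count_y]]

replicates being pooled by summation beforehand (a single test per contrast,
as in DEGseq's FET mode on pooled lanes).  Raw p-values are adjusted across
genes with the Benjamini-Hochberg step-up procedure and a gene is called
differential when the adjusted value falls below ``alpha`` (default 0.05).
The three-valued sign (+/0/-) is + when sample x is significantly higher
after library-size normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, round_half_up

__all__ = [
    "fpkm",
    "fisher_exact_two_sided",
    "bh_adjust",
    "contrast_signs",
    "differential_contrast",
    "mpv_pseudo_sample",
]


def fpkm(count, gene_length_bp, library_size):
    """Fragments per kilobase of gene model per million mapped fragments.

    ``count * 1e9 / (library_size * gene_length_bp)``; a gene is *expressed*
    iff its FPKM is > 0, i.e. iff its count is > 0.
    """
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    out = np.asarray(count, dtype=float) * 1e9 / (lib * length)
    if np.ndim(count) == 0 and np.ndim(out) == 0:
        return float(out)
    return out


def fisher_exact_two_sided(c1: int, n1: int, c2: int, n2: int) -> float:
    """Two-sided FET p-value for one gene's counts against two library totals.

    The p-value sums hypergeometric probabilities no larger than that of the
    observed table (minimum-likelihood two-sided rule, with a ~1e-7 relative
    tolerance for ties).
    """
    c1, n1, c2, n2 = int(c1), int(n1), int(c2), int(n2)
    if min(c1, c2) < 0 or c1 > n1 or c2 > n2:
        raise ValueError("need 0 <= c <= n for both samples")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if c1 == 0 and c2 == 0:
        return 1.0
    return float(
        stats.fisher_exact([[c1, n1 - c1], [c2, n2 - c2]]).pvalue
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fet_vector(cx: np.ndarray, nx: int, cy: np.ndarray, ny: int) -> np.ndarray:
    """Per-gene two-sided FET against fixed library totals, with caching.

    Low-count genes repeat the same (cx, cy) cell many times across a
    transcriptome; memoizing on the cell pair avoids recomputation.
    """
    cache: dict[tuple[int, int], float] = {}
    out = np.empty(len(cx), dtype=float)
    for i, (a, b) in enumerate(zip(cx, cy)):
        key = (int(a), int(b))
        p = cache.get(key)
        if p is None:
            p = fisher_exact_two_sided(key[0], nx, key[1], ny)
            cache[key] = p
        out[i] = p
    return out


def contrast_signs(
    counts_x: pd.Series,
    lib_x: float,
    counts_y: pd.Series,
    lib_y: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """FET + BH over a family of genes; returns p, q and the three-valued sign.

    The BH family is exactly the genes supplied here (one comparison family
    per contrast).  Sign is non-zero iff q < alpha, with direction from the
    library-size-normalized count difference.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cx = round_half_up(counts_x.values)
    cy = round_half_up(counts_y.values)
    nx, ny = int(round_half_up(lib_x)), int(round_half_up(lib_y))
    p = _fet_vector(cx, nx, cy, ny)
    q = bh_adjust(p)
    diff = cx / nx - cy / ny
    sign = np.where(q < alpha, np.sign(diff).astype(int), 0)
    return pd.DataFrame(
        {"count_x": cx, "count_y": cy, "p": p, "q": q, "sign": sign},
        index=counts_x.index,
    )


def differential_contrast(
    counts: CountTable,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """One DiffCall per gene expressed in at least one of the two samples.

    Replicates are pooled by summation; genes expressed in neither sample are
    excluded from the comparison family.  If ``lengths`` is given, FPKM
    columns are added for both samples.
    """
    x, y = contrast
    pooled_x, pooled_y = counts.pooled(x), counts.pooled(y)
    universe = counts.gene_ids[(pooled_x > 0) | (pooled_y > 0)]
    if len(universe) == 0:
        raise ValueError(f"no gene expressed in either sample of {x} vs {y}")
    lib_x, lib_y = counts.library_size(x), counts.library_size(y)
    res = contrast_signs(pooled_x.loc[universe], lib_x,
                         pooled_y.loc[universe], lib_y, alpha=alpha)
    res.insert(0, "contrast", f"{x}:{y}")
    if lengths is not None:
        lens = lengths.reindex(universe)
        res["fpkm_x"] = fpkm(res["count_x"].values, lens.values, lib_x)
        res["fpkm_y"] = fpkm(res["count_y"].values, lens.values, lib_y)
    return res


def mpv_pseudo_sample(
    counts: CountTable, a_sample: str, c_sample: str
) -> tuple[pd.Series, int]:
    """Mid-parent-value pseudo-library: integer counts plus its library size.

    Each parent's pooled count is rescaled to the common reference library
    size L* (the mean of the two parental library sizes), the two rescaled
    counts are averaged per gene, and the result is rounded half-up so the
    pseudo-sample can enter an exact test.  Returns ``(counts, L*)``.
    """
    lib_a = counts.library_size(a_sample)
    lib_c = counts.library_size(c_sample)
    if lib_a <= 0 or lib_c <= 0:
        raise ValueError("parental library sizes must be positive")
    lib_star = (lib_a + lib_c) / 2.0
    scaled = (counts.pooled(a_sample) * lib_star / lib_a
              + counts.pooled(c_sample) * lib_star / lib_c) / 2.0
    mpv = pd.Series(round_half_up(scaled.values), index=scaled.index)
    return mpv, int(round_half_up(lib_star))
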