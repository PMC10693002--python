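"""Between-population divergence over sliding windows.

For each population pair (one replicate block: FC vs NC), SNPs are called
on the pooled read counts of both populations jointly, and each window
receives

* a π-based FST, (π_total − π_within)/π_total, with π_within the mean of
  the two within-population read heterozygosities and π_total the read
  heterozygosity of the pooled counts, each averaged over the window's
  SNP sites (slightly negative values are reported as-is);
* a Fisher score: the mean over SNPs of −log10 of the two-sided Fisher
  exact p for the 2×2 major/minor read-count table.

The replicate-consistency screen multiplies the two blocks' Fisher scores
per window and flags the top 0.5% as outliers, so a window must diverge in
*both* blocks to be selected — divergence in one block only (drift, or
block-private selection) is attenuated by the product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diversity import DiversityParams, SiteCalls, call_sites
from .io_formats import ACGT_IDX, SyncTable

__all__ = [
    "fisher_exact_two_sided",
    "PairCalls",
    "pair_snp_calls",
    "pair_divergence",
    "window_fst",
    "window_fisher_score",
    "consistency_screen",
]


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The p-value is the total hypergeometric probability of all tables with
    the observed margins whose point probability does not exceed the
    observed one (the standard two-sided convention).  Zero-margin tables
    return p = 1.
    """
    M = a + b + c + d
    n_good = a + c  # column-1 total
    N = a + b  # row-1 total
    if M == 0 or n_good in (0, M) or N in (0, M):
        return 1.0
    lo = max(0, N - (M - n_good))
    hi = min(n_good, N)
    k = np.arange(lo, hi + 1)
    logp = (
        _log_comb(np.float64(n_good), k)
        + _log_comb(np.float64(M - n_good), N - k)
        - _log_comb(np.float64(M), np.float64(N))
    )
    obs = logp[a - lo]
    p = float(np.exp(logp[logp <= obs + 1e-7]).sum())
    return min(p, 1.0)


@dataclass
class PairCalls:
    """Joint SNP calls for one population pair on a common site grid.

    Arrays are over the pair's SNP sites only.  ``maj_a``/``min_a`` etc.
    are read counts of the pair-wise major and minor allele (defined on
    the summed counts) in each population.
    """

    site_index: np.ndarray  # row index into the SyncTable
    chrom: np.ndarray
    pos: np.ndarray
    maj_a: np.ndarray
    min_a: np.ndarray
    maj_b: np.ndarray
    min_b: np.ndarray


def pair_snp_calls(
    table: SyncTable,
    pop_a: int,
    pop_b: int,
    params: DiversityParams | None = None,
    calls: SiteCalls | None = None,
) -> PairCalls:
    """Call biallelic SNPs jointly for two populations.

    A site qualifies when coverage is valid in *both* populations and the
    summed counts carry at least ``min_count`` reads of a second allele;
    counts are collapsed to the two most frequent alleles of the sum.
    """
    params = params or DiversityParams()
    if calls is None:
        calls = call_sites(table, params)
    acgt = table.counts[:, :, list(ACGT_IDX)]
    comb = acgt[:, pop_a, :] + acgt[:, pop_b, :]
    order = np.argsort(comb, axis=1)
    maj = order[:, 3]
    mnr = order[:, 2]
    rows = np.arange(table.n_sites)
    min_comb = comb[rows, mnr]
    snp = calls.valid[:, pop_a] & calls.valid[:, pop_b] & (min_comb >= params.min_count)
    idx = np.nonzero(snp)[0]
    return PairCalls(
        site_index=idx,
        chrom=table.chrom[idx],
        pos=table.pos[idx],
        maj_a=acgt[idx, pop_a, maj[idx]],
        min_a=acgt[idx, pop_a, mnr[idx]],
        maj_b=acgt[idx, pop_b, maj[idx]],
        min_b=acgt[idx, pop_b, mnr[idx]],
    )


def _pi_two(maj: np.ndarray, mnr: np.ndarray) -> np.ndarray:
    C = (maj + mnr).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = 1.0 - (maj**2 + mnr**2) / C**2
        pi = np.where(C > 1, C / (C - 1.0) * het, 0.0)
    return pi


def pair_divergence(
    table: SyncTable,
    pop_a: int,
    pop_b: int,
    params: DiversityParams | None = None,
    window_size: int = 500,
    step: int = 250,
    agg: str = "mean",
    calls: SiteCalls | None = None,
) -> pd.DataFrame:
    """FST and Fisher score per sliding window for one population pair.

    Returns one row per window that contains at least one SNP, with
    columns chrom, start, end, n_snps, fst, fisher_score.
    """
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    if window_size % step != 0:
        raise ValueError("window_size must be a multiple of step")
    pc = pair_snp_calls(table, pop_a, pop_b, params, calls=calls)

    pi_a = _pi_two(pc.maj_a, pc.min_a)
    pi_b = _pi_two(pc.maj_b, pc.min_b)
    pi_t = _pi_two(pc.maj_a + pc.maj_b, pc.min_a + pc.min_b)
    pi_w = 0.5 * (pi_a + pi_b)

    neglogp = np.empty(len(pc.pos))
    for i in range(len(pc.pos)):
        p = fisher_exact_two_sided(
            int(pc.maj_a[i]), int(pc.min_a[i]), int(pc.maj_b[i]), int(pc.min_b[i])
        )
        neglogp[i] = -math.log10(max(p, 5e-324))

    n_shifts = window_size // step
    frames = []
    for shift in range(n_shifts):
        start = (pc.pos - shift * step) // window_size * window_size + shift * step
        sel = start >= 0
        df = pd.DataFrame(
            {
                "chrom": pc.chrom[sel],
                "start": start[sel],
                "pi_t": pi_t[sel],
                "pi_w": pi_w[sel],
                "neglogp": neglogp[sel],
            }
        )
        g = df.groupby(["chrom", "start"], sort=False).agg(
            n_snps=("neglogp", "size"),
            pi_t=("pi_t", "mean"),
            pi_w=("pi_w", "mean"),
            score_sum=("neglogp", "sum"),
            score_mean=("neglogp", "mean"),
        )
        frames.append(g.reset_index())
    out = pd.concat(frames, ignore_index=True)
    out["end"] = out["start"] + window_size
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fst"] = np.where(out["pi_t"] > 0, (out["pi_t"] - out["pi_w"]) / out["pi_t"], np.nan)
    out["fisher_score"] = out["score_mean"] if agg == "mean" else out["score_sum"]
    return out[
        ["chrom", "start", "end", "n_snps", "fst", "fisher_score"]
    ].sort_values(["chrom", "start"], ignore_index=True)


def window_fst(table, pop_a, pop_b, params=None, window_size=500, step=250, calls=None):
    """Windowed FST only (see :func:`pair_divergence`)."""
    df = pair_divergence(table, pop_a, pop_b, params, window_size, step, calls=calls)
    return df[["chrom", "start", "end", "n_snps", "fst"]]


def window_fisher_score(table, pop_a, pop_b, params=None, window_size=500, step=250,
                        agg="mean", calls=None):
    """Windowed Fisher score only (see :func:`pair_divergence`)."""
    df = pair_divergence(table, pop_a, pop_b, params, window_size, step, agg, calls=calls)
    return df[["chrom", "start", "end", "n_snps", "fisher_score"]]


def consistency_screen(
    windows_block1: pd.DataFrame,
    windows_block2: pd.DataFrame,
    top: float = 0.005,
) -> pd.DataFrame:
    """Cross-replicate product screen over a shared window grid.

    Only windows scored in both blocks participate.  The product of the
    two Fisher scores is ranked; the top ⌈top·W⌉ windows (ties broken by
    the larger single-block score, then coordinate) are flagged
    ``outlier``.  Windows with a zero score in either block can never be
    outliers.  Raises ``ValueError`` when the two grids do not match.
    """
    need = {"chrom", "start", "end", "fisher_score"}
    for df in (windows_block1, windows_block2):
        if not need.issubset(df.columns):
            raise ValueError(f"window tables need columns {sorted(need)}")
    w1 = windows_block1[["chrom", "start", "end", "fst", "fisher_score"]].copy() \
        if "fst" in windows_block1 else windows_block1[list(need)].copy()
    w2 = windows_block2[["chrom", "start", "end", "fst", "fisher_score"]].copy() \
        if "fst" in windows_block2 else windows_block2[list(need)].copy()
    size1 = (w1["end"] - w1["start"]).max()
    size2 = (w2["end"] - w2["start"]).max()
    if size1 != size2:
        raise ValueError("window grids disagree (different window sizes)")
    merged = w1.merge(w2, on=["chrom", "start", "end"], suffixes=("_1", "_2"), how="inner")
    if merged.empty:
        raise ValueError("window grids share no windows")
    merged["product_score"] = merged["fisher_score_1"] * merged["fisher_score_2"]
    merged["max_single"] = np.maximum(merged["fisher_score_1"], merged["fisher_score_2"])
    W = len(merged)
    k = math.ceil(top * W)
    order = merged.sort_values(
        ["product_score", "max_single", "chrom", "start"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    outlier_idx = order.index[:k]
    merged["outlier"] = False
    merged.loc[outlier_idx, "outlier"] = True
    merged.loc[merged["product_score"] <= 0, "outlier"] = False
    merged["percentile_rank"] = merged["product_score"].rank(pct=True)
    return merged.sort_values(["chrom", "start"], ignore_index=True)


def outlier_bed(screen: pd.DataFrame) -> pd.DataFrame:
    """BED-style frame (chrom, start, end, product_score) of outlier windows."""
    out = screen[screen["outlier"]][["chrom", "start", "end", "product_score"]]
    return out.sort_values(["chrom", "start"], ignore_index=True)
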