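"""Within-population diversity from pooled read counts.

Reads are treated as the sample: at a site with read counts c_a over the
four nucleotides and coverage C = Σ c_a, the per-site heterozygosity is the
average pairwise difference among reads,

    π̂ = C/(C−1) · (1 − Σ_a (c_a/C)²),

Watterson's θ per window is the count of segregating sites weighted by
1/a1(C) (a1 the harmonic number of the sample size), and Tajima's D is
computed on counts subsampled without replacement to a uniform depth n*
so that the Tajima (1989) normalising constants are well defined.

Coverage filters (40–700 by default), the minor-allele read minimum for
calling a SNP, and the minimum covered fraction a window must reach in
every population are all explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ACGT_IDX, GeneModel, SyncTable

__all__ = [
    "DiversityParams",
    "SiteCalls",
    "site_pi",
    "harmonic",
    "tajima_constants",
    "tajima_d_stat",
    "call_sites",
    "window_theta_pi",
    "window_tajima_d",
    "compare_windows",
    "filter_windows_by_genes",
]


@dataclass
class DiversityParams:
    """Site-filtering parameters shared by all diversity statistics."""

    min_cov: int = 40
    max_cov: int = 700
    min_count: int = 2
    min_covered_fraction: float = 0.6

    def validate(self) -> None:
        if self.max_cov < self.min_cov:
            raise ValueError("max_cov must be >= min_cov")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0.0 <= self.min_covered_fraction <= 1.0:
            raise ValueError("min_covered_fraction must lie in [0, 1]")


def harmonic(n: int | np.ndarray) -> np.ndarray:
    """a1(n) = Σ_{i=1}^{n−1} 1/i, vectorised (0 for n < 2)."""
    n = np.asarray(n)
    nmax = int(n.max()) if n.size else 2
    table = np.concatenate([[0.0, 0.0], np.cumsum(1.0 / np.arange(1, max(nmax, 2)))])
    return table[n]


class TajimaConstants(NamedTuple):
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Tajima (1989) normalising constants for sample size n (n >= 2)."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d_stat(pi_w, S, n_star: int):
    """Tajima's D from window sums: (π_w − S/a1) / sqrt(e1·S + e2·S(S−1)).

    ``pi_w`` is the window sum of per-site heterozygosities at uniform
    sample size ``n_star``; NaN where S = 0.
    """
    const = tajima_constants(n_star)
    pi_w = np.asarray(pi_w, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    theta_w = S / const.a1
    var = const.e1 * S + const.e2 * S * (S - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(S > 0, (pi_w - theta_w) / np.sqrt(var), np.nan)
    return d if d.ndim else float(d)


def site_pi(counts: np.ndarray) -> np.ndarray | float:
    """Average pairwise difference among reads at one or many sites.

    ``counts`` is a length-6 sync sextuple or an (n, 6) array (only the
    A/T/C/G columns enter).  Sites with fewer than two reads return NaN.
    """
    arr = np.asarray(counts, dtype=np.float64)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    acgt = arr[:, list(ACGT_IDX)]
    C = acgt.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = 1.0 - np.sum((acgt / C[:, None]) ** 2, axis=1)
        pi = C / (C - 1.0) * het
    pi[C < 2] = np.nan
    return float(pi[0]) if squeeze else pi


@dataclass
class SiteCalls:
    """Per-site, per-population calling results on a :class:`SyncTable`.

    All arrays are (n_sites, n_pops).  ``major``/``minor`` are ACGT column
    indices of the two most frequent alleles; sites with more than two
    alleles at or above ``min_count`` are collapsed to those two and
    flagged ``multiallelic``.  ``pi`` is the read heterozygosity of the
    collapsed counts at SNP sites and 0 at valid non-SNP sites.
    """

    table: SyncTable
    params: DiversityParams
    depth: np.ndarray
    valid: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    major_count: np.ndarray
    minor_count: np.ndarray
    is_snp: np.ndarray
    multiallelic: np.ndarray
    pi: np.ndarray

    @property
    def collapsed_depth(self) -> np.ndarray:
        return self.major_count + self.minor_count


def call_sites(table: SyncTable, params: DiversityParams | None = None) -> SiteCalls:
    """Apply coverage and minor-count filters to every site × population."""
    params = params or DiversityParams()
    params.validate()
    acgt = table.counts[:, :, list(ACGT_IDX)]
    depth = acgt.sum(axis=2)
    valid = (depth >= params.min_cov) & (depth <= params.max_cov)

    order = np.argsort(acgt, axis=2)  # ascending
    major = order[:, :, 3]
    minor = order[:, :, 2]
    major_count = np.take_along_axis(acgt, major[:, :, None], axis=2)[:, :, 0]
    minor_count = np.take_along_axis(acgt, minor[:, :, None], axis=2)[:, :, 0]
    n_above = (acgt >= params.min_count).sum(axis=2)
    multiallelic = n_above > 2
    is_snp = valid & (minor_count >= params.min_count)

    C2 = (major_count + minor_count).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = 1.0 - (major_count**2 + minor_count**2) / C2**2
        pi = np.where(C2 > 1, C2 / (C2 - 1.0) * het, 0.0)
    pi = np.where(is_snp, pi, 0.0)
    return SiteCalls(
        table=table, params=params, depth=depth, valid=valid, major=major,
        minor=minor, major_count=major_count, minor_count=minor_count,
        is_snp=is_snp, multiallelic=multiallelic, pi=pi,
    )


def _window_index(pos: np.ndarray, size: int) -> np.ndarray:
    return pos // size


def _chrom_lengths(table: SyncTable, chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    if chrom_lengths is not None:
        return chrom_lengths
    out: dict[str, int] = {}
    for chrom in pd.unique(table.chrom):
        out[str(chrom)] = int(table.pos[table.chrom == chrom].max()) + 1
    return out


def window_theta_pi(
    table: SyncTable,
    params: DiversityParams | None = None,
    window_size: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
    calls: SiteCalls | None = None,
) -> pd.DataFrame:
    """π and Watterson's θ per nonoverlapping window per population.

    Returns one row per (window, population) with columns chrom, start,
    end, pop, n_valid, S, pi, theta_w, covered_fraction and the
    window-level ``usable`` flag (covered fraction reached in *every*
    population).  The window grid is anchored at coordinate 0; a trailing
    partial window is judged on its actual length.
    """
    params = params or DiversityParams()
    calls = calls or call_sites(table, params)
    lengths = _chrom_lengths(table, chrom_lengths)

    win = _window_index(table.pos, window_size)
    n_pops = table.n_pops
    frames = []
    # per-site contributions: theta weight 1/a1(C2) at SNP sites
    a1 = harmonic(np.maximum(calls.collapsed_depth, 2))
    with np.errstate(divide="ignore"):
        theta_site = np.where(calls.is_snp & (a1 > 0), 1.0 / np.where(a1 > 0, a1, 1.0), 0.0)
    for p in range(n_pops):
        df = pd.DataFrame(
            {
                "chrom": table.chrom,
                "win": win,
                "valid": calls.valid[:, p].astype(np.int64),
                "snp": (calls.is_snp[:, p]).astype(np.int64),
                "pi": calls.pi[:, p],
                "theta": theta_site[:, p],
            }
        )
        g = df.groupby(["chrom", "win"], sort=True).agg(
            n_valid=("valid", "sum"), S=("snp", "sum"),
            pi_sum=("pi", "sum"), theta_sum=("theta", "sum"),
        )
        g["pop"] = table.pops[p]
        frames.append(g.reset_index())
    out = pd.concat(frames, ignore_index=True)
    out["start"] = out["win"] * window_size
    out["end"] = np.minimum(
        out["start"] + window_size,
        out["chrom"].map(lengths).astype(np.int64),
    )
    wlen = (out["end"] - out["start"]).astype(np.float64)
    out["covered_fraction"] = out["n_valid"] / wlen
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pi"] = np.where(out["n_valid"] > 0, out["pi_sum"] / out["n_valid"], np.nan)
        out["theta_w"] = np.where(out["n_valid"] > 0, out["theta_sum"] / out["n_valid"], np.nan)
    ok = (
        out.groupby(["chrom", "win"])["covered_fraction"]
        .transform("min")
        >= params.min_covered_fraction
    )
    npop_seen = out.groupby(["chrom", "win"])["pop"].transform("count")
    out["usable"] = ok & (npop_seen == n_pops)
    return out[
        ["chrom", "start", "end", "pop", "n_valid", "S", "pi", "theta_w",
         "covered_fraction", "usable"]
    ].sort_values(["chrom", "start", "pop"], ignore_index=True)


def subsample_minor_counts(
    calls: SiteCalls, n_star: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric subsample of each site's collapsed counts to n*.

    Returns (ok, k): ``ok`` marks sites with collapsed depth ≥ n* that are
    coverage-valid; ``k`` is the subsampled minor-allele count (0 wherever
    not ok or not a SNP).
    """
    C2 = calls.collapsed_depth
    ok = calls.valid & (C2 >= n_star)
    k = np.zeros_like(calls.minor_count)
    sel = ok & calls.is_snp
    if sel.any():
        k_sel = rng.hypergeometric(
            ngood=calls.minor_count[sel], nbad=calls.major_count[sel], nsample=n_star
        )
        k[sel] = k_sel
    return ok, k


def window_tajima_d(
    table: SyncTable,
    params: DiversityParams | None = None,
    window_size: int = 500,
    step: int = 250,
    n_star: int = 40,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    calls: SiteCalls | None = None,
) -> pd.DataFrame:
    """Tajima's D over sliding windows at uniform subsampled depth n*.

    Every coverage-valid site with at least n* reads over its two most
    frequent alleles is subsampled without replacement to n*; a site counts
    as segregating when the subsample still contains both alleles.  With S
    segregating sites, window sums π_w and θ_w = S/a1(n*),

        D = (π_w − θ_w) / sqrt(e1·S + e2·S·(S−1)),

    undefined (NaN) when S = 0.  The subsample is deterministic under
    ``seed``.
    """
    params = params or DiversityParams()
    calls = calls or call_sites(table, params)
    lengths = _chrom_lengths(table, chrom_lengths)
    const = tajima_constants(n_star)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(777,)))
    ok, k = subsample_minor_counts(calls, n_star, rng)

    kf = k.astype(np.float64)
    pi_site = (
        n_star / (n_star - 1.0)
        * (1.0 - (kf / n_star) ** 2 - ((n_star - kf) / n_star) ** 2)
    )
    pi_site = np.where(ok, pi_site, 0.0)
    seg = ok & (k >= 1) & (k <= n_star - 1)

    if window_size % step != 0:
        raise ValueError("window_size must be a multiple of step")
    n_shifts = window_size // step
    frames = []
    for p in range(table.n_pops):
        for shift in range(n_shifts):
            start = (table.pos - shift * step) // window_size * window_size + shift * step
            sel = start >= 0
            df = pd.DataFrame(
                {
                    "chrom": table.chrom[sel],
                    "start": start[sel],
                    "valid": ok[sel, p].astype(np.int64),
                    "S": seg[sel, p].astype(np.int64),
                    "pi_w": pi_site[sel, p],
                }
            )
            g = df.groupby(["chrom", "start"], sort=False).agg(
                n_valid=("valid", "sum"), S=("S", "sum"), pi_w=("pi_w", "sum")
            )
            g["pop"] = table.pops[p]
            frames.append(g.reset_index())
    out = pd.concat(frames, ignore_index=True)
    out["end"] = np.minimum(
        out["start"] + window_size, out["chrom"].map(lengths).astype(np.int64)
    )
    out["theta_w"] = out["S"] / const.a1
    out["tajima_d"] = tajima_d_stat(out["pi_w"].to_numpy(), out["S"].to_numpy(), n_star)
    wlen = (out["end"] - out["start"]).astype(np.float64)
    out["covered_fraction"] = out["n_valid"] / wlen
    grp = out.groupby(["chrom", "start"])
    ok_w = grp["covered_fraction"].transform("min") >= params.min_covered_fraction
    npop_seen = grp["pop"].transform("count")
    out["usable"] = ok_w & (npop_seen == table.n_pops)
    return out[
        ["chrom", "start", "end", "pop", "n_valid", "S", "pi_w", "theta_w",
         "tajima_d", "covered_fraction", "usable"]
    ].sort_values(["chrom", "start", "pop"], ignore_index=True)


def filter_windows_by_genes(
    windows: pd.DataFrame, genes: Sequence[GeneModel], flank: int = 5000
) -> pd.DataFrame:
    """Keep windows overlapping any of the given genes ± flank (≥ 1 bp)."""
    keep = np.zeros(len(windows), dtype=bool)
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        ivs = sorted(
            (max(0, g.start - flank), g.end + flank)
            for g in genes
            if g.chrom == chrom
        )
        if not ivs:
            continue
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged)
        sel = chroms == chrom
        idx = np.searchsorted(arr[:, 1], starts[sel], side="right")
        hit = (idx < len(arr)) & (arr[np.minimum(idx, len(arr) - 1), 0] < ends[sel])
        keep[sel] = hit
    return windows[keep]


def compare_windows(
    stats_a,
    stats_b,
    test: str = "kruskal_wallis",
    region_filter: tuple[Sequence[GeneModel], int] | None = None,
    value_column: str | None = None,
) -> tuple[float, float]:
    """Compare matched window statistics between two populations.

    ``stats_a``/``stats_b`` are either plain value sequences or window
    DataFrames (then ``value_column`` selects the statistic and
    ``region_filter=(genes, flank)`` restricts to windows overlapping the
    given genes ± flank).  Returns (statistic, p): Kruskal–Wallis H with
    its χ²(1) p-value, or Welch's t.
    """
    def extract(x):
        if isinstance(x, pd.DataFrame):
            if value_column is None:
                raise ValueError("value_column required with DataFrame input")
            df = x
            if region_filter is not None:
                genes, flank = region_filter
                df = filter_windows_by_genes(df, genes, flank)
            return df[value_column].to_numpy(dtype=np.float64)
        return np.asarray(x, dtype=np.float64)

    a = extract(stats_a)
    b = extract(stats_b)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 windows per group")
    if test == "kruskal_wallis":
        if np.array_equal(a, b) and np.all(a == a[0]):
            return 0.0, 1.0
        res = sps.kruskal(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
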