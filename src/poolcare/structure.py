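"""Population-structure summaries from pool allele frequencies.

The scaled covariance Ω of population allele frequencies summarises the
populations' shared drift history: each SNP's frequency vector is centred
on the across-population mean p̄ and scaled by sqrt(p̄(1−p̄)), and Ω is the
average outer product over SNPs.  The derived correlation matrix is
visualised as a UPGMA tree on the distance 1 − correlation; populations
with a shared history (here: the two populations of a replicate block,
which share a founder draw) cluster together.

This moment estimator deliberately ignores pool-sequencing sampling noise
in the frequency estimates; at the depths used here (≈100×, filtered at
40) that term is second order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .diversity import DiversityParams, SiteCalls, call_sites
from .io_formats import ACGT_IDX, SyncTable

__all__ = [
    "OmegaMatrix",
    "population_frequencies",
    "omega_matrix",
    "correlation_tree",
]


@dataclass
class OmegaMatrix:
    """Scaled covariance of population allele frequencies."""

    omega: np.ndarray  # (P, P)
    pops: list[str]
    n_snps: int

    @property
    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.omega))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = self.omega / np.outer(d, d)
        corr = np.where(np.isfinite(corr), corr, 1.0)
        np.fill_diagonal(corr, 1.0)
        return np.clip(corr, -1.0, 1.0)


def population_frequencies(
    table: SyncTable,
    params: DiversityParams | None = None,
    calls: SiteCalls | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-allele frequency matrix (SNPs × populations).

    SNPs are biallelic sites (two most frequent alleles of the pooled
    counts across populations, minor total ≥ min_count) that pass the
    coverage filter in every population.  The returned frequency is that
    of the across-population major allele.  Also returns the row indices
    of the retained sites in ``table``.
    """
    params = params or DiversityParams()
    if calls is None:
        calls = call_sites(table, params)
    acgt = table.counts[:, :, list(ACGT_IDX)]
    comb = acgt.sum(axis=1)
    order = np.argsort(comb, axis=1)
    maj = order[:, 3]
    mnr = order[:, 2]
    rows = np.arange(table.n_sites)
    keep = calls.valid.all(axis=1) & (comb[rows, mnr] >= params.min_count)
    idx = np.nonzero(keep)[0]
    P = table.n_pops
    pop_ax = np.arange(P)[None, :]
    maj_counts = acgt[idx[:, None], pop_ax, maj[idx][:, None]]
    mnr_counts = acgt[idx[:, None], pop_ax, mnr[idx][:, None]]
    tot = (maj_counts + mnr_counts).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(tot > 0, maj_counts / tot, np.nan)
    ok = ~np.isnan(freq).any(axis=1)
    return freq[ok], idx[ok]


def omega_matrix(
    freqs: np.ndarray, pops: list[str] | None = None, min_snps: int = 100
) -> OmegaMatrix:
    """Moment estimate of Ω from a (SNPs × populations) frequency matrix.

    Each SNP j is standardised as (p_ij − p̄_j)/sqrt(p̄_j(1−p̄_j)) with p̄_j
    the across-population mean; SNPs with p̄_j ∈ {0, 1} are dropped;
    Ω = XXᵀ/J.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.ndim != 2 or freqs.shape[1] < 2:
        raise ValueError("need a (SNPs x populations) matrix with >= 2 populations")
    pbar = freqs.mean(axis=1)
    keep = (pbar > 0.0) & (pbar < 1.0)
    freqs = freqs[keep]
    pbar = pbar[keep]
    J = freqs.shape[0]
    if J < min_snps:
        warnings.warn(f"only {J} usable SNPs (< {min_snps}); omega will be noisy")
    if J == 0:
        raise ValueError("no polymorphic SNPs left")
    X = (freqs - pbar[:, None]) / np.sqrt(pbar * (1.0 - pbar))[:, None]
    omega = X.T @ X / J
    names = pops if pops is not None else [f"pop{i + 1}" for i in range(freqs.shape[1])]
    return OmegaMatrix(omega=omega, pops=list(names), n_snps=J)


def correlation_tree(omega: OmegaMatrix) -> str:
    """UPGMA tree (newick, with branch lengths) on 1 − correlation(Ω).

    Negative distances arising from a non-positive-definite Ω are clipped
    at zero with a warning.  Deterministic for a given input; the leaf
    order in the newick string follows the clustering, the topology is
    invariant to population order.
    """
    corr = omega.correlation
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    if (dist < 0).any():
        warnings.warn("negative distances from non-positive-definite omega; clipping at 0")
        dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    tree = TreeNode.from_linkage_matrix(Z, omega.pops)
    # tiny negative branch lengths can appear from float round-off
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
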