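"""Annotation of outlier windows and simple over-representation tests.

A window is a *gene* hit if it overlaps a gene span by at least 1 bp, a
*5′ UTR* hit if it overlaps only the putative promoter — operationally the
500 bp immediately upstream of the gene start, strand-aware, clipped at
contig ends — and *intergenic* otherwise.  Genes are de-duplicated in the
per-category counts (a gene hit by several windows counts once), while
window-level feature fractions count each window once.

Term enrichment is the classic one-sided hypergeometric (Fisher) test of
the overlap between the selected gene set and each term's annotation,
with Benjamini–Hochberg adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GENE_CATEGORIES, GeneModel

__all__ = [
    "promoter_interval",
    "intersect_features",
    "categorize_hits",
    "enrichment_test",
]

PROMOTER_LENGTH = 500


def promoter_interval(
    gene: GeneModel,
    length: int = PROMOTER_LENGTH,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """Half-open promoter interval upstream of the transcription start.

    On the + strand this is [start − length, start), on the − strand
    [end, end + length); both are clipped at the contig boundaries.  May
    be empty (start == end) for a gene at the very contig edge.
    """
    if gene.strand == "-":
        s = gene.end
        e = gene.end + length
        if chrom_length is not None:
            e = min(e, chrom_length)
    else:
        s = max(0, gene.start - length)
        e = gene.start
    return s, e


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def intersect_features(
    windows: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int] | None = None,
    promoter_length: int = PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Label each window {gene, utr5, intergenic} and list the genes hit.

    ``windows`` needs chrom/start/end columns (0-based half-open).  The
    returned frame adds ``feature_class``, ``genes`` (gene-body hits) and
    ``utr5_genes`` (promoter hits) columns; a window overlapping both a
    gene body and a promoter is a gene hit, but both gene lists are kept.
    """
    by_chrom: dict[str, list[tuple[int, int, int, int, str]]] = {}
    for g in genes:
        cl = chrom_lengths.get(g.chrom) if chrom_lengths else None
        ps, pe = promoter_interval(g, promoter_length, cl)
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end, ps, pe, g.gene_id))

    classes: list[str] = []
    gene_hits: list[list[str]] = []
    utr_hits: list[list[str]] = []
    for _, row in windows.iterrows():
        ws, we = int(row["start"]), int(row["end"])
        ghits: list[str] = []
        uhits: list[str] = []
        for gs, ge, ps, pe, gid in by_chrom.get(str(row["chrom"]), ()):
            if _overlaps(ws, we, gs, ge):
                ghits.append(gid)
            elif _overlaps(ws, we, ps, pe):
                uhits.append(gid)
        if ghits:
            classes.append("gene")
        elif uhits:
            classes.append("utr5")
        else:
            classes.append("intergenic")
        gene_hits.append(sorted(ghits))
        utr_hits.append(sorted(uhits))
    out = windows.copy().reset_index(drop=True)
    out["feature_class"] = classes
    out["genes"] = gene_hits
    out["utr5_genes"] = utr_hits
    return out


@dataclass
class HitSummary:
    """Category counts (unique genes) and window feature fractions."""

    n_windows: int
    category_counts: dict[str, int]
    feature_fractions: dict[str, float]
    genes: list[str]
    utr5_only_genes: list[str]


def categorize_hits(
    hits: pd.DataFrame, categories: Mapping[str, str]
) -> HitSummary:
    """Summarise an intersected outlier table.

    Gene category counts de-duplicate genes across windows (promoter-only
    hits included); feature fractions are per window.  Genes absent from
    the category table count as ``other``.
    """
    n = len(hits)
    frac = {
        cls: (float((hits["feature_class"] == cls).sum()) / n if n else 0.0)
        for cls in ("gene", "utr5", "intergenic")
    }
    all_genes: set[str] = set()
    utr_only: set[str] = set()
    for _, row in hits.iterrows():
        all_genes.update(row["genes"])
        all_genes.update(row["utr5_genes"])
        if row["feature_class"] == "utr5":
            utr_only.update(row["utr5_genes"])
    counts = {c: 0 for c in GENE_CATEGORIES}
    for g in sorted(all_genes):
        counts[categories.get(g, "other")] += 1
    return HitSummary(
        n_windows=n,
        category_counts=counts,
        feature_fractions=frac,
        genes=sorted(all_genes),
        utr5_only_genes=sorted(utr_only),
    )


def enrichment_test(
    selected_genes: Iterable[str],
    universe_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    For a term annotated to K of the N universe genes, with n selected
    genes of which k carry the term, p = P(X ≥ k), X ~ Hypergeom(N, K, n).
    Terms with no universe annotation are skipped.  Returns a frame with
    per-term counts, p and Benjamini–Hochberg q, sorted by p.
    """
    selected = set(selected_genes)
    universe = set(universe_genes)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe)
    n = len(selected)
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in universe:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & selected)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = sps.false_discovery_control(df["p"].to_numpy(), method="bh")
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "term"], ignore_index=True)
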