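"""Genewise synonymous and nonsynonymous nucleotide diversity (πN/πS).

Site counting follows the Nei–Gojobori equal-rate convention: each codon
position contributes a synonymous-site fraction equal to the share of its
three possible single-nucleotide changes that preserve the amino acid
(changes to a stop codon count as nonsynonymous); reference codons that
are themselves stops are excluded entirely.  Variant effects are read off
by substituting the alternate base into the reference codon, strand-aware,
with codons assembled in transcript coordinates so exon-junction codons
are handled correctly.

The genewise ratio convention: πN/πS = 0 whenever πN = 0 (including the
no-SNP case), and missing (NaN) when πS = 0 < πN, since the ratio is then
unbounded.  Population-level summaries use the median across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .diversity import SiteCalls
from .io_formats import GeneModel

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = _TABLE.forward_table
_STOPS = set(_TABLE.stop_codons)
_BASES = ("A", "C", "G", "T")
_COL_TO_BASE = {0: "A", 1: "T", 2: "C", 3: "G"}  # sync column order


class StopCodonError(ValueError):
    pass


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, None for stops."""
    if codon in _STOPS:
        return None
    return _FORWARD[codon]


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts of one codon.

    Enumerates all nine single-nucleotide changes; the synonymous site
    count is (number of synonymous changes)/3 and the nonsynonymous count
    its complement to 3.  Raises :class:`StopCodonError` for stop codons
    and ``ValueError`` for ambiguous bases.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in _STOPS:
        raise StopCodonError(f"stop codon {codon}")
    aa = _translate(codon)
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if _translate(mut) == aa:  # stop -> None never equals aa
                syn += 1
    syn_sites = syn / 3.0
    return syn_sites, 3.0 - syn_sites


def _fetch(ref, chrom: str, start: int, end: int) -> str:
    return str(ref[chrom][start:end]).upper()


@dataclass
class _TranscriptMap:
    """CDS of one gene in transcript orientation with a genomic index map."""

    seq: str
    genomic_pos: np.ndarray  # genomic coordinate of each transcript base

    @classmethod
    def build(cls, gene: GeneModel, ref) -> "_TranscriptMap":
        chunks: list[str] = []
        gpos: list[np.ndarray] = []
        for s, e in gene.cds:  # already in transcription order
            seq = _fetch(ref, gene.chrom, s, e)
            coords = np.arange(s, e)
            if gene.strand == "-":
                seq = str(Seq(seq).reverse_complement())
                coords = coords[::-1]
            chunks.append(seq)
            gpos.append(coords)
        return cls(seq="".join(chunks), genomic_pos=np.concatenate(gpos))

    def index_of(self, genomic: int) -> int:
        hits = np.nonzero(self.genomic_pos == genomic)[0]
        if len(hits) != 1:
            raise ValueError(f"position {genomic} not in CDS")
        return int(hits[0])


def classify_variant_effect(
    gene: GeneModel, ref, site: int, alt: str
) -> str:
    """Classify a substitution at 0-based genomic ``site`` as synonymous
    or nonsynonymous, strand-aware.

    Raises ``ValueError`` if the site is outside the gene's CDS, the codon
    is a reference stop, or ``alt`` equals the reference base.
    """
    tm = _TranscriptMap.build(gene, ref)
    t = tm.index_of(site)
    alt = alt.upper()
    if gene.strand == "-":
        alt_t = str(Seq(alt).complement())
    else:
        alt_t = alt
    ci = t // 3
    codon = tm.seq[ci * 3: ci * 3 + 3]
    if len(codon) < 3:
        raise ValueError("incomplete terminal codon")
    off = t % 3
    if codon[off] == alt_t:
        raise ValueError("alt allele equals the reference base")
    if codon in _STOPS:
        raise StopCodonError(f"reference codon at site {site} is a stop")
    mut = codon[:off] + alt_t + codon[off + 1:]
    return "synonymous" if _translate(mut) == _translate(codon) else "nonsynonymous"


def gene_site_totals(gene: GeneModel, ref) -> tuple[float, float]:
    """(N_sites, S_sites) of a gene's CDS; stop codons are excluded and
    contribute neither sites nor length."""
    tm = _TranscriptMap.build(gene, ref)
    n_sites = 0.0
    s_sites = 0.0
    for ci in range(len(tm.seq) // 3):
        codon = tm.seq[ci * 3: ci * 3 + 3]
        if codon in _STOPS:
            continue
        syn, nonsyn = codon_site_counts(codon)
        s_sites += syn
        n_sites += nonsyn
    return n_sites, s_sites


def _ratio(pi_n: float, pi_s: float) -> float:
    if pi_n == 0.0:
        return 0.0
    if pi_s == 0.0:
        return float("nan")
    return pi_n / pi_s


def gene_pi_ratio(
    gene: GeneModel, calls: SiteCalls, ref, pop_index: int
) -> dict:
    """πN, πS and their ratio for one gene in one population.

    SNP sites inside the CDS (per the diversity calling rules) contribute
    their read heterozygosity to πN or πS according to the effect of the
    minor-vs-major substitution on the reference codon.  Sites whose
    reference base is not among the site's two retained alleles, and sites
    in reference stop codons, are skipped (counted in ``n_skipped``).
    """
    if not gene.valid_cds:
        return {"gene_id": gene.gene_id, "pi_n": np.nan, "pi_s": np.nan,
                "ratio": np.nan, "n_sites": np.nan, "s_sites": np.nan,
                "n_snps": 0, "n_skipped": 0, "valid": False}
    tm = _TranscriptMap.build(gene, ref)
    n_sites, s_sites = gene_site_totals(gene, ref)

    table = calls.table
    # candidate SNP rows inside any CDS interval of this gene
    on_chrom = table.chrom == gene.chrom
    pos = table.pos
    in_cds = np.zeros(table.n_sites, dtype=bool)
    for s, e in gene.cds:
        in_cds |= on_chrom & (pos >= s) & (pos < e)
    idx = np.nonzero(in_cds & calls.is_snp[:, pop_index])[0]

    pi_n_sum = 0.0
    pi_s_sum = 0.0
    n_skipped = 0
    for i in idx:
        ref_base = str(table.ref[i]).upper()
        maj = _COL_TO_BASE[int(calls.major[i, pop_index])]
        mnr = _COL_TO_BASE[int(calls.minor[i, pop_index])]
        if ref_base == maj:
            alt = mnr
        elif ref_base == mnr:
            alt = maj
        else:
            n_skipped += 1
            continue
        try:
            effect = classify_variant_effect(gene, ref, int(pos[i]), alt)
        except StopCodonError:
            n_skipped += 1
            continue
        if effect == "synonymous":
            pi_s_sum += float(calls.pi[i, pop_index])
        else:
            pi_n_sum += float(calls.pi[i, pop_index])
    pi_n = pi_n_sum / n_sites if n_sites > 0 else np.nan
    pi_s = pi_s_sum / s_sites if s_sites > 0 else np.nan
    return {
        "gene_id": gene.gene_id,
        "pi_n": pi_n,
        "pi_s": pi_s,
        "ratio": _ratio(pi_n, pi_s),
        "n_sites": n_sites,
        "s_sites": s_sites,
        "n_snps": int(len(idx)),
        "n_skipped": n_skipped,
        "valid": True,
    }


def genewise_pi_table(
    genes: list[GeneModel], calls: SiteCalls, ref
) -> pd.DataFrame:
    """πN/πS for every valid-CDS gene × population (long format)."""
    rows = []
    for gene in genes:
        if not gene.valid_cds:
            continue
        for p, pop in enumerate(calls.table.pops):
            rec = gene_pi_ratio(gene, calls, ref, p)
            rec["pop"] = pop
            rows.append(rec)
    cols = ["gene_id", "pop", "pi_n", "pi_s", "ratio", "n_sites", "s_sites",
            "n_snps", "n_skipped"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def population_summary(table: pd.DataFrame, how: str = "median") -> pd.Series:
    """Aggregate genewise ratios to one value per population (default:
    median across genes, NaN-dropping)."""
    if how not in ("median", "mean"):
        raise ValueError("how must be 'median' or 'mean'")
    return table.groupby("pop")["ratio"].agg(how)
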