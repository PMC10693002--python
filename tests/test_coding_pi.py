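import numpy as np
import pytest

from poolcare import coding_pi, diversity
from poolcare.coding_pi import (
    StopCodonError,
    classify_variant_effect,
    codon_site_counts,
    gene_pi_ratio,
    gene_site_totals,
    genewise_pi_table,
)
from poolcare.io_formats import GeneModel
from .conftest import make_sync

# a 30-bp coding sequence of ten non-stop codons (includes TTT, GGG, TGG)
CDS_SEQ = "TTTGGGTGGGCTATTCAAGACCGTCTGAAA"


@pytest.fixture()
def plus_gene():
    # gene spans [100, 130) on the + strand, one CDS covering it all
    return GeneModel("gP", "c1", "+", 100, 130, [(100, 130)])


@pytest.fixture()
def minus_gene():
    return GeneModel("gM", "c1", "-", 100, 130, [(100, 130)])


@pytest.fixture()
def ref_plus():
    return {"c1": "N" * 100 + CDS_SEQ + "N" * 70}


@pytest.fixture()
def ref_minus():
    from Bio.Seq import Seq

    rc = str(Seq(CDS_SEQ).reverse_complement())
    return {"c1": "N" * 100 + rc + "N" * 70}


class TestCodonSiteCounts:
    @pytest.mark.parametrize(
        "codon,syn",
        [("TTT", 1 / 3), ("TGG", 0.0), ("GGG", 1.0), ("TTC", 1 / 3)],
    )
    def test_standard_codons(self, codon, syn):
        s, n = codon_site_counts(codon)
        assert s == pytest.approx(syn)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(StopCodonError):
            codon_site_counts("TAA")

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("ANT")

    def test_gene_totals_cover_cds(self, plus_gene, ref_plus):
        n_sites, s_sites = gene_site_totals(plus_gene, ref_plus)
        assert n_sites + s_sites == pytest.approx(30.0)  # no stop codons here

    def test_stop_codons_excluded_from_totals(self):
        ref = {"c1": "TTT" + "TAA" + "GGG"}
        gene = GeneModel("g", "c1", "+", 0, 9, [(0, 9)])
        n_sites, s_sites = gene_site_totals(gene, ref)
        assert n_sites + s_sites == pytest.approx(6.0)


class TestVariantEffect:
    def test_synonymous_third_position(self, plus_gene, ref_plus):
        # TTT -> TTC at genomic position 102 (third base of codon 1)
        assert classify_variant_effect(plus_gene, ref_plus, 102, "C") == "synonymous"

    def test_nonsynonymous_change(self, plus_gene, ref_plus):
        # TTT -> TTA is Phe -> Leu
        assert classify_variant_effect(plus_gene, ref_plus, 102, "A") == "nonsynonymous"

    def test_minus_strand_complementing(self, minus_gene, ref_minus):
        # transcript codon 1 is TTT; its third base maps to genomic
        # position 100 + 27 on the reverse-complemented layout
        pos = 100 + 29 - 2
        assert classify_variant_effect(minus_gene, ref_minus, pos, "G") == "synonymous"

    def test_site_outside_cds_rejected(self, plus_gene, ref_plus):
        with pytest.raises(ValueError, match="not in CDS"):
            classify_variant_effect(plus_gene, ref_plus, 50, "A")

    def test_exon_junction_codon(self):
        # split TTT|GGG... across two CDS intervals: codon 1 spans the junction
        ref = {"c1": "TT" + "X" * 10 + "TGGG" + "AAGACCGTCTGAAA" + "TT"}
        gene = GeneModel("g", "c1", "+", 0, 30, [(0, 2), (12, 28)])
        # genomic position 12 is the third base of the junction codon TTT
        assert classify_variant_effect(gene, ref, 12, "C") == "synonymous"
        # genomic 15 is the third base of GGG -> GGC stays Gly
        assert classify_variant_effect(gene, ref, 15, "C") == "synonymous"
        # genomic 13 is the first base of GGG -> CGG is Gly -> Arg
        assert classify_variant_effect(gene, ref, 13, "C") == "nonsynonymous"


class TestGenePiRatio:
    def _calls(self, rows):
        table = make_sync(rows, ["p1"])
        params = diversity.DiversityParams(min_cov=5, max_cov=700)
        return diversity.call_sites(table, params)

    def test_zero_snps_ratio_zero(self, plus_gene, ref_plus):
        from poolcare.io_formats import BASE_TO_COL

        rows = []
        for i in range(30):
            counts = [0, 0, 0, 0, 0, 0]
            counts[BASE_TO_COL[CDS_SEQ[i]]] = 50
            rows.append(("c1", 101 + i, CDS_SEQ[i], [counts]))
        rec = gene_pi_ratio(plus_gene, self._calls(rows), ref_plus, 0)
        assert rec["pi_n"] == 0.0 and rec["pi_s"] == 0.0 and rec["ratio"] == 0.0

    def test_single_synonymous_snp(self, plus_gene, ref_plus):
        from poolcare.io_formats import BASE_TO_COL

        rows = []
        for i in range(30):
            counts = [0, 0, 0, 0, 0, 0]
            counts[BASE_TO_COL[CDS_SEQ[i]]] = 50
            if i == 2:  # TTT third position: T/C polymorphism, synonymous
                counts[BASE_TO_COL["T"]] = 25
                counts[BASE_TO_COL["C"]] = 25
            rows.append(("c1", 101 + i, CDS_SEQ[i], [counts]))
        rec = gene_pi_ratio(plus_gene, self._calls(rows), ref_plus, 0)
        n_sites, s_sites = gene_site_totals(plus_gene, ref_plus)
        site_pi_value = (50 / 49) * 0.5
        assert rec["pi_s"] == pytest.approx(site_pi_value / s_sites)
        assert rec["pi_n"] == 0.0
        assert rec["ratio"] == 0.0  # convention: 0 whenever pi_N = 0

    def test_nonsyn_only_ratio_missing(self, plus_gene, ref_plus):
        from poolcare.io_formats import BASE_TO_COL

        rows = []
        for i in range(30):
            counts = [0, 0, 0, 0, 0, 0]
            counts[BASE_TO_COL[CDS_SEQ[i]]] = 50
            if i == 0:  # TTT first position: T/A -> nonsynonymous
                counts[BASE_TO_COL["T"]] = 25
                counts[BASE_TO_COL["A"]] = 25
            rows.append(("c1", 101 + i, CDS_SEQ[i], [counts]))
        rec = gene_pi_ratio(plus_gene, self._calls(rows), ref_plus, 0)
        assert rec["pi_n"] > 0 and rec["pi_s"] == 0.0
        assert np.isnan(rec["ratio"])

    def test_partition_conserves_total_pi(self, plus_gene, ref_plus):
        from poolcare.io_formats import BASE_TO_COL

        rng = np.random.default_rng(4)
        rows = []
        total_pi = 0.0
        calls_expected = []
        for i in range(30):
            counts = [0, 0, 0, 0, 0, 0]
            ref_b = CDS_SEQ[i]
            counts[BASE_TO_COL[ref_b]] = 40
            if rng.random() < 0.4:
                alt = rng.choice([b for b in "ACGT" if b != ref_b])
                counts[BASE_TO_COL[alt]] = int(rng.integers(2, 20))
            rows.append(("c1", 101 + i, ref_b, [counts]))
        calls = self._calls(rows)
        rec = gene_pi_ratio(plus_gene, calls, ref_plus, 0)
        snp_pi_sum = calls.pi[calls.is_snp[:, 0], 0].sum()
        reconstructed = rec["pi_n"] * rec["n_sites"] + rec["pi_s"] * rec["s_sites"]
        assert reconstructed == pytest.approx(snp_pi_sum)

    def test_fourfold_degenerate_snps_give_zero_pi_n(self):
        # gene of GGx codons: every third position is 4-fold degenerate
        seq = "GGA" * 10
        ref = {"c1": seq}
        gene = GeneModel("g4", "c1", "+", 0, 30, [(0, 30)])
        from poolcare.io_formats import BASE_TO_COL

        rows = []
        for i in range(30):
            counts = [0, 0, 0, 0, 0, 0]
            counts[BASE_TO_COL[seq[i]]] = 50
            if i % 3 == 2:  # plant a SNP at every third position
                counts[BASE_TO_COL["C"]] = 20
            rows.append(("c1", i + 1, seq[i], [counts]))
        rec = gene_pi_ratio(gene, self._calls(rows), ref, 0)
        assert rec["pi_n"] == 0.0
        assert rec["pi_s"] > 0.0
        assert rec["n_snps"] == 10

    def test_invalid_cds_gene_skipped(self, ref_plus):
        gene = GeneModel("bad", "c1", "+", 100, 130, [(100, 129)], valid_cds=False)
        table = make_sync([("c1", 101, "T", [[50, 0, 0, 0, 0, 0]])], ["p1"])
        calls = diversity.call_sites(table, diversity.DiversityParams(min_cov=5))
        out = genewise_pi_table([gene], calls, ref_plus)
        assert out.empty
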