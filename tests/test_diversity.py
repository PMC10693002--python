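import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolcare import diversity
from poolcare.diversity import (
    DiversityParams,
    call_sites,
    compare_windows,
    harmonic,
    site_pi,
    tajima_constants,
    tajima_d_stat,
    window_tajima_d,
    window_theta_pi,
)
from .conftest import make_sync


def brute_force_pi(acgt):
    """Average pairwise difference among reads, by enumeration."""
    reads = []
    for base, c in zip("ATCG", acgt):
        reads.extend(base * c)
    pairs = list(itertools.combinations(range(len(reads)), 2))
    if not pairs:
        return np.nan
    diff = sum(reads[i] != reads[j] for i, j in pairs)
    return diff / len(pairs)


class TestSitePi:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 0, 0, 0, 0], 25 / 45),
            ([10, 0, 0, 0, 0, 0], 0.0),
            ([9, 1, 0, 0, 0, 0], 9 / 45),
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert site_pi(counts) == pytest.approx(expected)

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    @settings(max_examples=150, deadline=None)
    def test_equals_brute_force_pairwise(self, acgt):
        counts = acgt + [0, 0]
        got = site_pi(counts)
        want = brute_force_pi(acgt)
        if sum(acgt) < 2:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want)

    def test_single_read_undefined(self):
        assert np.isnan(site_pi([1, 0, 0, 0, 0, 0]))


class TestWindowThetaPi:
    def _uniform_window(self, n_snp=3, n_sites=1000, depth=10):
        rows = []
        for i in range(n_sites):
            if i < n_snp:
                counts = [depth // 2, depth - depth // 2, 0, 0, 0, 0]
            else:
                counts = [depth, 0, 0, 0, 0, 0]
            rows.append(("c1", i + 1, "A", [counts]))
        return make_sync(rows, ["p1"])

    def test_watterson_formula(self):
        table = self._uniform_window()
        params = DiversityParams(min_cov=5, max_cov=700, min_covered_fraction=0.5)
        out = window_theta_pi(table, params, window_size=1000)
        row = out.iloc[0]
        a1_10 = sum(1 / i for i in range(1, 10))
        assert row["S"] == 3
        assert row["theta_w"] == pytest.approx(3 / (a1_10 * 1000))
        # one A:5/T:5 SNP contributes 25/45 per site
        assert row["n_valid"] == 1000

    def test_pi_single_snp_window(self):
        rows = [("c1", 1, "A", [[5, 5, 0, 0, 0, 0]])] + [
            ("c1", i + 1, "A", [[10, 0, 0, 0, 0, 0]]) for i in range(1, 1000)
        ]
        table = make_sync(rows, ["p1"])
        params = DiversityParams(min_cov=5, max_cov=700)
        out = window_theta_pi(table, params, window_size=1000)
        assert out.iloc[0]["pi"] == pytest.approx((25 / 45) / 1000)

    def test_low_coverage_window_unusable(self):
        # population 2 covers only 30% of the window adequately
        rows = []
        for i in range(1000):
            c2 = [50, 0, 0, 0, 0, 0] if i < 300 else [5, 0, 0, 0, 0, 0]
            rows.append(("c1", i + 1, "A", [[50, 0, 0, 0, 0, 0], c2]))
        table = make_sync(rows, ["p1", "p2"])
        out = window_theta_pi(table, DiversityParams(min_cov=40), window_size=1000)
        assert not out["usable"].any()
        p1 = out[out["pop"] == "p1"].iloc[0]
        assert p1["covered_fraction"] == pytest.approx(1.0)

    def test_monomorphic_sites_give_zero_pi_at_any_subsampling(self):
        rows = [("c1", i + 1, "A", [[60 + i % 5, 0, 0, 0, 0, 0]]) for i in range(200)]
        table = make_sync(rows, ["p1"])
        for n_star in (10, 40):
            td = window_tajima_d(table, DiversityParams(), n_star=n_star, seed=0)
            assert (td["pi_w"] == 0).all()
            assert (td["S"] == 0).all()


class TestTajimaD:
    def test_constants_a1(self):
        assert harmonic(np.array([10]))[0] == pytest.approx(2.828968, abs=1e-6)
        c = tajima_constants(10)
        assert c.a1 == pytest.approx(2.828968, abs=1e-6)

    def test_zero_when_pi_equals_theta(self):
        c = tajima_constants(10)
        S = 3
        assert tajima_d_stat(S / c.a1, S, 10) == pytest.approx(0.0)

    def test_undefined_when_no_segregating_sites(self):
        assert np.isnan(tajima_d_stat(0.0, 0, 10))

    def test_three_singletons_negative(self):
        # n*=10, S=3 singletons: pi_w = 3 * (10/9)(1 - 0.81 - 0.01) = 0.6
        rows = []
        for i in range(500):
            counts = [9, 1, 0, 0, 0, 0] if i in (10, 20, 30) else [10, 0, 0, 0, 0, 0]
            rows.append(("c1", i + 1, "A", [counts]))
        table = make_sync(rows, ["p1"])
        params = DiversityParams(min_cov=5, max_cov=700, min_count=1)
        td = window_tajima_d(table, params, window_size=500, step=250, n_star=10, seed=0)
        row = td[td["start"] == 0].iloc[0]
        assert row["S"] == 3
        assert row["pi_w"] == pytest.approx(0.6)
        assert row["theta_w"] == pytest.approx(3 / 2.828968, abs=1e-5)
        assert row["tajima_d"] < 0

    def test_sliding_windows_overlap(self):
        rows = [("c1", 300, "A", [[30, 30, 0, 0, 0, 0]])]
        table = make_sync(rows, ["p1"])
        td = window_tajima_d(table, DiversityParams(), n_star=40, seed=0)
        # position 299 (0-based) lies in windows [0,500) and [250,750)
        assert sorted(td["start"]) == [0, 250]


class TestCompareWindows:
    def test_kruskal_wallis_example(self):
        stat, p = compare_windows([1, 2, 3], [4, 5, 6], test="kruskal_wallis")
        assert stat == pytest.approx(3.857142857, abs=1e-6)

    def test_welch_t_identical_vectors(self):
        stat, _ = compare_windows([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="welch_t")
        assert stat == pytest.approx(0.0)

    def test_single_window_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_windows([1.0], [1.0, 2.0], test="kruskal_wallis")

    def test_region_filter_restricts_windows(self):
        import pandas as pd

        from poolcare.io_formats import GeneModel

        df_a = pd.DataFrame(
            {"chrom": ["c1"] * 4, "start": [0, 1000, 2000, 3000],
             "end": [500, 1500, 2500, 3500], "value": [1.0, 2.0, 3.0, 4.0]}
        )
        df_b = df_a.assign(value=[5.0, 6.0, 7.0, 8.0])
        gene = GeneModel("g", "c1", "+", 1100, 1300, [], valid_cds=False)
        # gene +/- 600 bp covers [500,1900): half-open, so the window
        # [0,500) does not overlap and only the window at 1000 qualifies
        filtered = diversity.filter_windows_by_genes(df_a, [gene], 600)
        assert filtered["start"].tolist() == [1000]
        with pytest.raises(ValueError, match="at least 2"):
            compare_windows(df_a, df_b, test="welch_t",
                            region_filter=([gene], 600), value_column="value")
        wide = diversity.filter_windows_by_genes(df_a, [gene], 1200)
        assert wide["start"].tolist() == [0, 1000, 2000]
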