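import filecmp

import numpy as np
import pytest

from poolcare import popsim
from poolcare.popsim import NEUTRAL, CONSISTENT, PRIVATE_B1, PRIVATE_B2, SimConfig


def small_config(**kw):
    base = dict(
        chrom_lengths={"chr1": 50_000},
        n_loci=500,
        selected_fraction=0.1,
        block_private_fraction=0.04,
        gene_spacing=10_000,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestWrightFisherDynamics:
    def test_no_forces_frequencies_constant(self):
        cfg = small_config(selected_fraction=0, block_private_fraction=0, mu=0,
                           drift=False, founder_sfs=("fixed", 0.3), block_jitter_sd=0)
        st = popsim.simulate_experiment(cfg)
        assert np.allclose(st.traj, 0.3)

    def test_heterozygosity_decay_matches_closed_form(self):
        # E[H_t] = H_0 (1 - 1/2N)^t with 2N = 4*pairs = 100 chromosomes
        cfg = small_config(
            n_pairs_fc=25, n_pairs_nc=25, n_loci=10_000, selected_fraction=0,
            block_private_fraction=0, founder_sfs=("fixed", 0.5), mu=0,
            block_jitter_sd=0, chrom_lengths={"chr1": 100_000},
            pool_sizes=(41, 50, 50, 50), seed=3,
        )
        st = popsim.simulate_experiment(cfg)
        expected = 0.5 * (1 - 1 / 100) ** 30
        for pop in range(4):
            H = st.heterozygosity(pop, 30)
            # MC standard error of mean het over 10k loci is ~0.002
            assert H == pytest.approx(expected, abs=0.01)

    def test_deterministic_selection_recursion(self):
        cfg = small_config(selected_fraction=1.0, block_private_fraction=0, s_nc=0.5,
                           drift=False, mu=0, selected_founder_range=(0.5, 0.5),
                           block_jitter_sd=0)
        st = popsim.simulate_experiment(cfg)
        # iterate p' = p(1+s)/(1+ps) 30 times from 0.5
        p = 0.5
        for _ in range(30):
            p = p * 1.5 / (1 + 0.5 * p)
        assert np.allclose(st.freqs[1], p)  # NC population
        assert p > 0.99
        assert np.allclose(st.freqs[0], 0.5)  # FC relaxed

    def test_selected_nc_frequencies_dominate_fc(self, default_experiment):
        state, _, _ = default_experiment
        sel = state.labels == CONSISTENT
        assert state.freqs[1][sel].mean() > state.freqs[0][sel].mean() + 0.3
        assert state.freqs[3][sel].mean() > state.freqs[2][sel].mean() + 0.3

    def test_block_private_confounders_exist(self, default_experiment):
        state, _, _ = default_experiment
        assert (state.labels == PRIVATE_B1).sum() > 0
        assert (state.labels == PRIVATE_B2).sum() > 0
        # private-to-block-1 loci respond in NC1 but not NC2
        p1 = state.labels == PRIVATE_B1
        assert state.freqs[1][p1].mean() > state.founder[0][p1].mean() + 0.3
        drift_only = abs(state.freqs[3][p1].mean() - state.founder[1][p1].mean())
        assert drift_only < 0.1


class TestPoolSequencing:
    def test_pure_frequencies_without_error(self):
        for f, col in ((0.0, "ref"), (1.0, "alt")):
            cfg = small_config(selected_fraction=0, block_private_fraction=0,
                              founder_sfs=("fixed", f), block_jitter_sd=0, mu=0,
                              drift=False, seq_error=0.0, emit_monomorphic=False)
            st = popsim.simulate_experiment(cfg)
            tab = popsim.pool_seq_reads(st)
            acgt = tab.counts[:, :, :4]
            from poolcare.io_formats import BASE_TO_COL
            want = np.array([
                BASE_TO_COL[b] for b in (st.ref_base if col == "ref" else st.alt_base)
            ])
            on_allele = acgt[np.arange(tab.n_sites)[:, None], np.arange(4)[None, :],
                             want[:, None]]
            assert (on_allele == acgt.sum(axis=2)).all()

    def test_mean_alt_fraction_with_errors(self):
        # E[alt read fraction] = f(1-eps) + (1-f) eps/3
        f, eps = 0.5, 0.001
        cfg = SimConfig(
            chrom_lengths={"chr1": 1_000_000}, n_loci=100_000, generations=0,
            selected_fraction=0, block_private_fraction=0, mu=0, drift=False,
            founder_sfs=("fixed", f), block_jitter_sd=0, seq_error=eps,
            emit_monomorphic=False, gene_spacing=100_000, seed=9,
        )
        st = popsim.simulate_experiment(cfg)
        tab = popsim.pool_seq_reads(st)
        from poolcare.io_formats import BASE_TO_COL
        alt_col = np.array([BASE_TO_COL[b] for b in st.alt_base])
        pop = 0
        alt = tab.counts[np.arange(tab.n_sites), pop, alt_col].sum()
        depth = tab.counts[:, pop, :4].sum()
        expected = f * (1 - eps) + (1 - f) * eps / 3
        se = np.sqrt(expected * (1 - expected) / depth) * 3
        # pool sampling adds binomial(2*pool) variance around f per site
        assert alt / depth == pytest.approx(expected, abs=max(3 * se, 2e-3))

    def test_pool_size_exceeding_census_rejected(self):
        with pytest.raises(ValueError, match="exceeds census"):
            small_config(n_pairs_fc=10, pool_sizes=(41, 52, 52, 59)).validate()


class TestDatasetWriter:
    def test_seeded_rerun_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            cfg = small_config(seed=5)
            st = popsim.simulate_experiment(cfg)
            tab = popsim.pool_seq_reads(st)
            popsim.write_synthetic_dataset(st, tab, tmp_path / d)
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors and set(match) == set(names)

    def test_truth_table_counts_and_pop_number(self, tmp_path):
        cfg = small_config(seed=2)
        st = popsim.simulate_experiment(cfg)
        tab = popsim.pool_seq_reads(st)
        paths = popsim.write_synthetic_dataset(st, tab, tmp_path)
        truth = [ln for ln in open(paths["truth"]).read().splitlines()[1:] if ln]
        n_sel = round(cfg.n_loci * cfg.selected_fraction)
        n_priv = round(cfg.n_loci * cfg.block_private_fraction)
        assert len(truth) == n_sel + n_priv
        first = open(paths["sync"]).readline().split("\t")
        assert len(first) == 3 + 4  # four populations

    def test_labels_sum_to_n_loci(self, default_experiment):
        state, _, _ = default_experiment
        n = state.config.n_loci
        counts = {lab: int((state.labels == lab).sum())
                  for lab in (NEUTRAL, CONSISTENT, PRIVATE_B1, PRIVATE_B2)}
        assert sum(counts.values()) == n
        assert counts[CONSISTENT] == round(n * state.config.selected_fraction)
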