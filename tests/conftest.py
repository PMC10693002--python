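"""Shared fixtures: small hand-built sync tables and the two session-scoped
synthetic experiments (the default design and the screen scenario)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from poolcare import divergence, diversity, popsim

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from poolcare.io_formats import SyncTable


def make_sync(rows, pops):
    """Build a SyncTable from (chrom, pos1, ref, [sextuple, ...]) tuples
    (pos1 is 1-based, as in the file format)."""
    chrom = np.array([r[0] for r in rows], dtype=object)
    pos = np.array([r[1] - 1 for r in rows], dtype=np.int64)
    ref = np.array([r[2] for r in rows], dtype=object)
    counts = np.array([r[3] for r in rows], dtype=np.int64)
    return SyncTable(chrom=chrom, pos=pos, ref=ref, counts=counts, pops=list(pops))


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic experiment (seed 1): state, reads, calls."""
    cfg = popsim.SimConfig(seed=1)
    state = popsim.simulate_experiment(cfg)
    table = popsim.pool_seq_reads(state)
    calls = diversity.call_sites(table)
    return state, table, calls


@pytest.fixture(scope="session")
def screen_experiment():
    """The replicate-consistency screen scenario (seed 1) with both the
    FC-vs-NC screen and the same-regime permutation screen."""
    cfg = popsim.screen_config(seed=1)
    state = popsim.simulate_experiment(cfg)
    table = popsim.pool_seq_reads(state)
    calls = diversity.call_sites(table)
    d1 = divergence.pair_divergence(table, 0, 1, calls=calls)
    d2 = divergence.pair_divergence(table, 2, 3, calls=calls)
    screen = divergence.consistency_screen(d1, d2)
    # permutation control: pair populations within regime instead
    p1 = divergence.pair_divergence(table, 0, 2, calls=calls)  # FC1 vs FC2
    p2 = divergence.pair_divergence(table, 1, 3, calls=calls)  # NC1 vs NC2
    perm = divergence.consistency_screen(p1, p2)
    return state, table, screen, perm


def windows_containing(pos: int, size: int = 500, step: int = 250):
    """Start coordinates of the sliding windows that contain a position."""
    starts = []
    for shift in range(size // step):
        s = (pos - shift * step) // size * size + shift * step
        if s >= 0:
            starts.append(s)
    return starts
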