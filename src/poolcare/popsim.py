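"""Forward Wright–Fisher simulator for a two-block, two-regime
evolve-and-resequence design with pooled sequencing.

The simulated experiment mirrors a laboratory evolution study on a
pair-breeding insect: four populations founded from one outbred stock,
arranged as two replicate blocks, each containing one population evolving
under relaxed selection (Full Care, "FC") and one under directional
selection imposed by a harsh environment (No Care, "NC").  Populations are
diploid with discrete generations and a census of 2 × (breeding pairs)
individuals.  A configurable subset of loci is under directional selection
in the NC regime; a further subset is selected in only one block
("block-private"), providing drift-like confounders for downstream
replicate-consistency screens.

Loci are unlinked biallelic sites.  Per generation and locus the favoured
("alt") allele frequency p is updated by

    selection   p' = p (1 + s) / (1 + p s)
    drift       p'' ~ Binomial(2N, p') / 2N      (2N chromosomes, N = 2·pairs)
    mutation    p''' = p'' + mu (1 − 2 p'')      (symmetric, deterministic)

Pooled sequencing then draws, per site and population, a pool allele
frequency (binomial over the 2 × pool-size chromosomes actually pooled), a
Poisson read depth, and read counts with uniform scatter of errors to the
other three bases.

All randomness flows from one seed; each population has fixed substreams so
adding populations never shifts existing draws.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import BASE_TO_COL, SampleSheet, SyncTable, write_sample_sheet, write_sync

_BASES = np.array(["A", "C", "G", "T"])

# fixed substream ids (SeedSequence spawn keys)
_STREAM_GENOME = 0
_STREAM_FOUNDER = 1
_STREAM_ANNOT = 2
_STREAM_DRIFT0 = 10  # + population index
_STREAM_SEQ0 = 40  # + population index


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SimConfig:
    """Design and nuisance parameters of the simulated experiment.

    Defaults reproduce the study conditions: two blocks × (FC, NC), 30
    generations, 37 FC / 49 NC breeding pairs per generation, pools of
    41–59 individuals sequenced at ~100× with 0.1% read error.
    """

    n_pairs_fc: int = 37
    n_pairs_nc: int = 49
    generations: int = 30
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    n_loci: int = 16_000
    selected_fraction: float = 0.10
    block_private_fraction: float = 0.02
    s_nc: float = 0.25
    s_fc: float = 0.0
    mu: float = 1e-8
    founder_sfs: tuple = ("beta", 0.2, 0.2, 0.05, 0.95)
    selected_founder_range: tuple[float, float] = (0.10, 0.50)
    block_jitter_sd: float = 0.02
    sweep_cluster_size: int = 1
    sweep_cluster_span: int = 450
    pool_sizes: tuple[int, ...] = (41, 52, 52, 59)  # FC1, NC1, FC2, NC2
    mean_depth: float = 100.0
    seq_error: float = 0.001
    drift: bool = True
    emit_monomorphic: bool = True
    gene_spacing: int = 10_000
    seed: int = 0

    # fixed population layout: FC1 NC1 FC2 NC2
    pop_names: tuple[str, ...] = ("FC1", "NC1", "FC2", "NC2")
    pop_blocks: tuple[int, ...] = (1, 1, 2, 2)
    pop_regimes: tuple[str, ...] = ("FC", "NC", "FC", "NC")

    def validate(self) -> None:
        if not 0.0 <= self.s_nc <= 1.0 or not 0.0 <= self.s_fc <= 1.0:
            raise ValueError("selection coefficients must lie in [0, 1]")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in [0, 1]")
        if not 0.0 <= self.block_private_fraction <= 1.0:
            raise ValueError("block_private_fraction must lie in [0, 1]")
        if self.selected_fraction + self.block_private_fraction > 1.0:
            raise ValueError("selected fractions exceed 1")
        if len(self.pool_sizes) != len(self.pop_names):
            raise ValueError("one pool size per population required")
        for i, ps in enumerate(self.pool_sizes):
            census = 2 * (self.n_pairs_nc if self.pop_regimes[i] == "NC" else self.n_pairs_fc)
            if ps > census:
                raise ValueError(
                    f"pool size {ps} for {self.pop_names[i]} exceeds census {census}"
                )
        total = sum(self.chrom_lengths.values())
        if self.n_loci > total:
            raise ValueError("more loci than genome positions")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must lie in [0, 1)")

    def census(self, pop_index: int) -> int:
        """Diploid census size N = 2 × pairs for one population."""
        pairs = self.n_pairs_nc if self.pop_regimes[pop_index] == "NC" else self.n_pairs_fc
        return 2 * pairs

    def sample_sheet(self) -> SampleSheet:
        return SampleSheet(
            names=list(self.pop_names),
            blocks=list(self.pop_blocks),
            regimes=list(self.pop_regimes),
            pool_sizes=list(self.pool_sizes),
        )


# truth labels
NEUTRAL, CONSISTENT, PRIVATE_B1, PRIVATE_B2 = 0, 1, 2, 3
LABEL_NAMES = {NEUTRAL: "neutral", CONSISTENT: "consistent",
               PRIVATE_B1: "private_block1", PRIVATE_B2: "private_block2"}


@dataclass
class SimState:
    """Result of a forward simulation: trajectories plus the design."""

    config: SimConfig
    genome: dict[str, str]
    loci_chrom: np.ndarray  # per locus
    loci_pos: np.ndarray  # 0-based, sorted within chrom
    ref_base: np.ndarray
    alt_base: np.ndarray
    labels: np.ndarray  # NEUTRAL/CONSISTENT/PRIVATE_B1/PRIVATE_B2 per locus
    clusters: np.ndarray  # sweep unit id per locus (-1 for neutral)
    is_target: np.ndarray  # True for the focal locus of each sweep unit
    founder: np.ndarray  # (n_blocks, n_loci) block founder frequencies
    traj: np.ndarray  # (n_pops, generations+1, n_loci) alt-allele freq

    @property
    def freqs(self) -> np.ndarray:
        """Terminal alt-allele frequencies, shape (n_pops, n_loci)."""
        return self.traj[:, -1, :]

    def heterozygosity(self, pop: int, generation: int) -> float:
        p = self.traj[pop, generation, :]
        return float(np.mean(2.0 * p * (1.0 - p)))


def _draw_founder(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = cfg.founder_sfs[0]
    if kind == "beta":
        _, a, b, lo, hi = cfg.founder_sfs
        p = rng.beta(a, b, size=n)
        return np.clip(p, lo, hi)
    if kind == "uniform":
        _, lo, hi = cfg.founder_sfs
        return rng.uniform(lo, hi, size=n)
    if kind == "fixed":
        return np.full(n, float(cfg.founder_sfs[1]))
    raise ValueError(f"unknown founder_sfs kind {kind!r}")


def _make_genome_and_loci(cfg: SimConfig):
    """Random genome plus the locus map: positions, truth labels, sweep
    cluster ids and per-locus role (target vs dragged hitchhiker).

    Selected units occupy ``sweep_cluster_size`` loci within a
    ``sweep_cluster_span``-bp span, emulating the footprint a selective
    sweep leaves on linked variation (the Wright–Fisher loci themselves
    are unlinked, so linkage drag is imposed by selecting the whole
    cluster).  With cluster size 1 a unit is a single locus.
    """
    rng = _rng(cfg.seed, _STREAM_GENOME)
    genome: dict[str, str] = {}
    for chrom in sorted(cfg.chrom_lengths):
        L = cfg.chrom_lengths[chrom]
        genome[chrom] = "".join(_BASES[rng.integers(0, 4, size=L)])
    chroms = sorted(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    m = cfg.sweep_cluster_size
    span = cfg.sweep_cluster_span
    n = cfg.n_loci
    n_sel = int(round(n * cfg.selected_fraction))
    n_priv = int(round(n * cfg.block_private_fraction))
    if n_sel % m or n_priv % m:
        raise ValueError("selected locus counts must be multiples of sweep_cluster_size")
    if m > 1 and span < m:
        raise ValueError("sweep_cluster_span too small for cluster size")
    units = [(CONSISTENT, n_sel // m)]
    n_priv_units = n_priv // m
    units += [(PRIVATE_B1, n_priv_units // 2),
              (PRIVATE_B2, n_priv_units - n_priv_units // 2)]

    flat_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    cluster_parts: list[np.ndarray] = []
    target_parts: list[np.ndarray] = []
    used: set[int] = set()
    cluster_id = 0
    for label, n_units in units:
        for _ in range(n_units):
            # rejection-sample an anchor whose span is free and inside one chrom
            while True:
                anchor = int(rng.integers(0, total - span))
                c = int(np.searchsorted(offsets, anchor, side="right") - 1)
                if anchor + span > offsets[c + 1]:
                    continue
                pos = anchor + np.sort(rng.choice(span, size=m, replace=False))
                if not any(int(p) in used for p in pos):
                    break
            used.update(int(p) for p in pos)
            flat_parts.append(pos.astype(np.int64))
            label_parts.append(np.full(m, label, dtype=np.int64))
            cluster_parts.append(np.full(m, cluster_id, dtype=np.int64))
            tgt = np.zeros(m, dtype=bool)
            tgt[0] = True
            target_parts.append(tgt)
            cluster_id += 1
    n_neutral = n - n_sel - n_priv
    cand = rng.choice(total, size=min(total, n_neutral + 2000), replace=False)
    cand = cand[~np.isin(cand, np.fromiter(used, dtype=np.int64, count=len(used)))] \
        if used else cand
    if len(cand) < n_neutral:
        raise ValueError("genome too small for the requested locus count")
    flat_parts.append(np.asarray(cand[:n_neutral], dtype=np.int64))
    label_parts.append(np.full(n_neutral, NEUTRAL, dtype=np.int64))
    cluster_parts.append(np.full(n_neutral, -1, dtype=np.int64))
    target_parts.append(np.zeros(n_neutral, dtype=bool))

    flat = np.concatenate(flat_parts)
    order_idx = np.argsort(flat, kind="stable")
    flat = flat[order_idx]
    labels = np.concatenate(label_parts)[order_idx]
    clusters = np.concatenate(cluster_parts)[order_idx]
    is_target = np.concatenate(target_parts)[order_idx]

    ci = np.searchsorted(offsets, flat, side="right") - 1
    loci_chrom = np.array([chroms[i] for i in ci], dtype=object)
    loci_pos = flat - offsets[ci]
    ref = np.array([genome[loci_chrom[i]][loci_pos[i]] for i in range(n)], dtype=object)
    # alt: a base different from ref, drawn uniformly from the other three
    shift = rng.integers(1, 4, size=n)
    base_order = {b: i for i, b in enumerate("ACGT")}
    alt = np.array([_BASES[(base_order[ref[i]] + shift[i]) % 4] for i in range(n)],
                   dtype=object)
    return genome, loci_chrom, loci_pos, ref, alt, labels, clusters, is_target


def simulate_experiment(config: SimConfig) -> SimState:
    """Run the forward simulation; fully deterministic under ``config.seed``."""
    cfg = config
    cfg.validate()
    (genome, loci_chrom, loci_pos, ref, alt,
     labels, clusters, is_target) = _make_genome_and_loci(cfg)

    frng = _rng(cfg.seed, _STREAM_FOUNDER)
    n = cfg.n_loci
    base = _draw_founder(cfg, frng, n)
    # the focal locus of each sweep unit starts as a standing variant at
    # low-to-intermediate frequency, so that 30 generations of directional
    # selection move it detectably; dragged hitchhikers keep their own
    # founder frequency from the neutral SFS
    lo, hi = cfg.selected_founder_range
    base[is_target] = frng.uniform(lo, hi, size=int(is_target.sum()))

    blocks = sorted(set(cfg.pop_blocks))
    founder = np.empty((len(blocks), n))
    for bi, _ in enumerate(blocks):
        if cfg.block_jitter_sd > 0:
            jitter = frng.normal(0.0, cfg.block_jitter_sd, size=n)
            founder[bi] = np.clip(base + jitter, 0.01, 0.99)
        else:
            founder[bi] = base

    n_pops = len(cfg.pop_names)
    traj = np.empty((n_pops, cfg.generations + 1, n), dtype=np.float64)
    for i in range(n_pops):
        block = cfg.pop_blocks[i]
        bi = blocks.index(block)
        s = cfg.s_nc if cfg.pop_regimes[i] == "NC" else cfg.s_fc
        sel = (labels == CONSISTENT) | (labels == (PRIVATE_B1 + block - 1))
        two_n = 2 * cfg.census(i)  # chromosomes
        rng = _rng(cfg.seed, _STREAM_DRIFT0 + i)
        p = founder[bi].copy()
        traj[i, 0] = p
        for t in range(1, cfg.generations + 1):
            if s > 0:
                ps = p[sel]
                p[sel] = ps * (1.0 + s) / (1.0 + ps * s)
            if cfg.drift:
                p = rng.binomial(two_n, p) / two_n
            if cfg.mu > 0:
                p = p + cfg.mu * (1.0 - 2.0 * p)
            traj[i, t] = p
    return SimState(
        config=cfg,
        genome=genome,
        loci_chrom=loci_chrom,
        loci_pos=loci_pos,
        ref_base=ref,
        alt_base=alt,
        labels=labels,
        clusters=clusters,
        is_target=is_target,
        founder=founder,
        traj=traj,
    )


def _multinomial_reads(rng, depth, p_list):
    """Sequential-binomial draw of counts for categories with probs p_list
    (plus an implicit remainder category); all arrays site-length."""
    remaining = depth.copy()
    prob_left = np.ones_like(p_list[0])
    out = []
    for p in p_list:
        frac = np.divide(p, prob_left, out=np.zeros_like(p), where=prob_left > 0)
        frac = np.clip(frac, 0.0, 1.0)
        c = rng.binomial(remaining, frac)
        out.append(c)
        remaining = remaining - c
        prob_left = prob_left - p
    out.append(remaining)
    return out


def pool_seq_reads(state: SimState, config: SimConfig | None = None) -> SyncTable:
    """Generate pooled read counts as a :class:`SyncTable`.

    For every variable locus and population: the pool's allele frequency is
    a binomial draw of 2 × pool-size chromosomes at the terminal population
    frequency; read depth is Poisson(mean_depth); reads are then
    multinomial over the four bases with error mass seq_error scattered
    uniformly to the three non-true bases.  With
    ``config.emit_monomorphic`` the invariant reference background of the
    genome is emitted too (errors only), giving a sync file that covers
    every position like a real merged pileup.
    """
    cfg = state.config if config is None else config
    cfg.validate()
    n_pops = len(cfg.pop_names)
    eps = cfg.seq_error

    chroms = sorted(cfg.chrom_lengths)
    if cfg.emit_monomorphic:
        n_sites = sum(cfg.chrom_lengths[c] for c in chroms)
        chrom_arr = np.concatenate(
            [np.full(cfg.chrom_lengths[c], c, dtype=object) for c in chroms]
        )
        pos_arr = np.concatenate(
            [np.arange(cfg.chrom_lengths[c], dtype=np.int64) for c in chroms]
        )
        ref_arr = np.concatenate(
            [np.frombuffer(state.genome[c].encode(), dtype="S1").astype("U1") for c in chroms]
        ).astype(object)
        offsets = {}
        off = 0
        for c in chroms:
            offsets[c] = off
            off += cfg.chrom_lengths[c]
        loc_idx = np.array(
            [offsets[state.loci_chrom[i]] + state.loci_pos[i] for i in range(cfg.n_loci)],
            dtype=np.int64,
        )
    else:
        n_sites = cfg.n_loci
        chrom_arr = state.loci_chrom.copy()
        pos_arr = state.loci_pos.copy()
        ref_arr = state.ref_base.copy()
        loc_idx = np.arange(cfg.n_loci, dtype=np.int64)

    ref_col = np.array([BASE_TO_COL[b] for b in ref_arr], dtype=np.int64)
    alt_col_loci = np.array([BASE_TO_COL[b] for b in state.alt_base], dtype=np.int64)

    counts = np.zeros((n_sites, n_pops, 6), dtype=np.int64)
    for i in range(n_pops):
        rng = _rng(cfg.seed, _STREAM_SEQ0 + i)
        two_pool = 2 * cfg.pool_sizes[i]
        f_pool = rng.binomial(two_pool, state.freqs[i]) / two_pool
        depth = rng.poisson(cfg.mean_depth, size=n_sites)

        # variable loci: four categories alt/ref/err1/err2
        d_loc = depth[loc_idx]
        p_alt = f_pool * (1 - eps) + (1 - f_pool) * eps / 3.0
        p_ref = (1 - f_pool) * (1 - eps) + f_pool * eps / 3.0
        n_alt, n_ref, n_e1, n_e2 = _multinomial_reads(
            rng, d_loc, [p_alt, p_ref, np.full_like(p_alt, eps / 3.0)]
        )
        rc = ref_col[loc_idx]
        ac = alt_col_loci
        # the two error bases are the ACGT columns that are neither ref nor alt
        pair_table = np.zeros((4, 4, 2), dtype=np.int64)
        for r in range(4):
            for a in range(4):
                others = [c for c in range(4) if c != r and c != a]
                pair_table[r, a] = (others + others)[:2]
        err_cols = pair_table[rc, ac]
        np.add.at(counts, (loc_idx, i, ac), n_alt)
        np.add.at(counts, (loc_idx, i, rc), n_ref)
        np.add.at(counts, (loc_idx, i, err_cols[:, 0]), n_e1)
        np.add.at(counts, (loc_idx, i, err_cols[:, 1]), n_e2)

        if cfg.emit_monomorphic:
            bg = np.ones(n_sites, dtype=bool)
            bg[loc_idx] = False
            d_bg = depth[bg]
            e_tot = rng.binomial(d_bg, eps)
            e1 = rng.binomial(e_tot, 1.0 / 3.0)
            e2 = rng.binomial(e_tot - e1, 0.5)
            e3 = e_tot - e1 - e2
            rcb = ref_col[bg]
            idx_bg = np.nonzero(bg)[0]
            np.add.at(counts, (idx_bg, i, rcb), d_bg - e_tot)
            other_table = np.array(
                [[c for c in range(4) if c != r] for r in range(4)], dtype=np.int64
            )
            err_bg = other_table[rcb]
            np.add.at(counts, (idx_bg, i, err_bg[:, 0]), e1)
            np.add.at(counts, (idx_bg, i, err_bg[:, 1]), e2)
            np.add.at(counts, (idx_bg, i, err_bg[:, 2]), e3)

    return SyncTable(
        chrom=chrom_arr, pos=pos_arr, ref=ref_arr, counts=counts,
        pops=list(cfg.pop_names),
    )


# ---------------------------------------------------------------------------
# toy annotation + dataset writer
# ---------------------------------------------------------------------------


def toy_annotation(cfg: SimConfig, unit_spans: pd.DataFrame | None = None):
    """Deterministically place toy genes along the genome.

    One gene per ``gene_spacing`` tile (1.5 kb span, single 1,200-bp CDS for
    protein-coding genes); strands alternate; categories drawn with fixed
    probabilities; each gene gets 1–3 GO-like terms from a pool of 20.
    lncRNA genes carry no CDS.  When the selected-unit table is given, a
    tile containing a unit centres its gene on that unit, so known selected
    loci fall inside annotated genes.
    """
    rng = _rng(cfg.seed, _STREAM_ANNOT)
    cats = np.array(["TF", "expression_related", "lncRNA", "other"])
    cat_p = np.array([0.10, 0.15, 0.10, 0.65])
    terms = [f"GO:{i:07d}" for i in range(1, 21)]
    anchors: dict[str, list[int]] = {}
    if unit_spans is not None:
        for _, r in unit_spans.iterrows():
            anchors.setdefault(str(r["chrom"]), []).append(
                (int(r["start"]) + int(r["end"])) // 2
            )
        for v in anchors.values():
            v.sort()
    genes = []
    gid = 0
    for chrom in sorted(cfg.chrom_lengths):
        L = cfg.chrom_lengths[chrom]
        for tile in range(0, L - cfg.gene_spacing + 1, cfg.gene_spacing):
            start = tile + 2000
            in_tile = [a for a in anchors.get(chrom, ())
                       if tile <= a < tile + cfg.gene_spacing]
            if in_tile:
                start = min(max(in_tile[0] - 750, tile), L - 1500)
            end = start + 1500
            if end > L:
                continue
            gid += 1
            strand = "+" if gid % 2 else "-"
            cat = str(rng.choice(cats, p=cat_p))
            n_terms = int(rng.integers(1, 4))
            gterms = sorted(rng.choice(terms, size=n_terms, replace=False))
            if cat == "lncRNA":
                cds = None
            elif strand == "+":
                cds = (start, start + 1200)
            else:
                cds = (end - 1200, end)
            genes.append(
                {"gene_id": f"gene{gid:04d}", "chrom": chrom, "start": start,
                 "end": end, "strand": strand, "category": cat, "cds": cds,
                 "terms": list(gterms)}
            )
    return genes


def write_synthetic_dataset(state: SimState, reads: SyncTable, outdir: str | Path) -> dict:
    """Write the full synthetic dataset; byte-identical under a fixed seed.

    Emits: ``synthetic.sync``, ``samples.tsv``, ``truth.tsv`` (selected
    loci with labels), ``genes.gff3``, ``categories.tsv``, ``go_map.tsv``
    and ``reference.fa``.  Returns the path map.
    """
    cfg = state.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sync": outdir / "synthetic.sync",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "gff3": outdir / "genes.gff3",
        "categories": outdir / "categories.tsv",
        "go_map": outdir / "go_map.tsv",
        "fasta": outdir / "reference.fa",
    }
    write_sync(reads, paths["sync"])
    write_sample_sheet(cfg.sample_sheet(), paths["samples"])

    sel = np.nonzero(state.labels != NEUTRAL)[0]
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\tunit\trole\n")
        for j in sel:
            role = "target" if state.is_target[j] else "hitchhiker"
            fh.write(
                f"{state.loci_chrom[j]}\t{state.loci_pos[j] + 1}\t{state.ref_base[j]}"
                f"\t{state.alt_base[j]}\t{LABEL_NAMES[int(state.labels[j])]}"
                f"\t{int(state.clusters[j])}\t{role}\n"
            )

    genes = toy_annotation(cfg, selected_unit_spans(state))
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g['chrom']}\tpoolcare\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )
            if g["cds"] is not None:
                s, e = g["cds"]
                fh.write(
                    f"{g['chrom']}\tpoolcare\tCDS\t{s + 1}\t{e}\t.\t{g['strand']}\t0\t"
                    f"ID={g['gene_id']}.cds;Parent={g['gene_id']}\n"
                )
    with open(paths["categories"], "w") as fh:
        for g in genes:
            fh.write(f"{g['gene_id']}\t{g['category']}\n")
    with open(paths["go_map"], "w") as fh:
        for g in genes:
            for t in g["terms"]:
                fh.write(f"{g['gene_id']}\t{t}\n")
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(state.genome):
            fh.write(f">{chrom}\n")
            fh.write("\n".join(textwrap.wrap(state.genome[chrom], 60)))
            fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def block_structure_config(seed: int = 0) -> SimConfig:
    """Configuration emphasising shared block history: founder batches of
    the two blocks differ (jitter sd 0.1) while regime-consistent selection
    touches only 0.5% of loci, so the dominant covariance signal is the
    block, as when replicate blocks are founded a week apart from a
    shifting stock population."""
    return SimConfig(
        chrom_lengths={"chr1": 500_000, "chr2": 500_000},
        n_loci=5_000,
        selected_fraction=0.005,
        block_private_fraction=0.005,
        block_jitter_sd=0.10,
        emit_monomorphic=False,
        gene_spacing=50_000,
        seed=seed,
    )


def screen_config(seed: int = 0) -> SimConfig:
    """Configuration for the replicate-consistency screen experiment.

    The default experiment's SNP density (one variable locus per 25 bp) on
    a 6-Mb genome (SNP rows only), with exactly 50 consistently selected
    and 50 block-private loci planted.  The dense SNP map matters: window
    Fisher scores average ~20 SNPs, so independent single-locus drift
    extremes are damped while a driven locus still lifts its window in
    both blocks.  Selected loci are strongly driven sweeps from
    mid-frequency standing variants (founder frequency 0.3–0.6, s = 0.5),
    where the read-level Fisher contrast between a fixed NC allele and the
    relaxed FC population is greatest.  The window universe (~24k scored
    windows) makes the top-0.5% outlier set larger than the ~100 windows
    carrying planted signal (every locus lies in two overlapping windows).
    """
    return SimConfig(
        chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
        n_loci=240_000,
        selected_fraction=50 * 12 / 240_000,
        block_private_fraction=50 * 12 / 240_000,
        sweep_cluster_size=12,
        sweep_cluster_span=450,
        s_nc=0.5,
        selected_founder_range=(0.10, 0.40),
        emit_monomorphic=False,
        gene_spacing=50_000,
        seed=seed,
    )


def selected_unit_spans(state: SimState) -> pd.DataFrame:
    """One row per sweep unit: label, chrom, genomic span of its loci."""
    rows = []
    sel = state.clusters >= 0
    for cid in np.unique(state.clusters[sel]):
        idx = np.nonzero(state.clusters == cid)[0]
        rows.append(
            {
                "unit": int(cid),
                "label": LABEL_NAMES[int(state.labels[idx[0]])],
                "chrom": state.loci_chrom[idx[0]],
                "start": int(state.loci_pos[idx].min()),
                "end": int(state.loci_pos[idx].max()) + 1,
                "n_loci": len(idx),
            }
        )
    return pd.DataFrame(rows)
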