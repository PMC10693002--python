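"""Config-driven orchestration: simulate → diversity → coding πN/πS →
divergence screen → annotation → structure, with one seed and a
machine-readable summary.

The run directory receives per-window TSVs, the outlier BED, the Ω matrix
and newick tree, and ``summary.json``.  Every output is a pure function of
(config, seed): rerunning with the same seed reproduces the files
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotate_screen, coding_pi, divergence, diversity, popsim, structure
from .io_formats import (
    SampleSheet,
    SyncTable,
    apply_mask,
    read_bed_mask,
    read_gene_models,
    read_sample_sheet,
    read_sync,
    read_term_map,
    read_category_table,
)

log = logging.getLogger("poolcare")

DEFAULT_PARAMS: dict[str, Any] = {
    "min_cov": 40,
    "max_cov": 700,
    "min_count": 2,
    "min_covered_fraction": 0.6,
    "pi_window": 1000,
    "d_window": 500,
    "d_step": 250,
    "n_star": 40,
    "top_fraction": 0.005,
    "promoter_length": 500,
    "diverged_flank": 5000,
    "fisher_agg": "mean",
}


class ConfigError(ValueError):
    pass


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Validate and normalise a pipeline config; raises before any stage."""
    cfg = dict(config)
    params = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ConfigError(f"unknown params: {sorted(unknown)}")
    if params["max_cov"] < params["min_cov"]:
        raise ConfigError("max_cov must be >= min_cov")
    if not 0 < params["top_fraction"] <= 1:
        raise ConfigError("top_fraction must lie in (0, 1]")
    if params["d_window"] % params["d_step"] != 0:
        raise ConfigError("d_window must be a multiple of d_step")
    if params["n_star"] < 2:
        raise ConfigError("n_star must be >= 2")
    if params["fisher_agg"] not in ("mean", "sum"):
        raise ConfigError("fisher_agg must be 'mean' or 'sum'")
    for key in ("pi_window", "promoter_length", "diverged_flank"):
        if params[key] < 0:
            raise ConfigError(f"{key} must be non-negative")
    cfg["params"] = params
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or an 'inputs' section")
    if "inputs" in cfg:
        need = {"sync", "samples"}
        missing = need - set(cfg["inputs"])
        if missing:
            raise ConfigError(f"inputs section missing {sorted(missing)}")
        for k, path in cfg["inputs"].items():
            if not Path(path).exists():
                raise ConfigError(f"input {k} not found: {path}")
    if "simulate" in cfg:
        sim_fields = {f.name for f in dataclasses.fields(popsim.SimConfig)}
        unknown = set(cfg["simulate"]) - sim_fields
        if unknown:
            raise ConfigError(f"unknown simulate options: {sorted(unknown)}")
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if math.isnan(v) else v
    if isinstance(x, np.bool_):
        return bool(x)
    return x


def _block_compare(windows: pd.DataFrame, sheet: SampleSheet, column: str, test: str):
    """FC-vs-NC comparison of usable windows per block; returns summary dict."""
    usable = windows[windows["usable"]]
    out = {}
    for block, (fc, nc) in sheet.pairs_by_block().items():
        a = usable[usable["pop"] == sheet.names[fc]][column]
        b = usable[usable["pop"] == sheet.names[nc]][column]
        stat, p = diversity.compare_windows(a, b, test=test)
        out[f"block{block}"] = {
            "fc": sheet.names[fc],
            "nc": sheet.names[nc],
            f"{column}_fc_median": float(np.nanmedian(a)),
            f"{column}_nc_median": float(np.nanmedian(b)),
            f"{column}_fc_mean": float(np.nanmean(a)),
            f"{column}_nc_mean": float(np.nanmean(b)),
            "statistic": float(stat),
            "p_value": float(p),
            "test": test,
        }
    return out


def run_pipeline(
    config: Mapping[str, Any],
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run all stages; returns the summary dict (also written as JSON)."""
    cfg = validate_config(config)
    params = cfg["params"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(cfg.get("seed", 0))

    summary: dict[str, Any] = {"seed": seed}

    # ------------------------------------------------------------------ inputs
    if "simulate" in cfg:
        log.info("simulating experiment (seed=%d)", seed)
        sim_cfg = popsim.SimConfig(**{**cfg["simulate"], "seed": seed})
        state = popsim.simulate_experiment(sim_cfg)
        table = popsim.pool_seq_reads(state)
        paths = popsim.write_synthetic_dataset(state, table, outdir / "synthetic")
        sheet = sim_cfg.sample_sheet()
        genes = read_gene_models(paths["gff3"], paths["categories"])
        categories = read_category_table(paths["categories"])
        term_map = read_term_map(paths["go_map"])
        ref = state.genome
        chrom_lengths = dict(sim_cfg.chrom_lengths)
        summary["simulate"] = {
            "n_loci": sim_cfg.n_loci,
            "n_selected_consistent": int((state.labels == popsim.CONSISTENT).sum()),
            "n_selected_private": int((state.labels >= popsim.PRIVATE_B1).sum()),
            "generations": sim_cfg.generations,
        }
    else:
        inputs = cfg["inputs"]
        sheet = read_sample_sheet(inputs["samples"])
        table = read_sync(inputs["sync"], sheet.names)
        genes = (
            read_gene_models(inputs["gff3"], inputs.get("categories"))
            if "gff3" in inputs
            else []
        )
        categories = (
            read_category_table(inputs["categories"]) if "categories" in inputs else {}
        )
        term_map = read_term_map(inputs["go_map"]) if "go_map" in inputs else {}
        if "fasta" in inputs:
            import pyfaidx

            fa = pyfaidx.Fasta(inputs["fasta"])
            ref = fa
            chrom_lengths = {name: len(fa[name]) for name in fa.keys()}
        else:
            ref = None
            chrom_lengths = None
        if "mask" in inputs:
            table = apply_mask(table, read_bed_mask(inputs["mask"]))

    div_params = diversity.DiversityParams(
        min_cov=params["min_cov"],
        max_cov=params["max_cov"],
        min_count=params["min_count"],
        min_covered_fraction=params["min_covered_fraction"],
    )
    calls = diversity.call_sites(table, div_params)
    pairs = sheet.pairs_by_block()

    # --------------------------------------------------------------- diversity
    log.info("windowed pi/theta (%d-bp windows)", params["pi_window"])
    tp = diversity.window_theta_pi(
        table, div_params, params["pi_window"], chrom_lengths, calls=calls
    )
    tp.to_csv(outdir / "theta_pi_windows.tsv", sep="\t", index=False)
    summary["theta"] = _block_compare(tp, sheet, "theta_w", "kruskal_wallis")
    summary["pi"] = _block_compare(tp, sheet, "pi", "kruskal_wallis")

    log.info("Tajima's D (%d/%d windows, n*=%d)", params["d_window"], params["d_step"],
             params["n_star"])
    td = diversity.window_tajima_d(
        table, div_params, params["d_window"], params["d_step"], params["n_star"],
        seed=seed, chrom_lengths=chrom_lengths, calls=calls,
    )
    td.to_csv(outdir / "tajima_d_windows.tsv", sep="\t", index=False)
    summary["tajima_d"] = _block_compare(td, sheet, "tajima_d", "welch_t")

    # --------------------------------------------------------------- coding pi
    if genes and ref is not None:
        log.info("genewise piN/piS over %d genes", len(genes))
        gw = coding_pi.genewise_pi_table(genes, calls, ref)
        gw.to_csv(outdir / "genewise_pin_pis.tsv", sep="\t", index=False)
        med = coding_pi.population_summary(gw)
        summary["pin_pis"] = {"median_by_pop": {k: _jsonable(v) for k, v in med.items()}}
        for block, (fc, nc) in pairs.items():
            a = gw[gw["pop"] == sheet.names[fc]]["ratio"]
            b = gw[gw["pop"] == sheet.names[nc]]["ratio"]
            try:
                stat, p = diversity.compare_windows(a, b, test="kruskal_wallis")
            except ValueError:
                stat, p = float("nan"), float("nan")
            summary["pin_pis"][f"block{block}"] = {
                "statistic": _jsonable(stat), "p_value": _jsonable(p),
            }
    else:
        gw = None

    # -------------------------------------------------------------- divergence
    log.info("per-block divergence and consistency screen")
    block_windows = {}
    for block, (fc, nc) in pairs.items():
        dv = divergence.pair_divergence(
            table, fc, nc, div_params, params["d_window"], params["d_step"],
            params["fisher_agg"], calls=calls,
        )
        dv.to_csv(outdir / f"divergence_block{block}.tsv", sep="\t", index=False)
        block_windows[block] = dv
    blocks = sorted(block_windows)
    screen = divergence.consistency_screen(
        block_windows[blocks[0]], block_windows[blocks[1]], top=params["top_fraction"]
    )
    screen.to_csv(outdir / "consistency_screen.tsv", sep="\t", index=False)
    bed = divergence.outlier_bed(screen)
    bed.to_csv(outdir / "outlier_windows.bed", sep="\t", index=False, header=False)
    summary["divergence"] = {
        "n_windows": int(len(screen)),
        "n_outliers": int(screen["outlier"].sum()),
        "mean_fst_block1": _jsonable(np.nanmean(block_windows[blocks[0]]["fst"])),
        "mean_fst_block2": _jsonable(np.nanmean(block_windows[blocks[1]]["fst"])),
    }

    # -------------------------------------------------------------- annotation
    if genes:
        hits = annotate_screen.intersect_features(
            bed, genes, chrom_lengths, params["promoter_length"]
        )
        hit_summary = annotate_screen.categorize_hits(hits, categories)
        hits_out = hits.copy()
        hits_out["genes"] = hits_out["genes"].map(",".join)
        hits_out["utr5_genes"] = hits_out["utr5_genes"].map(",".join)
        hits_out.to_csv(outdir / "outlier_annotation.tsv", sep="\t", index=False)
        summary["annotation"] = {
            "n_outlier_windows": hit_summary.n_windows,
            "n_diverged_genes": len(hit_summary.genes),
            "n_utr5_only_genes": len(hit_summary.utr5_only_genes),
            "category_counts": hit_summary.category_counts,
            "feature_fractions": {k: _jsonable(v) for k, v in
                                  hit_summary.feature_fractions.items()},
        }
        if term_map:
            enr = annotate_screen.enrichment_test(
                hit_summary.genes, [g.gene_id for g in genes], term_map
            )
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["annotation"]["n_terms_tested"] = int(len(enr))
            summary["annotation"]["n_terms_q_lt_0.05"] = int((enr["q"] < 0.05).sum())

        # diversity restricted to diverged genes +/- flank
        diverged = [g for g in genes if g.gene_id in set(hit_summary.genes)]
        if diverged:
            summary["tajima_d_diverged"] = {}
            for block, (fc, nc) in pairs.items():
                usable = td[td["usable"]]
                a = usable[usable["pop"] == sheet.names[fc]]
                b = usable[usable["pop"] == sheet.names[nc]]
                try:
                    stat, p = diversity.compare_windows(
                        a, b, test="welch_t",
                        region_filter=(diverged, params["diverged_flank"]),
                        value_column="tajima_d",
                    )
                except ValueError:
                    stat, p = float("nan"), float("nan")
                af = diversity.filter_windows_by_genes(a, diverged, params["diverged_flank"])
                bf = diversity.filter_windows_by_genes(b, diverged, params["diverged_flank"])
                summary["tajima_d_diverged"][f"block{block}"] = {
                    "tajima_d_fc_mean": _jsonable(np.nanmean(af["tajima_d"])),
                    "tajima_d_nc_mean": _jsonable(np.nanmean(bf["tajima_d"])),
                    "statistic": _jsonable(stat),
                    "p_value": _jsonable(p),
                }
            if gw is not None and len(gw):
                dg = gw[gw["gene_id"].isin(set(hit_summary.genes))]
                med = dg.groupby("pop")["ratio"].median()
                summary["pin_pis_diverged"] = {
                    "median_by_pop": {k: _jsonable(v) for k, v in med.items()}
                }

    # --------------------------------------------------------------- structure
    log.info("omega matrix and correlation tree")
    freqs, _ = structure.population_frequencies(table, div_params, calls=calls)
    om = structure.omega_matrix(freqs, pops=sheet.names)
    pd.DataFrame(om.omega, index=sheet.names, columns=sheet.names).to_csv(
        outdir / "omega.tsv", sep="\t"
    )
    newick = structure.correlation_tree(om)
    (outdir / "correlation_tree.nwk").write_text(newick + "\n")
    summary["structure"] = {
        "n_snps": om.n_snps,
        "correlation": {
            f"{sheet.names[i]}:{sheet.names[j]}": _jsonable(om.correlation[i, j])
            for i in range(len(sheet.names))
            for j in range(i + 1, len(sheet.names))
        },
        "tree": newick,
    }

    summary = _jsonable(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )
    return summary
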