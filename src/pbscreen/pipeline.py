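"""End-to-end orchestration of the simulate -> screen-call and
simulate -> DE -> rescue stage chains, driven by a YAML config.

All randomness derives from one top-level seed, split deterministically per
stage; every emitted artifact is recorded in a JSON manifest with its
sha256 checksum and the parameters that produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import __version__, de, rescue, screen
from .io import sha256_of, write_bed_records, write_fasta, write_gtf, write_tsv
from .sim import (
    SimCountsConfig,
    SimScreenConfig,
    simulate_annotation,
    simulate_counts,
    simulate_screen,
)

log = logging.getLogger("pbscreen")

STAGE_ORDER = ["sim_screen", "screen_call", "sim_counts", "de", "rescue"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", [])
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return cfg


def run_end_to_end(config: dict, outdir: str | Path) -> dict:
    """Run the selected stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = [s for s in STAGE_ORDER if s in config.get("stages", [])]
    manifest: dict = {"version": __version__, "seed": seed, "stages": stages, "artifacts": {}}

    def emit(name: str, path: Path, params: dict) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": sha256_of(path),
            "params": {k: repr(v) for k, v in params.items()},
        }

    # validate referenced input paths before any computation
    for stage in stages:
        for key in ("counts", "samples", "bed", "gtf", "fasta"):
            val = config.get(stage, {}).get(key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"stage {stage}: input {key}={val} does not exist")

    state: dict = {}
    for stage in stages:
        log.info("stage %s", stage)
        params = dict(config.get(stage, {}))
        if stage == "sim_screen":
            params["suppressor_genes"] = frozenset(params.get("suppressor_genes", []))
            scfg = SimScreenConfig(seed=seed, **{k: v for k, v in params.items() if k != "seed"})
            genome, genes, ttaa = simulate_annotation(scfg)
            records, truth = simulate_screen(scfg, genes, ttaa)
            write_fasta(genome, outdir / "genome.fa")
            write_gtf(genes, outdir / "genes.gtf")
            write_bed_records(records, outdir / "integrations.bed")
            write_tsv(truth.true_sites, outdir / "screen_truth_sites.tsv")
            state.update(genome=genome, genes=genes, ttaa=ttaa, records=records)
            for name in ["genome.fa", "genes.gtf", "integrations.bed", "screen_truth_sites.tsv"]:
                emit(name, outdir / name, params)
        elif stage == "screen_call":
            ccfg = screen.ScreenCallConfig(**params)
            collapsed = screen.collapse_records(state["records"])
            report = screen.validate_ttaa(collapsed.sites, state["genome"])
            valid = {
                (r.chrom, int(r.pos), r.orientation)
                for r in report.itertuples(index=False)
                if r.ttaa_ok
            }
            assignments = screen.assign_genes(valid, state["genes"], ccfg)
            tallies = screen.tally_gene_events(assignments, collapsed.events)
            index = screen.build_ttaa_index(state["genome"], state["genes"], ccfg, state.get("ttaa"))
            hits = screen.call_candidates(tallies, index, ccfg, n_total_sites=len(valid))
            write_tsv(report, outdir / "sites.tsv", params)
            write_tsv(assignments, outdir / "assignments.tsv", params)
            write_tsv(hits, outdir / "hits.tsv", params)
            state["hits"] = hits
            for name in ["sites.tsv", "assignments.tsv", "hits.tsv"]:
                emit(name, outdir / name, params)
        elif stage == "sim_counts":
            if "condition_layout" in params:
                params["condition_layout"] = tuple(
                    (str(c), int(n)) for c, n in params["condition_layout"]
                )
            ccfg = SimCountsConfig(seed=seed, **{k: v for k, v in params.items() if k != "seed"})
            matrix, truth = simulate_counts(ccfg)
            matrix.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
            write_tsv(
                truth.true_lfc.rename_axis("gene_id").reset_index(),
                outdir / "counts_truth_lfc.tsv",
            )
            state.update(matrix=matrix, counts_truth=truth, counts_cfg=ccfg)
            for name in ["counts.tsv", "samples.tsv", "counts_truth_lfc.tsv"]:
                emit(name, outdir / name, params)
        elif stage == "de":
            if "matrix" not in state:
                state["matrix"] = de.CountMatrix.from_tsv(params["counts"], params["samples"])
            rule = de.FilterRule(**params.get("filter", {}))
            thresholds = de.DEGThresholds(
                lfc_threshold=params.get("lfc", 0.5), p_threshold=params.get("p", 0.05)
            )
            matrix = de.filter_low_counts(state["matrix"], rule)
            factors = de.estimate_size_factors(matrix)
            state["de_tables"] = {}
            for pair in params["contrasts"]:
                a, b = pair
                res = de.run_contrast(matrix, (a, b), factors)
                degs = de.call_degs(res, thresholds)
                tag = f"{a}_vs_{b}"
                write_tsv(res, outdir / f"de_{tag}.tsv", params)
                write_tsv(degs, outdir / f"degs_{tag}.tsv", params)
                state["de_tables"][(a, b)] = res
                state.setdefault("deg_tables", {})[(a, b)] = degs
                emit(f"de_{tag}.tsv", outdir / f"de_{tag}.tsv", params)
                emit(f"degs_{tag}.tsv", outdir / f"degs_{tag}.tsv", params)
        elif stage == "rescue":
            rule = rescue.RescueRule(**params.get("rule", {}))
            healthy = params["healthy"]
            disease = params["disease"]
            suppressor = params["suppressor"]
            degs = state["deg_tables"][(disease, healthy)]
            calls, frac = rescue.classify_rescue(
                degs,
                state["de_tables"][(suppressor, healthy)],
                state["de_tables"][(suppressor, disease)],
                rule,
            )
            write_tsv(calls, outdir / "rescue_calls.tsv", {**params, "fraction_pct": frac})
            manifest["rescue_fraction_pct"] = frac
            emit("rescue_calls.tsv", outdir / "rescue_calls.tsv", params)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
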