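"""End-to-end pipeline orchestration from a YAML/TOML-style config.

``run_pipeline`` executes simulate -> features -> replicate merging ->
peptide mapping -> statistics and writes tidy TSV/FASTA/JSON outputs plus a
run manifest (seed, parameters, per-stage record counts). Reruns with the
same config are byte-identical apart from nothing: no timestamps are
written.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import export_reference_fasta
from .features import (
    evenness_profile,
    gene_usage,
    jaccard_overlap,
    light_chain_coherence_within,
    usage_correlation,
)
from .mapping import (
    build_reference_index,
    class_switch_table,
    classify_matches,
    match_peptides,
    reconstruct_vdj,
    recover_paired_chain,
)
from .merge import depth_overlap_curve, merge_cumulative
from .simulate import (
    SimulationConfig,
    default_germline,
    generate_contaminants,
    generate_decoy_reference,
    simulate_abseq_run,
    simulate_paired_repertoire,
    simulate_repertoire,
    subsample_replicates,
)
from .stats import compare_groups

logger = logging.getLogger("abseqmap")

__all__ = ["run_pipeline", "load_config", "default_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs from
    completed stages remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def default_config() -> dict:
    return {
        "seed": 0,
        "n_donors": 4,
        "bulk_clonotypes": 2000,
        "sc_cells": 600,
        "replicates": {"k": 4, "depth": 100, "orderings": 5},
        "light_chain_coherence": 0.9,
        "serum": {"n_clonotypes": 30, "rank_bias": 0.0,
                  "contaminant_rate": 0.05, "decoy_rate": 0.05},
        "min_cdr3_overlap": 3,
        "il_equivalence": False,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = default_config()
    merged.update(cfg or {})
    return merged


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run all stages per config, writing outputs under ``outdir``.

    Returns the run manifest (also written to manifest.json).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config, "counts": {}}
    seed = int(config["seed"])

    def _stage(name):
        logger.info("stage %s", name)
        return name

    stage = _stage("simulate")
    try:
        heavy_g = default_germline("heavy")
        light_g = default_germline("kappa")
        donors = [f"D{i + 1}" for i in range(int(config["n_donors"]))]
        sim = SimulationConfig(
            n_clonotypes=int(config["bulk_clonotypes"]),
            light_chain_coherence=float(config["light_chain_coherence"]),
            serum_rank_bias=float(config["serum"]["rank_bias"]),
            n_serum_clonotypes=int(config["serum"]["n_clonotypes"]),
            contaminant_rate=float(config["serum"]["contaminant_rate"]),
            decoy_rate=float(config["serum"]["decoy_rate"]),
            seed=seed,
        )
        bulk_reps = [
            simulate_repertoire(sim, heavy_g, donor=d, method="bulk") for d in donors
        ]
        sc_reps = [
            simulate_paired_repertoire(
                sim, heavy_g, light_g, donor=d, n_cells=int(config["sc_cells"])
            )
            for d in donors
        ]
        manifest["counts"]["bulk_clonotypes"] = sum(r.n for r in bulk_reps)
        manifest["counts"]["sc_cells"] = sum(len(r.cells) for r in sc_reps)
        export_reference_fasta(bulk_reps + sc_reps, outdir / "reference.fasta")
    except Exception as e:  # noqa: BLE001 - abort names the stage
        raise PipelineError(stage, e) from e

    stage = _stage("features")
    try:
        profiles = [gene_usage(r) for r in bulk_reps + sc_reps]
        corr = usage_correlation(profiles)
        corr.to_frame().to_csv(outdir / "usage_correlation.tsv", sep="\t")
        corr.to_long().to_csv(outdir / "usage_correlation_long.tsv", sep="\t", index=False)
        overlaps = []
        reps = bulk_reps + sc_reps
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                overlaps.append(
                    {
                        "sample_a": reps[i].sample_id,
                        "sample_b": reps[j].sample_id,
                        "metric": "jaccard_cdr3",
                        "value": jaccard_overlap(reps[i].cdr3_set(), reps[j].cdr3_set()),
                        "same_donor": reps[i].donor == reps[j].donor,
                    }
                )
        overlap_df = pd.DataFrame(overlaps)
        overlap_df.to_csv(outdir / "cdr3_overlap.tsv", sep="\t", index=False)
        evenness = pd.concat(
            [
                evenness_profile(r).to_frame().assign(sample_id=r.sample_id)
                for r in reps
            ]
        )
        evenness.to_csv(outdir / "evenness.tsv", sep="\t", index=False)
        lcc_rows = [
            {
                "sample_id": r.sample_id,
                "scope": "within_donor",
                "n_eligible_pairs": (res := light_chain_coherence_within(r)).n_eligible_pairs,
                "n_coherent_pairs": res.n_coherent_pairs,
                "coherence_pct": res.coherence_pct,
            }
            for r in sc_reps
        ]
        pd.DataFrame(lcc_rows).to_csv(outdir / "lcc.tsv", sep="\t", index=False)
        manifest["counts"]["pairwise_overlaps"] = len(overlap_df)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = _stage("replicate_merge")
    try:
        rcfg = config["replicates"]
        k, depth = int(rcfg["k"]), int(rcfg["depth"])
        if depth > len(sc_reps[0].cells):
            raise ValueError(
                f"replicate depth {depth} exceeds simulated cells {len(sc_reps[0].cells)}"
            )
        replicates = subsample_replicates(sc_reps[0], k=k, depth=depth, seed=seed)
        if int(rcfg.get("merge_k", k)) > len(replicates):
            raise ValueError("merge k exceeds number of simulated replicates")
        merged = merge_cumulative(replicates, k=k, seed=seed)
        curve = depth_overlap_curve(
            bulk_reps[0], replicates, seeds=[seed + i for i in range(int(rcfg["orderings"]))]
        )
        curve.to_csv(outdir / "depth_overlap_curve.tsv", sep="\t", index=False)
        manifest["counts"]["merged_cells"] = len(merged.cells)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = _stage("map_peptides")
    try:
        decoys = generate_decoy_reference(
            200, heavy_g, seed=seed + 17,
            true_sequences={ct.vdj_aa for r in bulk_reps + sc_reps for ct in r.clonotypes},
        )
        contaminants = generate_contaminants(seed=seed + 23)
        peptides = simulate_abseq_run(
            [bulk_reps[0], sc_reps[0]], sim,
            contaminants=contaminants, decoys=decoys,
        )
        peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        index = build_reference_index(
            [bulk_reps[0]], [sc_reps[0]], decoys=decoys, contaminants=contaminants
        )
        matches = match_peptides(peptides, index, il_equivalence=bool(config["il_equivalence"]))
        matches, ladder = classify_matches(
            matches, index, min_cdr3_overlap=int(config["min_cdr3_overlap"])
        )
        ladder.to_frame().to_csv(outdir / "filter_ladder.tsv", sep="\t", index=False)
        identifications = []
        fasta_rows = []
        for m in matches:
            if not m.uniquely_mapped:
                continue
            ic = reconstruct_vdj(m, index, rank_reference=bulk_reps[0])
            if ic.source in ("sc", "both"):
                try:
                    ic = recover_paired_chain(ic, sc_reps[0])
                except ValueError:
                    pass
            identifications.append(
                {
                    "peptide": m.peptide.sequence,
                    "clonotype_key": ic.clonotype_key,
                    "chain": ic.chain,
                    "v_gene": ic.v_gene,
                    "j_gene": ic.j_gene,
                    "cdr3_aa": ic.cdr3_aa,
                    "source": ic.source,
                    "clonal_rank": ic.clonal_rank,
                    "partner_v_gene": ic.partner_v_gene,
                    "partner_cdr3_aa": ic.partner_cdr3_aa,
                }
            )
            fasta_rows.append(ic)
        pd.DataFrame(
            identifications,
            columns=[
                "peptide", "clonotype_key", "chain", "v_gene", "j_gene",
                "cdr3_aa", "source", "clonal_rank", "partner_v_gene",
                "partner_cdr3_aa",
            ],
        ).to_csv(outdir / "identifications.tsv", sep="\t", index=False)
        with open(outdir / "recovered_vdj.fasta", "w") as fh:
            for i, ic in enumerate(fasta_rows):
                fh.write(f">id{i}|{ic.clonotype_key}|{ic.chain}|{ic.source}\n{ic.vdj_aa}\n")
                if ic.partner_vdj_aa:
                    fh.write(f">id{i}|partner|{ic.partner_cdr3_aa}\n{ic.partner_vdj_aa}\n")
        class_switch_table(matches, index).to_csv(outdir / "class_switch.tsv", sep="\t")
        manifest["counts"]["peptides"] = len(peptides)
        manifest["counts"]["filter_ladder"] = {
            "all": ladder.all,
            "antibody_specific": ladder.antibody_specific,
            "cdr3_overlapping": ladder.cdr3_overlapping,
            "uniquely_mapped": ladder.uniquely_mapped,
            "multi_mapped": ladder.multi_mapped,
        }
        manifest["counts"]["identifications"] = len(identifications)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = _stage("stats")
    try:
        cmp = compare_groups(
            overlap_df["value"].to_numpy(),
            overlap_df["same_donor"].map({True: "same_donor", False: "different_donor"}),
        )
        stats_out = {
            "global_p": cmp.global_p,
            "medians": cmp.medians,
            "group_sizes": cmp.group_sizes,
            "pairwise_adjusted": cmp.pairwise_adjusted.to_dict(),
        }
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=2, sort_keys=True)
    except Exception as e:
        raise PipelineError(stage, e) from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
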