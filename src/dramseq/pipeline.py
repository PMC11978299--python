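"""End-to-end orchestration: simulate -> pileup -> call -> annotate/motif/quant.

``run_pipeline`` consumes a plain config dict (typically loaded from YAML),
writes every stage's table under the output directory and records a manifest
with the package version, a hash of the config, the seeds used and per-stage
row counts.  Re-running with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict
from itertools import combinations

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    assign_regions,
    distance_histogram,
    distance_to_reference,
    metagene_profile,
)
from .calling import (
    HIGH_CONFIDENCE,
    FilterParams,
    assign_genes,
    call_replicated_sites,
    deaminase_appeared,
    high_confidence_tier,
    merge_editor_genes,
    subtract_background,
    write_sites_bed,
)
from .genemodel import write_bed12
from .motif import build_pfm, extract_flanks, write_flanks_fasta, write_pfm
from .pileup import build_pileup, extract_candidates
from .quantify import replicate_correlation
from .simulate import (
    ConditionSpec,
    generate_transcriptome,
    plant_m5c_sites,
    simulate_reads,
    write_fasta,
    write_truth,
)

logger = logging.getLogger(__name__)

CONVERSION_OF = {"ABE": "A2G", "CBE": "C2U"}
# fixed per-condition seed offsets so replicate streams never collide
_CONDITION_OFFSET = {"DRAM": 0, "KNOCKOUT": 100, "DEAMINASE_ONLY": 200, "DRAM_MUT": 300}

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "read_length": 100,
    "simulator": {
        "n_transcripts": 20,
        "length_range": [600, 1200],
        "utr_cds_fractions": [0.2, 0.5, 0.3],
        "n_sites": 40,
        "editors": ["CBE"],
        "rate_range": [0.1, 0.4],
        "window_halfwidth": 20,
        "region_weights": {"CDS": 0.5, "UTR3": 0.35, "UTR5": 0.15},
    },
    "conditions": {
        "DRAM": {
            "replicate_count": 3,
            "coverage_mean": 100,
            "rate_multiplier": 1.0,
            "background_rate": 0.0002,
            "error_rate": 0.001,
        },
        "KNOCKOUT": {
            "replicate_count": 1,
            "coverage_mean": 100,
            "rate_multiplier": 0.1,
            "background_rate": 0.0002,
            "error_rate": 0.001,
        },
        "DEAMINASE_ONLY": {
            "replicate_count": 2,
            "coverage_mean": 100,
            "rate_multiplier": 0.0,
            "background_rate": 0.001,
            "background_region_bias": 3.0,
            "error_rate": 0.001,
        },
    },
    "filter": {},
    "high_confidence": {
        "ratio_min": 0.10,
        "ratio_max": 0.60,
        "fold_vs_knockout": 2.0,
        "min_edited_reads": 4,
    },
    "metagene_bins": 90,
    "distance_window": 3000,
    "flank_k": 20,
}


def _merged(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merged(out[k], v)
        else:
            out[k] = v
    return out


def merge_config(user: dict) -> dict:
    """Overlay a user config on the defaults.

    Blocks deep-merge, except that a user-supplied ``conditions`` mapping
    defines the condition set itself (each named condition still inherits
    defaults for unspecified fields) — otherwise a condition could never be
    dropped.
    """
    merged = _merged(DEFAULT_CONFIG, user)
    if "conditions" in user:
        merged["conditions"] = {
            name: _merged(DEFAULT_CONFIG["conditions"].get(name, {}), block or {})
            for name, block in user["conditions"].items()
        }
    return merged


def load_config(path: str | None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def run_pipeline(config: dict, outdir: str, seed: int | None = None) -> dict:
    """Run the whole workflow; returns the manifest dict (also written to disk)."""
    config = merge_config(config)
    if seed is not None:
        config["seed"] = seed
    seed = int(config["seed"])
    os.makedirs(outdir, exist_ok=True)
    sim = config["simulator"]
    read_length = int(config["read_length"])
    params = FilterParams(**config["filter"])
    hc_params = FilterParams(**_merged(config["filter"], config["high_confidence"]))

    counts: dict = {}
    outputs: dict = {}

    transcriptome = generate_transcriptome(
        n_transcripts=int(sim["n_transcripts"]),
        length_range=tuple(sim["length_range"]),
        utr_cds_fractions=tuple(sim["utr_cds_fractions"]),
        seed=seed,
    )
    fasta = os.path.join(outdir, "reference.fa")
    bed = os.path.join(outdir, "genes.bed")
    write_fasta(transcriptome.references, fasta)
    write_bed12(transcriptome.genes, bed)
    outputs["reference"] = fasta
    outputs["gene_model"] = bed
    counts["transcripts"] = len(transcriptome.genes)

    editors = list(sim.get("editors") or [sim.get("editor", "CBE")])
    sites_by_editor: dict[str, pd.DataFrame] = {}
    all_truth = []
    dram_candidate_sets: dict[str, list[pd.DataFrame]] = {}
    for ei, editor in enumerate(editors):
        conv = CONVERSION_OF[editor]
        truth = plant_m5c_sites(
            transcriptome,
            n_sites=int(sim["n_sites"]),
            region_weights=sim["region_weights"],
            rate_range=tuple(sim["rate_range"]),
            window_halfwidth=int(sim["window_halfwidth"]),
            editor=editor,
            seed=seed + 1 + ei,
        )
        all_truth.extend(truth)
        counts[f"planted_sites_{editor}"] = len(truth)

        per_condition: dict[str, list[pd.DataFrame]] = {}
        pileups: dict[str, list[pd.DataFrame]] = {}
        for cond_name, block in config["conditions"].items():
            spec = ConditionSpec(
                condition=cond_name,
                seed=seed + 10_000 * (ei + 1) + _CONDITION_OFFSET[cond_name],
                **block,
            )
            sams = simulate_reads(
                transcriptome,
                truth,
                spec,
                read_length=read_length,
                out_dir=os.path.join(outdir, "alignments"),
                editor=editor,
            )
            cands, piles = [], []
            for sam in sams:
                pile = build_pileup(sam, transcriptome.references)
                piles.append(pile)
                cands.append(extract_candidates(pile, transcriptome, conv))
            per_condition[cond_name] = cands
            pileups[cond_name] = piles
            counts[f"candidates_{editor}_{cond_name}"] = sum(len(c) for c in cands)

        ko_cands = ko_pile = None
        if "KNOCKOUT" in per_condition:
            ko_cands = pd.concat(per_condition["KNOCKOUT"], ignore_index=True)
            ko_pile = pd.concat(pileups["KNOCKOUT"], ignore_index=True)
        else:
            logger.warning(
                "no KNOCKOUT condition configured: fold-vs-knockout filter disabled"
            )
        called = call_replicated_sites(
            per_condition["DRAM"], ko_cands, params, knockout_pileup=ko_pile
        )
        background = deaminase_appeared(per_condition.get("DEAMINASE_ONLY", []), params)
        called = subtract_background(called, background)
        called = assign_genes(called, transcriptome)
        hc = high_confidence_tier(called, hc_params)
        sites_tsv = os.path.join(outdir, f"sites_{editor}.tsv")
        called.to_csv(sites_tsv, sep="\t", index=False)
        hc.to_csv(os.path.join(outdir, f"sites_{editor}_high_confidence.tsv"), sep="\t", index=False)
        write_sites_bed(called, os.path.join(outdir, f"sites_{editor}.bed"))
        outputs[f"sites_{editor}"] = sites_tsv
        counts[f"called_sites_{editor}"] = len(called)
        counts[f"high_confidence_sites_{editor}"] = len(hc)
        counts[f"background_removed_{editor}"] = len(background)
        sites_by_editor[editor] = called
        dram_candidate_sets[editor] = per_condition["DRAM"]

    truth_path = os.path.join(outdir, "truth.tsv")
    write_truth(all_truth, truth_path)
    outputs["truth"] = truth_path

    all_sites = pd.concat(sites_by_editor.values(), ignore_index=True)

    regions = assign_regions(all_sites, transcriptome)
    regions.to_csv(os.path.join(outdir, "regions.tsv"), sep="\t", index=False)
    profile = metagene_profile(regions, n_bins=int(config["metagene_bins"]))
    profile.table.to_csv(os.path.join(outdir, "metagene.tsv"), sep="\t", index=False)
    counts["exonic_sites"] = profile.n_sites

    reference_m5c = pd.DataFrame(
        {
            "ref": [s.transcript_id for s in all_truth],
            "pos": [
                transcriptome.gene_by_id(s.transcript_id).to_genomic(s.position)
                for s in all_truth
            ],
        }
    )
    records = distance_to_reference(
        all_sites, reference_m5c, transcriptome, window=int(config["distance_window"])
    )
    records.to_csv(os.path.join(outdir, "distances.tsv"), sep="\t", index=False)
    distance_histogram(records).to_csv(
        os.path.join(outdir, "distance_histogram.tsv"), sep="\t", index=False
    )
    counts["distance_records"] = len(records)

    if len(all_sites):
        flanks = extract_flanks(all_sites, transcriptome, k=int(config["flank_k"]))
        write_flanks_fasta(flanks, os.path.join(outdir, "flanks.fa"))
        pfm = build_pfm(flanks["flank"])
        write_pfm(pfm, os.path.join(outdir, "pfm.tsv"))
        counts["flank_sequences"] = pfm.n_sequences

    correlations = {}
    for editor, reps in dram_candidate_sets.items():
        gene_counts = []
        for rep in reps:
            annotated = assign_genes(rep, transcriptome) if len(rep) else rep
            if len(rep):
                per_gene = (
                    annotated.assign(gene_id=annotated["gene_id"].str.split(","))
                    .explode("gene_id")
                    .groupby("gene_id")["edited_reads"]
                    .sum()
                )
            else:
                per_gene = pd.Series(dtype=float)
            gene_counts.append(per_gene)
        for i, j in combinations(range(len(gene_counts)), 2):
            try:
                r = replicate_correlation(gene_counts[i], gene_counts[j])
            except ValueError:
                r = float("nan")
            correlations[f"{editor}_rep{i + 1}_vs_rep{j + 1}"] = r
    pd.Series(correlations, name="pearson_r").rename_axis("pair").to_csv(
        os.path.join(outdir, "replicate_correlation.tsv"), sep="\t"
    )

    outputs = {k: os.path.relpath(v, outdir) for k, v in outputs.items()}
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "filter_params": asdict(params),
        "high_confidence_params": asdict(hc_params),
        "row_counts": counts,
        "replicate_correlations": correlations,
        "outputs": outputs,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
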