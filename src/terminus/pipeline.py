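"""End-to-end orchestration: simulate -> annotate -> quantify -> diffapa ->
pas -> clones, with deterministic seeding and a run manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleavage_mapping, differential_apa, end_annotation, isoform_quant, pas_analysis
from .config import PipelineConfig, config_hash
from .io_formats import CoverageTrack, UtrIsoform, write_ends_bed
from .synthetic_data import (
    COMPARTMENTS,
    SimConfig,
    SyntheticDataset,
    impa1_fixture,
    shift_study_loci,
    simulate_dataset,
)

logger = logging.getLogger("terminus")

__all__ = ["run_pipeline", "simulate_stage", "annotate_stage", "quantify_stage"]


def simulate_stage(config: PipelineConfig, outdir: Path) -> SyntheticDataset:
    loci = shift_study_loci(
        n_loci=config.n_loci,
        n_shift=config.n_shift,
        n_background=config.n_background,
    )
    if config.include_impa1:
        next_start = max(s.utr_start for s in loci) + 20_000
        loci.append(impa1_fixture(utr_start=next_start))
    sim_cfg = SimConfig(
        seed=config.seed,
        read_length=config.read_length,
        end_jitter_sd=config.end_jitter_sd,
        nb_dispersion=config.nb_dispersion,
        replicates=config.replicates,
        background_rate=config.background_rate,
    )
    ds = simulate_dataset(loci, sim_cfg, outdir=outdir)
    # cleavage clones: 5' ends of cleaved fragments scatter just downstream
    # of the proximal end of the last locus
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xC10E,)))
    site = loci[-1].end_coords()[0] + 1
    positions = site + np.abs(np.rint(rng.normal(0, 40, size=12))).astype(int)
    pd.DataFrame(
        {"clone_id": [f"clone{i:02d}" for i in range(len(positions))], "position": positions}
    ).to_csv(outdir / "clones.tsv", sep="\t", index=False)
    with open(outdir / "clone_site.txt", "w") as fh:
        fh.write(str(site) + "\n")
    return ds


def annotate_stage(
    ds: SyntheticDataset, config: PipelineConfig, outdir: Path
) -> list[UtrIsoform]:
    pooled = {comp: ds.pooled_track(comp) for comp in COMPARTMENTS}
    isoforms, log = end_annotation.annotate_ends(
        pooled,
        ds.transcripts,
        window=config.window,
        min_depth=config.min_depth,
        min_positions=config.min_positions,
        max_gap=config.max_gap,
        max_assign_dist=config.max_assign_dist,
        smooth_width=config.smooth_width,
        k_max=config.k_max,
        penalty_alpha=config.penalty_alpha,
        cluster_dist=config.cluster_dist,
        min_drop_fold=config.min_drop_fold,
    )
    write_ends_bed(isoforms, outdir / "ends.bed")
    with open(outdir / "annotate_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=int)
    return isoforms


def sample_tracks(ds: SyntheticDataset) -> dict[str, CoverageTrack]:
    return {f"{comp}_rep{rep}": t for (comp, rep), t in ds.tracks.items()}


def quantify_stage(
    isoforms: list[UtrIsoform], ds: SyntheticDataset, config: PipelineConfig, outdir: Path
):
    tracks = sample_tracks(ds)
    counts = isoform_quant.quantify_isoforms(
        isoforms,
        tracks,
        window=config.terminal_window,
        read_length=config.read_length,
        pseudocount=config.density_pseudocount,
    )
    samples_by_comp = {
        comp: [s for s in tracks if s.startswith(comp)] for comp in COMPARTMENTS
    }
    calls, models = isoform_quant.call_expression_table(
        counts, samples_by_comp, strict=config.strict_calls
    )
    rows = []
    for rec in counts:
        row = {
            "transcript_id": rec.transcript_id,
            "end": rec.end,
            "utr_length": rec.utr_length,
            "strand": rec.strand,
        }
        for s, v in rec.counts.items():
            row[f"count_{s}"] = v
        for s, v in rec.log_density.items():
            row[f"logdens_{s}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "end": c.end,
                "compartment": c.compartment,
                "p_background": ",".join(f"{p:.6g}" for p in c.p_background),
                "called": c.called,
            }
            for c in calls
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    return counts, calls, samples_by_comp


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all six stages on a freshly simulated dataset.

    Deterministic for a fixed config (all randomness flows from
    ``config.seed``); writes versioned TSV outputs and a manifest recording
    the config hash and per-stage row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config), "config": config.to_dict(), "stages": {}}

    logger.info("stage simulate")
    ds = simulate_stage(config, outdir)
    manifest["stages"]["simulate"] = {
        "n_loci": len(ds.loci),
        "n_samples": len(ds.tracks),
        "truth_rows": len(ds.truth),
    }

    logger.info("stage annotate")
    isoforms = annotate_stage(ds, config, outdir)
    manifest["stages"]["annotate"] = {"n_isoforms": len(isoforms)}

    logger.info("stage quantify")
    counts, calls, samples_by_comp = quantify_stage(isoforms, ds, config, outdir)
    manifest["stages"]["quantify"] = {
        "n_isoforms": len(counts),
        "n_calls": len(calls),
        "n_called": sum(c.called for c in calls),
    }

    logger.info("stage diffapa")
    pairs, skipped = differential_apa.build_tandem_pairs(counts, calls, samples_by_comp)
    results = differential_apa.score_tandem_pairs(
        pairs,
        pseudocount=config.score_pseudocount,
        s1_threshold=config.s1_threshold,
        s2_threshold=config.s2_threshold,
        fdr_threshold=config.fdr_threshold,
        stringent_low=config.stringent_low,
        stringent_high=config.stringent_high,
    )
    differential_apa.results_frame(results).to_csv(outdir / "diffapa.tsv", sep="\t", index=False)
    manifest["stages"]["diffapa"] = {
        "n_pairs": len(pairs),
        "n_skipped": len(skipped),
        "n_shifted": sum(r.shift != "none" for r in results),
    }

    logger.info("stage pas")
    genome = {ds.loci[0].chrom: ds.sequence}
    hits = []
    for iso in isoforms:
        hits.extend(
            pas_analysis.scan_pas_motifs(
                genome, iso, config.pas_upstream, config.pas_downstream
            )
        )
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(outdir / "pas_hits.tsv", sep="\t", index=False)
    lengths = sorted(i.utr_length for i in isoforms)
    median_len = lengths[len(lengths) // 2] if lengths else 0
    short = [i for i in isoforms if i.utr_length <= median_len]
    long_ = [i for i in isoforms if i.utr_length > median_len]
    if short and long_:
        enr = pas_analysis.pas_enrichment(hits, short, hits, long_)
        enr.to_csv(outdir / "pas_enrichment.tsv", sep="\t", index=False)
    truth_ref = (
        ds.truth[["end_coord"]]
        .drop_duplicates()
        .rename(columns={"end_coord": "start"})
        .assign(chrom=ds.loci[0].chrom, strand="+")
    )
    novel = [i for i in isoforms if i.provenance == "novel"]
    if novel:
        curve = pas_analysis.reference_recovery_curve(novel, truth_ref)
        pd.DataFrame(
            {"threshold": curve.thresholds, "fraction_recovered": curve.fraction_recovered}
        ).to_csv(outdir / "pas_recovery.tsv", sep="\t", index=False)
    manifest["stages"]["pas"] = {"n_hits": len(hits), "n_novel": len(novel)}

    logger.info("stage clones")
    positions = cleavage_mapping.read_clone_positions(outdir / "clones.tsv")
    site = int(open(outdir / "clone_site.txt").read().strip())
    hist = cleavage_mapping.bin_clone_distances(positions, site, config.clone_bin)
    hist.to_frame().to_csv(outdir / "clone_histogram.tsv", sep="\t", index=False)
    manifest["stages"]["clones"] = {"n_clones": hist.n_clones, "n_bins": len(hist.bins)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir
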