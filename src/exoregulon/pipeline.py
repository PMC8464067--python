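"""End-to-end orchestration: simulate -> call peaks -> annotate -> type -> regulon.

One YAML-loadable configuration drives a fully seeded run; every stage
persists its intermediates (FASTA/GFF3/bedGraph/BED/TSV) and the final
report is a JSON document whose every number is recomputable from those
intermediates.  Reports are deterministic: provenance records the config
hash, seed and package version, and repeated runs with the same config and
seed produce byte-identical output.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotate, io, peaks, regulon, synth
from .cooccupancy import OccupancyPeakSet, classify_cooccupancy, summarize_cooccupancy

log = logging.getLogger("exoregulon")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "tf_name": "TF1",
    "simulate": {
        "genome_length": 1_000_000,
        "n_genes": 800,
        "n_sites": 50,
        "regulatory_fraction": 0.6,
        "motif": "TTCNNNNNNGAA",
        "n_replicates": 2,
        "reads_per_site": 200.0,
        "background_rate": 0.01,
        "border_offset": 20,
        "border_jitter_sd": 3.0,
        "occupancy_fractions": {"rnap_rpod": 0.5, "rnap_only": 0.25, "none": 0.25},
        "n_direct": 20,
        "repressed_fraction": 0.8,
        "baseline_mean": 500.0,
        "dispersion": 0.05,
        "rnaseq_replicates": 3,
        "planted_lfc": 2.0,
    },
    "peaks": {
        "snr_min": 1.5,
        "snr_mode": "floor",  # "floor" (top-5% noise level) or "mock" (IP/Mock)
        "top_fraction": 0.05,
        "d_min": 5,
        "d_max": 100,
        "smoothing_window": 5,
        "pad": 0,
        "pseudocount": 1.0,
        "match_tolerance": 20,
        "target_depth": 1_000_000.0,
    },
    "annotate": {"upstream_max": 300},
    "cooccupancy": {"upstream": 300, "downstream": 50, "mode": "promoter"},
    "de": {"lfc_min": 1.0, "alpha": 0.05, "pseudocount": 0.5},
    "enrichment": {"alpha": 0.01},
}


def make_config(overrides: dict | None = None) -> dict:
    """Deep-merge overrides into the default configuration; unknown keys fail."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _merge(cfg, overrides, path="")
    _validate(cfg)
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return make_config(yaml.safe_load(fh) or {})


def _merge(base: dict, overrides: dict, path: str) -> None:
    for k, v in overrides.items():
        if k not in base:
            raise ValueError(f"unknown config key {path + k!r}")
        if isinstance(base[k], dict) and k != "occupancy_fractions":
            if not isinstance(v, dict):
                raise ValueError(f"config section {path + k!r} must be a mapping")
            _merge(base[k], v, path + k + ".")
        else:
            base[k] = v


def _validate(cfg: dict) -> None:
    pk = cfg["peaks"]
    for key in ("snr_min", "top_fraction", "d_min", "d_max", "target_depth"):
        if pk[key] <= 0:
            raise ValueError(f"peaks.{key} must be positive")
    if not 0 < pk["top_fraction"] <= 1:
        raise ValueError("peaks.top_fraction must be in (0, 1]")
    if pk["snr_mode"] not in ("floor", "mock"):
        raise ValueError("peaks.snr_mode must be 'floor' or 'mock'")
    sim = cfg["simulate"]
    if not 0 <= sim["regulatory_fraction"] <= 1:
        raise ValueError("simulate.regulatory_fraction must be in [0, 1]")
    if cfg["de"]["alpha"] <= 0 or cfg["enrichment"]["alpha"] <= 0:
        raise ValueError("alpha thresholds must be positive")


def _simulate(cfg: dict) -> synth.SimulatedDataset:
    sim = cfg["simulate"]
    return synth.simulate_dataset(
        genome_spec=synth.GenomeSpec(length=sim["genome_length"], n_genes=sim["n_genes"]),
        read_model=synth.ReadModel(
            border_offset=sim["border_offset"],
            border_jitter_sd=sim["border_jitter_sd"],
            reads_per_site=sim["reads_per_site"],
            background_rate=sim["background_rate"],
        ),
        expression_model=synth.ExpressionModel(
            baseline_mean=sim["baseline_mean"],
            dispersion=sim["dispersion"],
            n_replicates=sim["rnaseq_replicates"],
            planted_lfc=sim["planted_lfc"],
        ),
        n_sites=sim["n_sites"],
        regulatory_fraction=sim["regulatory_fraction"],
        motif=sim["motif"],
        n_replicates=sim["n_replicates"],
        occupancy_fractions=sim["occupancy_fractions"],
        n_direct=sim["n_direct"],
        repressed_fraction=sim["repressed_fraction"],
        upstream_max=cfg["annotate"]["upstream_max"],
        promoter_downstream=cfg["cooccupancy"]["downstream"],
        seed=cfg["seed"],
    )


def call_peaks_from_tracks(
    tracks: dict[str, dict[str, peaks.StrandCoverage]], cfg_peaks: dict
) -> list[peaks.ExoPeak]:
    """Depth-normalize, call candidates per IP replicate, filter and combine."""
    ip_samples = sorted(s for s in tracks if s != "mock")
    flat = [tracks[s][st] for s in tracks for st in ("+", "-")]
    normed = peaks.normalize_depth(flat, cfg_peaks["target_depth"])
    by_sample: dict[str, dict[str, peaks.StrandCoverage]] = {}
    for t in normed:
        by_sample.setdefault(t.sample_id, {})[t.strand] = t

    candidates = {}
    for s in ip_samples:
        fwd, rev = by_sample[s]["+"], by_sample[s]["-"]
        if cfg_peaks["snr_mode"] == "mock" and "mock" in by_sample:
            reference = [by_sample["mock"]["+"], by_sample["mock"]["-"]]
        else:
            pooled = fwd.values + rev.values
            reference = peaks.noise_floor(pooled, cfg_peaks["top_fraction"])
        cands = peaks.call_candidates(
            fwd, rev,
            reference=reference,
            smoothing_window=cfg_peaks["smoothing_window"],
            d_min=cfg_peaks["d_min"],
            d_max=cfg_peaks["d_max"],
            pad=cfg_peaks["pad"],
            pseudocount=cfg_peaks["pseudocount"],
        )
        log.info("sample %s: %d candidate peaks", s, len(cands))
        candidates[s] = cands
    final = peaks.filter_and_combine(
        candidates, snr_min=cfg_peaks["snr_min"], match_tolerance=cfg_peaks["match_tolerance"]
    )
    log.info("%d peaks pass S/N and replicate filters", len(final))
    return final


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic-study pipeline and return the report.

    When `outdir` is given, every intermediate (genome, annotation, tracks,
    peak calls, assignments, co-occupancy calls, DE table, regulon summary,
    COG enrichment) is persisted there along with report.json.
    """
    cfg = make_config(config if config is not None else {})
    chash = io.config_hash(cfg)
    data = _simulate(cfg)
    final_peaks = call_peaks_from_tracks(data.tracks, cfg["peaks"])

    assignments = [
        annotate.assign_target(p, data.genes, cfg["annotate"]["upstream_max"])
        for p in final_peaks
    ]
    loc_summary = annotate.summarize_locations(assignments)

    rnap = OccupancyPeakSet("RNAP", data.rnap)
    rpod = OccupancyPeakSet("RpoD", data.rpod)
    co_calls = [
        classify_cooccupancy(
            a, rnap, rpod, data.genes,
            upstream=cfg["cooccupancy"]["upstream"],
            downstream=cfg["cooccupancy"]["downstream"],
            genome_length=len(data.genome),
            mode=cfg["cooccupancy"]["mode"],
        )
        for a in assignments
    ]
    co_summary = summarize_cooccupancy(co_calls)

    groups = ["WT"] * cfg["simulate"]["rnaseq_replicates"] + ["KO"] * cfg["simulate"]["rnaseq_replicates"]
    de = regulon.call_de(
        regulon.simple_de_test(data.counts, groups, cfg["de"]["pseudocount"]),
        lfc_min=cfg["de"]["lfc_min"],
        alpha=cfg["de"]["alpha"],
    )
    bound = sorted({g for a in assignments for g in a.target_genes})
    direct = regulon.direct_regulon(bound, de)
    summary = regulon.regulon_summary(cfg["tf_name"], assignments, co_calls, direct)
    cog = regulon.cog_enrichment(bound, data.genes, cfg["enrichment"]["alpha"]) if bound else pd.DataFrame()

    report = {
        "provenance": {"config_hash": chash, "seed": cfg["seed"], "version": __version__},
        "locations": loc_summary,
        "cooccupancy": co_summary,
        "regulon": summary,
        "n_de_genes": int(de["is_de"].sum()),
        "n_significant_cogs": int(cog["significant"].sum()) if len(cog) else 0,
    }

    if outdir is not None:
        _persist(Path(outdir), cfg, data, final_peaks, assignments, co_calls, de, direct, cog, report)
    return report


def _persist(outdir, cfg, data, final_peaks, assignments, co_calls, de, direct, cog, report):
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(outdir / "genome.fa", data.genome)
    io.write_gff3(outdir / "genes.gff3", data.genes)
    for sample, pair in data.tracks.items():
        for strand, suffix in (("+", "fwd"), ("-", "rev")):
            io.write_bedgraph(outdir / f"{sample}.{suffix}.bedGraph", pair[strand].values)
    io.write_tsv(outdir / "sites_truth.tsv", data.sites)
    io.write_tsv(outdir / "occupancy_truth.tsv", data.occupancy_truth)
    io.write_bed(outdir / "rnap.bed", data.rnap, names=[f"RNAP{i}" for i in range(len(data.rnap))])
    io.write_bed(outdir / "rpod.bed", data.rpod, names=[f"RpoD{i}" for i in range(len(data.rpod))])
    data.counts.to_csv(outdir / "counts.tsv", sep="\t")

    pk = peaks.peaks_to_frame(final_peaks, tf=cfg["tf_name"])
    io.write_tsv(outdir / "peaks.tsv", pk)
    io.write_bed(
        outdir / "peaks.bed",
        list(zip(pk["fwd_border"], pk["rev_border"])),
        names=pk["name"],
        scores=[round(100 * s) for s in pk["snr"]],
    )
    io.write_tsv(
        outdir / "assignments.tsv",
        pd.DataFrame(
            {
                "center": [a.peak.center for a in assignments],
                "location_class": [a.location_class for a in assignments],
                "target_genes": [",".join(a.target_genes) for a in assignments],
                "secondary_targets": [",".join(a.secondary_targets) for a in assignments],
                "distance_to_start": [a.distance_to_start for a in assignments],
                "cooccupancy": [c.type for c in co_calls],
            }
        ),
    )
    io.write_tsv(outdir / "de.tsv", de)
    io.write_tsv(outdir / "direct_targets.tsv", direct["direct_targets"])
    if len(cog):
        io.write_tsv(outdir / "cog_enrichment.tsv", cog)
    seq_records = annotate.extract_site_sequences(final_peaks, data.genome, flank=10, tf=cfg["tf_name"])
    annotate.write_motif_fasta(outdir / "motif_input.fa", seq_records)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
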