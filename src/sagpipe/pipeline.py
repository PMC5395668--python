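"""End-to-end orchestration of the pipeline stages with a single seeded config.

``run_pipeline`` executes the stages in dependency order on synthetic
data — pangenome simulation, core-gene combinatorics and power-law fit,
reference layouts and rolling-window recovery, SAG completeness and
genome-size estimation, dereplication with majority-rules family
assignment, and reciprocal best-hit read recruitment — writing every
stage's output as TSV/JSON under a run directory together with a
provenance manifest (package version, seeds, parameters, input
checksums).  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import sagpipe
from sagpipe import (
    PangenomeSpec,
    generate_pangenome,
    generate_sag,
    generate_paralog_families,
    generate_readset,
    mutate_sequence,
    OrthologMatrix,
    core_curve,
    fit_power_law,
    marker_catalog,
    build_layout,
    simulate_recovery,
    estimate_completeness,
    estimate_genome_size,
    dereplicate,
    majority_rules_assign,
    align_reads,
    rbb_recruit,
    recruitment_summary,
    identity_depth_table,
)
from sagpipe.completeness import layout_to_dict
from sagpipe.paralogs import lineage_table

logger = logging.getLogger("sagpipe")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; unknown keys are rejected up front."""

    seed: int = 0
    # pangenome simulation
    n_genomes: int = 25
    core_size: int = 71
    accessory_pool: int = 500
    accessory_retention: float = 0.30
    duplication_rate: float = 0.0
    genome_length: int = 3_000_000
    gene_length: int = 900
    # core-gene combinatorics
    max_combinations: int = 10_000
    fit_curve: bool = True
    # rolling-window recovery
    fraction_step: float = 0.01
    n_starts: int = 1000
    # synthetic SAGs to estimate
    sag_fractions: tuple = (0.2, 0.4, 0.6)
    sag_windows: int = 1
    # dereplication / family assignment
    derep_threshold: float = 0.8
    n_families: int = 6
    family_size: int = 4
    family_identity: float = 0.95
    family_length: int = 200
    # read recruitment
    read_length: int = 100
    reads_per_depth: int = 150
    depths: tuple = (500.0, 1000.0, 4000.0)
    depth_mutation_rates: tuple = (0.05, 0.03, 0.02)
    decoy_divergence: float = 0.15
    # stage toggles
    run_core: bool = True
    run_completeness: bool = True
    run_derep: bool = True
    run_recruit: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        d = dict(d)
        for key in ("sag_fractions", "depths", "depth_mutation_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every enabled stage; returns the provenance manifest (also written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sagpipe_version": sagpipe.__version__,
        "config": config.to_dict(),
        "outputs": [],
        "checksums": {},
    }

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"].append(name)
        return path

    logger.info("stage simulate: pangenome of %d genomes", config.n_genomes)
    try:
        spec = PangenomeSpec(
            n_genomes=config.n_genomes,
            core_size=config.core_size,
            accessory_pool=config.accessory_pool,
            accessory_retention=config.accessory_retention,
            duplication_rate=config.duplication_rate,
            genome_length=config.genome_length,
            gene_length=config.gene_length,
            seed=config.seed,
        )
        pan = generate_pangenome(spec, with_sequences=False)
    except Exception:
        logger.exception("stage simulate failed")
        raise
    emit(pan.gene_table, "gene_table.tsv")
    emit(pan.assignments, "cluster_assignments.tsv")

    matrix = OrthologMatrix.from_assignments(pan.gene_table, pan.assignments)

    if config.run_core:
        logger.info("stage core-genes: combinatorial core analysis")
        curve = core_curve(matrix, max_combinations=config.max_combinations, seed=config.seed)
        emit(curve.to_frame(), "core_curve.tsv")
        core_json: dict = {
            "exhaustive_core": int(curve.points[-1].mean) if curve.points else None,
        }
        if config.fit_curve and len(curve.points) >= 4:
            fit = fit_power_law(curve.ks, curve.means)
            core_json["power_law"] = {"a": fit.a, "b": fit.b, "c": fit.c, "rss": fit.rss}
        with open(outdir / "core_fit.json", "w") as fh:
            json.dump(core_json, fh, indent=2)
        manifest["outputs"].append("core_fit.json")

    catalog = marker_catalog(matrix, pan.gene_table, pan.assignments)

    if config.run_completeness:
        logger.info("stage recovery: rolling-window simulation over %d layouts", config.n_genomes)
        grid = np.round(
            np.arange(config.fraction_step, 1.0 + config.fraction_step / 2, config.fraction_step),
            10,
        )
        layouts = []
        contig_lengths = pan.gene_table.groupby("contig_id")["end"].max()
        for genome_id in matrix.genomes:
            markers = catalog.markers_for(genome_id)
            from sagpipe.completeness import GenomeLayout

            layouts.append(
                GenomeLayout(
                    genome_id=genome_id,
                    length=config.genome_length,
                    markers={c: (s, e) for c, (_ctg, s, e, _st) in markers.items()},
                )
            )
        with open(outdir / "layouts.json", "w") as fh:
            json.dump([layout_to_dict(la) for la in layouts], fh)
        manifest["outputs"].append("layouts.json")
        dist = simulate_recovery(layouts, fraction_grid=grid, n_starts=config.n_starts)
        emit(dist.summary(), "recovery_distribution.tsv")

        logger.info("stage estimate: %d synthetic SAGs", len(config.sag_fractions))
        rows = []
        ref_layout = layouts[0]
        for i, f in enumerate(config.sag_fractions):
            sag = generate_sag(
                genome_length=ref_layout.length,
                markers=ref_layout.markers,
                true_fraction=float(f),
                n_windows=config.sag_windows,
                seed=config.seed + 1000 + i,
                source_genome=ref_layout.genome_id,
            )
            est_f, quartiles = estimate_completeness(sag.marker_count, dist)
            est = estimate_genome_size(
                sag.recovered_length, est_f, quartiles, sag_id=f"sag{i}", k=sag.marker_count
            )
            rows.append(
                (
                    est.sag_id,
                    sag.true_fraction,
                    est.k,
                    round(est.fraction, 4),
                    round(est.size, 1),
                    round(est.uncertainty, 1),
                )
            )
        emit(
            pd.DataFrame(
                rows,
                columns=["sag_id", "true_fraction", "n_markers", "fraction_complete", "genome_size", "size_pm"],
            ),
            "size_estimates.tsv",
        )

    if config.run_derep:
        logger.info("stage derep-assign: %d synthetic families", config.n_families)
        fams = generate_paralog_families(
            config.n_families,
            config.family_size,
            config.family_identity,
            length=config.family_length,
            seed=config.seed + 2000,
        )
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        truth = dict(zip(fams["seq_id"], fams["family_id"]))
        clusters = dereplicate(seqs, config.derep_threshold)
        for cluster in clusters:
            majority_rules_assign(cluster, truth)
        emit(lineage_table(clusters), "lineages.tsv")

    if config.run_recruit:
        logger.info("stage recruit: reciprocal best-hit recruitment")
        rng = np.random.default_rng(config.seed + 3000)
        focal_len = max(20 * config.read_length, 5000)
        focal_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=focal_len))
        decoy_seq, _ = mutate_sequence(focal_seq, config.decoy_divergence, rng)
        genomes = {"focal": focal_seq, "decoy": decoy_seq}
        rates = dict(zip(config.depths, config.depth_mutation_rates))
        reads, truth = generate_readset(
            genomes,
            depths=list(config.depths),
            reads_per_depth=config.reads_per_depth,
            read_length=config.read_length,
            mutation_rate=rates,
            seed=config.seed + 3001,
        )
        stage1 = align_reads(reads, [("focal", focal_seq)], min_identity=0.6)
        candidates = stage1.queries()
        stage2 = align_reads(
            [r for r in reads if r[0] in candidates],
            [("focal", focal_seq), ("decoy", decoy_seq)],
            min_identity=0.3,
        )
        result = rbb_recruit(stage1, stage2, focal_ids={"focal"})
        profile = recruitment_summary(result, truth[["read_id", "sample", "depth"]], focal_genome="focal")
        emit(profile.per_depth, "recruitment_profile.tsv")
        tidy, means = identity_depth_table(profile)
        emit(tidy, "identity_depth.tsv")
        emit(means, "identity_depth_means.tsv")

    for name in list(manifest["outputs"]):
        manifest["checksums"][name] = _sha256(outdir / name)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d outputs in %s", len(manifest["outputs"]), outdir)
    return manifest
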