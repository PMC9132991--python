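"""Configuration, stage wiring, and reproducible end-to-end runs.

A single YAML config with per-stage blocks drives the pipeline
simulate -> preprocess -> distances -> genomics -> sequence -> associate,
with the bulk exposure branch alongside.  Every random stage takes an
explicit seed; a run manifest records the config hash and per-output
checksums so deterministic stages can be verified to reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, distance, exposure, genomics, io, preprocess, sequence, simulate


class ConfigError(ValueError):
    pass


@dataclass
class StageConfig:
    def update(self, overrides: dict) -> None:
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown config keys for {type(self).__name__}: {sorted(unknown)}")
        for k, v in overrides.items():
            setattr(self, k, v)


@dataclass
class SimulateConfig(StageConfig):
    n_receptors: int = 150
    alignment_length: int = 300
    cis_duplication_prob: float = 0.85
    sequence_coupling: float = 0.5
    program_scale: float = 0.5
    n_genes: int = 500
    cells_per_population_mean: float = 8.4
    cells_per_population_dispersion: float = 1.2
    doublet_rate: float = 0.0
    seed: int = 0


@dataclass
class PreprocessConfig(StageConfig):
    scale_factor: float = 1e4
    n_mads: float = 3.0
    scaled_mad: bool = True
    n_components: int = 50
    exclude_receptor_genes: bool = True
    min_cells: int = 3


@dataclass
class DistanceConfig(StageConfig):
    n_pcs: int | None = None  # None -> kneedle-selected
    n_perm: int = 1000
    min_cells_centroid: int = 10
    pool_mode: str = "histogram"
    seed: int = 0


@dataclass
class AssociateConfig(StageConfig):
    n_bins: int = 10
    n_first_bins: int = 3
    mode: str = "equal_width"


@dataclass
class ExposureConfig(StageConfig):
    n_genes: int = 2000
    fc_magnitude: float = 2.0
    frac_txn_up: float = 0.05
    frac_txn_down: float = 0.05
    frac_post: float = 0.05
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    q_cut: float = 0.1
    seed: int = 0


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    distances: DistanceConfig = field(default_factory=DistanceConfig)
    associate: AssociateConfig = field(default_factory=AssociateConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load, default and validate a YAML config; unknown keys are rejected."""
    cfg = PipelineConfig()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for stage, block in overrides.items():
            data.setdefault(stage, {}).update(block)
    known_stages = {f.name for f in dataclasses.fields(cfg)}
    unknown = set(data) - known_stages
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for stage, block in data.items():
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"config section {stage!r} must be a mapping")
        getattr(cfg, stage).update(block)
    # range checks
    if cfg.distances.n_perm < 0:
        raise ConfigError("distances.n_perm must be >= 0")
    if cfg.preprocess.min_cells < 1:
        raise ConfigError("preprocess.min_cells must be >= 1")
    if cfg.associate.n_bins < 2:
        raise ConfigError("associate.n_bins must be >= 2")
    return cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path, stages: list[str] | None = None) -> dict:
    """Execute the synthetic end-to-end pipeline; returns the run manifest."""
    all_stages = ["simulate", "preprocess", "distances", "genomics", "sequence", "associate", "exposure"]
    stages = stages or all_stages
    order = [s for s in all_stages if s in stages]
    deps = {
        "preprocess": ["simulate"],
        "distances": ["preprocess"],
        "genomics": ["simulate"],
        "sequence": ["simulate"],
        "associate": ["distances", "genomics", "sequence"],
    }
    done: set[str] = set()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    state: dict = {}

    for stage in order:
        for dep in deps.get(stage, []):
            if dep not in done:
                raise ConfigError(f"stage {stage!r} requires {dep!r} to run first")
        t0 = time.time()
        outputs = _run_stage(stage, config, out, state)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _checksum(p) for p in outputs},
        }
        done.add(stage)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stage(stage: str, cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    if stage == "simulate":
        fam_spec = simulate.ORFamilySpec(
            n_receptors=cfg.simulate.n_receptors,
            alignment_length=cfg.simulate.alignment_length,
            cis_duplication_prob=cfg.simulate.cis_duplication_prob,
            seed=cfg.simulate.seed,
        )
        family = simulate.simulate_or_family(fam_spec)
        sc_spec = simulate.OSNSimSpec(
            n_genes=cfg.simulate.n_genes,
            program_scale=cfg.simulate.program_scale,
            sequence_coupling=cfg.simulate.sequence_coupling,
            cells_per_population_mean=cfg.simulate.cells_per_population_mean,
            cells_per_population_dispersion=cfg.simulate.cells_per_population_dispersion,
            doublet_rate=cfg.simulate.doublet_rate,
            seed=cfg.simulate.seed + 1,
        )
        dataset = simulate.simulate_osn_counts(family, sc_spec)
        io.write_or_family(family, out / "family")
        io.write_10x(dataset, out / "sc_counts")
        io.write_sc_truth(dataset, out / "sc_counts")
        state["family"], state["dataset"] = family, dataset
        return sorted((out / "family").iterdir()) + sorted((out / "sc_counts").iterdir())

    if stage == "preprocess":
        dataset = state["dataset"]
        cm = dataset.to_count_matrix()
        normed = preprocess.log_normalize(cm, scale_factor=cfg.preprocess.scale_factor)
        assign = preprocess.assign_populations(normed)
        assign = preprocess.mad_multiplet_filter(
            assign, n_mads=cfg.preprocess.n_mads, scaled_mad=cfg.preprocess.scaled_mad
        )
        assign = preprocess.filter_populations_min_cells(assign, cfg.preprocess.min_cells)
        emb = preprocess.pca_embed(
            normed,
            n_components=min(cfg.preprocess.n_components, len(cm.cell_ids) - 1),
            exclude_receptor_genes=cfg.preprocess.exclude_receptor_genes,
        )
        assign.to_frame().to_csv(out / "assignment.tsv", sep="\t", index=False)
        pd.DataFrame(emb.coordinates, index=cm.cell_ids).to_csv(out / "embedding.tsv", sep="\t")
        state["assignment"], state["embedding"] = assign, emb
        return [out / "assignment.tsv", out / "embedding.tsv"]

    if stage == "distances":
        assign, emb = state["assignment"], state["embedding"]
        mask = assign.status == "assigned"
        labels = assign.receptor_id[mask]
        n_pcs = cfg.distances.n_pcs or emb.n_selected
        coords = emb.coordinates[mask]
        model = distance.PopulationDistance(coords, labels, n_pcs=n_pcs)
        res = model.fit(
            n_perm=cfg.distances.n_perm, seed=cfg.distances.seed, pool_mode=cfg.distances.pool_mode
        )
        res.summary().to_csv(out / "distance_summary.tsv", sep="\t", index=False)
        cents = distance.centroids(coords[:, :n_pcs], labels, min_cells=cfg.distances.min_cells_centroid)
        cmat = distance.centroid_distance_matrix(cents)
        cmat.to_csv(out / "centroid_distances.tsv", sep="\t")
        state["distance_results"], state["centroid_matrix"] = res, cmat
        return [out / "distance_summary.tsv", out / "centroid_distances.tsv"]

    if stage == "genomics":
        family = state["family"]
        anchors = family.annotations()
        model = genomics.fit_cluster_model(anchors)
        pairs = genomics.pairwise_genomic_distances(anchors, model.cluster_assignment)
        pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in anchors],
                "chromosome": [a.chromosome for a in anchors],
                "anchor": [a.anchor_position for a in anchors],
                "cluster_id": [model.cluster_assignment[a.gene_id] for a in anchors],
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        pairs.to_csv(out / "genomic_pairs.tsv", sep="\t", index=False)
        state["cluster_model"], state["genomic_pairs"] = model, pairs
        return [out / "clusters.tsv", out / "genomic_pairs.tsv"]

    if stage == "sequence":
        family = state["family"]
        aln = sequence.ORAlignment(
            list(family.receptor_ids),
            list(family.aligned_sequences),
            dict(zip(family.receptor_ids, family.class_label)),
        )
        aln = sequence.trim_alignment(aln)
        aa = sequence.pairwise_aa_matrix(aln)
        aa.to_csv(out / "aa_differences.tsv", sep="\t")
        state["aa_matrix"] = aa
        return [out / "aa_differences.tsv"]

    if stage == "associate":
        family = state["family"]
        model = state["cluster_model"]
        table = association.build_pair_table(
            state["centroid_matrix"],
            state["genomic_pairs"],
            state["aa_matrix"],
            model.cluster_assignment,
            dict(zip(family.receptor_ids, family.class_label)),
            dict(zip(family.receptor_ids, family.chromosome)),
        )
        anchors = family.annotations()
        neighbor = genomics.adjacent_distances(
            [a for a in anchors if a.gene_id in set(table.pop_a) | set(table.pop_b)]
        )
        thresholds = association.close_thresholds(
            neighbor, table.loc[table.same_class, "aa_difference"].to_numpy()
        )
        classified = association.classify_pairs(table, thresholds)
        tests = association.category_tests(classified)
        classified.to_csv(out / "pair_table.tsv", sep="\t", index=False)
        tests.to_csv(out / "category_tests.tsv", sep="\t", index=False)
        return [out / "pair_table.tsv", out / "category_tests.tsv"]

    if stage == "exposure":
        spec = simulate.ExposureSimSpec(
            n_genes=cfg.exposure.n_genes,
            fc_magnitude=cfg.exposure.fc_magnitude,
            frac_txn_up=cfg.exposure.frac_txn_up,
            frac_txn_down=cfg.exposure.frac_txn_down,
            frac_post=cfg.exposure.frac_post,
            seed=cfg.exposure.seed,
        )
        dataset = simulate.simulate_exposure_counts(spec)
        io.write_exposure(dataset, out / "exposure")
        de = exposure.nb_wald_de(
            dataset.exon_counts,
            dataset.condition,
            lfc_threshold=cfg.exposure.lfc_threshold,
            alpha=cfg.exposure.alpha,
        )
        eisa = exposure.ExonIntronSplit(
            dataset.exon_counts, dataset.transcript_counts, dataset.condition
        ).fit(q_cut=cfg.exposure.q_cut)
        de.table.to_csv(out / "de_results.tsv", sep="\t")
        eisa.classification.rename("class").to_csv(out / "eisa_classes.tsv", sep="\t")
        return sorted((out / "exposure").iterdir()) + [out / "de_results.tsv", out / "eisa_classes.tsv"]

    raise ConfigError(f"unknown stage {stage!r}")
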