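"""Pipeline orchestration: configuration, validation, stage wiring,
manifest writing.

A run executes the stages in dependency order on synthetic (or supplied)
inputs: counts -> transcriptome -> enrichment; scenes -> morphometry;
cell tables -> fate mapping; feature table -> correlation surface.  A single
global seed fans out to per-stage seeds derived by hashing the stage name,
so each stage is reproducible independently of stage order.  The manifest
records the config snapshot, per-stage outputs with checksums, wall-clock
times, and the seed; re-running with the same config and seed reproduces
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlate as corr
from . import enrichment as enr
from . import fate_mapping as fate
from . import morphometry as morph
from . import synthetic as syn
from . import transcriptome as tx

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "stage_seed"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """All thresholds and toggles of a pipeline run (field defaults are the
    study values)."""

    out_dir: str = "miaglia_run"
    seed: int = 0
    # stage toggles
    run_transcriptome: bool = True
    run_enrichment: bool = True
    run_morphometry: bool = True
    run_fate_mapping: bool = True
    run_correlate: bool = True
    # transcriptome
    counts_path: str | None = None  # None -> synthetic
    meta_path: str | None = None
    min_cpm: float = 2.0
    min_samples: int = 3
    k: int = 5
    kmeans_restarts: int = 25
    elbow_k_range: tuple[int, int] = (2, 8)
    de_alpha: float = 0.05
    # enrichment
    n_perm_overlap: int = 10_000
    n_perm_connectedness: int = 100_000
    # morphometry
    voxel_size_um: tuple[float, float, float] = syn.DEFAULT_VOXEL_SIZE
    interaction_radii_um: tuple[float, float, float] = (0.3, 0.9, 1.5)
    interaction_z_planes: tuple[int, int, int] = (1, 3, 5)
    soma_distance_filter_um: float = 95.0
    coverage_bins: int = 36
    # fate mapping
    fate_n_cells: int = 1000
    fate_fractions: tuple[float, float, float] = (0.41, 0.198, 0.392)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("elbow_k_range", "voxel_size_um", "interaction_radii_um",
                    "interaction_z_planes", "fate_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Exhaustive list of config violations (empty when valid)."""
    problems: list[str] = []
    if config.min_cpm <= 0:
        problems.append("min_cpm must be positive")
    if config.min_samples <= 0:
        problems.append("min_samples must be positive")
    if config.k < 2:
        problems.append("k must be >= 2")
    if any(v <= 0 for v in config.voxel_size_um):
        problems.append("voxel sizes must be strictly positive")
    radii = config.interaction_radii_um
    planes = config.interaction_z_planes
    if not (radii[0] < radii[1] < radii[2]):
        problems.append("interaction radii must nest (encapsulation < apposition < proximity)")
    z_step = config.voxel_size_um[2]
    for name, r, p in zip(("encapsulation", "apposition", "proximity"), radii, planes):
        if abs(r - p * z_step) > 1e-9:
            problems.append(
                f"{name} radius {r} um inconsistent with {p} z-planes x {z_step} um step"
            )
    f = config.fate_fractions
    if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
        problems.append("fate_fractions must be a point in the 3-simplex")
    if config.n_perm_overlap < 1 or config.n_perm_connectedness < 1:
        problems.append("permutation counts must be >= 1")
    if config.soma_distance_filter_um < 0:
        problems.append("soma distance filter must be non-negative")
    if config.elbow_k_range[0] < 2 or config.elbow_k_range[1] - config.elbow_k_range[0] < 2:
        problems.append("elbow k range must start at >= 2 and span >= 3 values")
    return problems


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    config: dict
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, outputs: dict[str, Path], seconds: float) -> None:
        self.stages[name] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "checksums": {k: _sha256(p) for k, p in outputs.items()},
            "seconds": round(seconds, 3),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed mixed with a stable hash of the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all enabled stages and write outputs plus a manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.to_dict(), VERSION, config.seed)

    modules_assignment = None
    truth = None
    counts = None

    if config.run_transcriptome:
        t0 = time.perf_counter()
        outputs = {}
        if config.counts_path:
            if not Path(config.counts_path).exists():
                raise FileNotFoundError(f"transcriptome stage: missing input {config.counts_path}")
            counts = tx.read_counts_tsv(config.counts_path, config.meta_path)
        else:
            synth = syn.generate_counts(seed=stage_seed(config.seed, "counts"))
            counts = synth.counts
            truth = synth.true_modules
            counts.counts.to_csv(out / "counts.tsv", sep="\t")
            counts.meta.to_csv(out / "metadata.csv")
            synth.truth_table().to_csv(out / "true_modules.tsv", sep="\t")
            outputs |= {
                "counts": out / "counts.tsv",
                "metadata": out / "metadata.csv",
                "true_modules": out / "true_modules.tsv",
            }
        filtered, n_kept = tx.filter_expressed(counts, config.min_cpm, config.min_samples)
        z = tx.zscore_rows(tx.log2_cpm(filtered))
        modules_assignment = tx.kmeans_modules(
            z, config.k, seed=stage_seed(config.seed, "kmeans"),
            n_restarts=config.kmeans_restarts,
        )
        assert modules_assignment.module_sizes.sum() == n_kept  # partition identity
        wcss = tx.wcss_by_k(
            z, range(config.elbow_k_range[0], config.elbow_k_range[1] + 1),
            seed=stage_seed(config.seed, "kmeans"), n_restarts=config.kmeans_restarts,
        )
        pur = tx.purity(tx.cpm(filtered))
        groups = counts.meta["group"]
        p60_saline = counts.samples[groups == "P60_Saline_CTRL"]
        p60_mia = counts.samples[groups == "P60_MIA_CTRL"]
        de = None
        if len(p60_saline) >= 2 and len(p60_mia) >= 2:
            de = tx.nb_exact_test(filtered, p60_mia, p60_saline, alpha=config.de_alpha)

        modules_assignment.labels.to_csv(out / "modules.tsv", sep="\t")
        pd.Series(wcss, name="wcss").rename_axis("k").to_csv(out / "wcss_by_k.csv")
        pur.fractions.to_csv(out / "purity.csv")
        outputs |= {"modules": out / "modules.tsv", "wcss": out / "wcss_by_k.csv",
                    "purity": out / "purity.csv"}
        if de is not None:
            de.table.to_csv(out / "de_p60_mia_vs_saline.tsv", sep="\t")
            outputs["de"] = out / "de_p60_mia_vs_saline.tsv"
        manifest.add_stage("transcriptome", outputs, time.perf_counter() - t0)

    if config.run_enrichment and modules_assignment is not None:
        t0 = time.perf_counter()
        rng = np.random.default_rng(stage_seed(config.seed, "enrichment"))
        module_sets = [
            enr.GeneSet(m, modules_assignment.genes_in(m), "mouse")
            for m in modules_assignment.module_sizes.index
        ]
        # synthetic one-to-one ortholog map over the filtered universe
        universe = sorted(modules_assignment.labels.index)
        ortho = enr.OrthologMap(
            pd.DataFrame({"mouse": universe, "human": [g.upper() for g in universe]})
        )
        # one enriched human list (drawn from the largest module) + one random
        largest = module_sets[int(np.argmax([len(s) for s in module_sets]))]
        enriched_members = rng.choice(sorted(largest.members), size=min(50, len(largest)),
                                      replace=False)
        random_members = rng.choice(universe, size=50, replace=False)
        human_sets = [
            enr.GeneSet("planted_list", {g.upper() for g in enriched_members}, "human"),
            enr.GeneSet("random_list", {g.upper() for g in random_members}, "human"),
        ]
        bg, filtered_sets = enr.build_background(module_sets, human_sets, ortho)
        grid = enr.overlap_matrix(filtered_sets[: len(module_sets)],
                                  filtered_sets[len(module_sets):], bg)
        perm = enr.permutation_overlap_test(
            filtered_sets[module_sets.index(largest)], filtered_sets[len(module_sets)],
            bg, n_perm=config.n_perm_overlap,
            seed=stage_seed(config.seed, "perm_overlap"),
            n_tests=len(grid),
        )
        net, planted = syn.generate_network(
            200, 20, seed=stage_seed(config.seed, "network")
        )
        conn = enr.connectedness_permutation(
            planted, net, n_perm=config.n_perm_connectedness,
            seed=stage_seed(config.seed, "perm_conn"),
        )
        grid.to_csv(out / "overlap_grid.csv", index=False)
        with open(out / "permutations.json", "w") as fh:
            json.dump(
                {"overlap": dataclasses.asdict(perm), "connectedness": dataclasses.asdict(conn)},
                fh, indent=2,
            )
        net.to_edge_list().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        manifest.add_stage(
            "enrichment",
            {"overlap_grid": out / "overlap_grid.csv",
             "permutations": out / "permutations.json",
             "network": out / "network_edges.tsv"},
            time.perf_counter() - t0,
        )

    morph_summary = None
    if config.run_morphometry:
        t0 = time.perf_counter()
        scene_rng = np.random.default_rng(stage_seed(config.seed, "scene"))
        spine_specs = []
        for i in range(10):
            neck = float(scene_rng.uniform(0.0, 3.5))
            head = float(scene_rng.uniform(0.1, 0.9))
            offset = (float(scene_rng.uniform(0.1, 2.0)), 0.0,
                      float(scene_rng.choice([0.0, 0.3, 0.6])))
            spine_specs.append(
                syn.SpineSpec(position_um=5.0 + 9.0 * i, neck_um=neck, head_um=head,
                              offset_um=offset)
            )
        scene = syn.SceneSpec(
            dendrite_length_um=100.0, spines=tuple(spine_specs),
            voxel_size_um=config.voxel_size_um,
            seed=stage_seed(config.seed, "scene"),
        )
        spines, cloud = syn.generate_scene(scene)
        segment = morph.DendriteSegment(100.0, config.soma_distance_filter_um, spines)
        density = morph.spine_density(segment)
        interactions = morph.interaction_density(segment, cloud, n_bins=config.coverage_bins)
        morph_summary = {"spine_density": density, "interaction_density": interactions}
        pd.DataFrame(
            [dataclasses.asdict(r) for r in morph.score_interactions(spines, cloud)]
        ).to_csv(out / "interactions.csv", index=False)
        pd.DataFrame([density | {k: interactions[k] for k in interactions}]).T.rename(
            columns={0: "per_10um"}
        ).to_csv(out / "densities.csv")
        manifest.add_stage(
            "morphometry",
            {"interactions": out / "interactions.csv", "densities": out / "densities.csv"},
            time.perf_counter() - t0,
        )

    if config.run_fate_mapping:
        t0 = time.perf_counter()
        cells = syn.generate_fate_table(
            config.fate_n_cells, config.fate_fractions,
            seed=stage_seed(config.seed, "fate"),
        )
        summary = fate.group_summary(cells)
        cells.to_csv(out / "fate_cells.csv", index=False)
        summary.to_csv(out / "fate_demographics.csv", index=False)
        manifest.add_stage(
            "fate_mapping",
            {"cells": out / "fate_cells.csv", "demographics": out / "fate_demographics.csv"},
            time.perf_counter() - t0,
        )

    if config.run_correlate:
        t0 = time.perf_counter()
        rng = np.random.default_rng(stage_seed(config.seed, "correlate"))
        n_cells = 30
        latent = rng.normal(size=n_cells)
        features = pd.DataFrame(
            {
                "Rn": 100 + 20 * latent + rng.normal(0, 5, n_cells),
                "Dur_half": 1.2 + 0.1 * latent + rng.normal(0, 0.05, n_cells),
                "AP_rise": 0.5 + 0.05 * latent + rng.normal(0, 0.02, n_cells),
                "AP_fall": 0.8 + 0.08 * latent + rng.normal(0, 0.04, n_cells),
                "sEPSC_amp": 12 - 1.5 * latent + rng.normal(0, 1, n_cells),
                "MG_branches_9th": np.round(10 + 3 * latent + rng.normal(0, 1, n_cells)),
                "total_interaction_density": 0.5 + 0.1 * latent + rng.normal(0, 0.05, n_cells),
                "total_spine_density": 8 + rng.normal(0, 1, n_cells),
            },
            index=[f"cell{i + 1:02d}" for i in range(n_cells)],
        )
        surface = corr.spearman_matrix(features)
        paths = corr.export_surface(surface, out / "correlation")
        manifest.add_stage("correlate", paths, time.perf_counter() - t0)

    config.to_yaml(out / "config.yaml")
    manifest.write(out / "manifest.json")
    return manifest
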