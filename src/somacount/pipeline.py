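"""End-to-end orchestration: simulate -> preprocess -> segment -> quantify -> test.

The pipeline runs a fixed stage order per animal and side::

    read -> [stitch] -> downsample -> denoise -> threshold sweep ->
    select threshold -> assign regions -> volume gates -> L/R max-merge ->
    composite pooling -> major aggregation

followed by the statistics stage on the composite count table.  Every stage
logs input/output cardinalities into a run manifest; no detection is dropped
silently (gate-rejected and out-of-atlas detections are counted with reason
codes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import imaging, quantify, stats, synthetic
from .imaging import Volume3D
from .quantify import GateSpec, Labelmap, RegionTree

log = logging.getLogger("somacount")

DEFAULT_THRESHOLDS = [200.0, 300.0, 400.0, 500.0, 600.0]


@dataclass
class PipelineConfig:
    """Everything a quantification + statistics run needs.

    ``downsample_factor`` maps genotype -> in-plane factor (the acquisition
    campaigns this models used 2x2 for most genotypes and 3x3 for one);
    factors feed the voxel-count correction automatically.
    """

    workspace: Path
    labelmap_path: Path
    tree_path: Path
    animals_path: Path  # CSV: animal_id, genotype, downsample_factor
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    gates: GateSpec = field(default_factory=GateSpec)
    connectivity: int = 26
    qc_region_ids: list[int] = field(default_factory=list)
    reference_genotype: str = "WT"
    alpha: float = 0.01
    min_ref_count: int = 25
    denoise_method: str = "none"
    threshold_override: float | None = None
    separate_families: list[list[str]] = field(default_factory=list)
    composite_defs_path: Path | None = None
    voxel_size: tuple[float, float, float] = imaging.DEFAULT_VOXEL_SIZE_UM
    seed: int = 0

    def validate(self) -> None:
        for name in ("labelmap_path", "tree_path", "animals_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ws = Path(raw.get("workspace", Path(path).parent))
        gates_raw = raw.get("gates", {})
        gates = GateSpec(
            default_min=int(gates_raw.get("default_min", quantify.DEFAULT_MIN_VOXELS)),
            max_voxels=int(gates_raw.get("max_voxels", quantify.DEFAULT_MAX_VOXELS)),
            min_voxels={int(k): int(v) for k, v in gates_raw.get("min_voxels", {}).items()},
        )
        return cls(
            workspace=ws,
            labelmap_path=ws / raw["labelmap"],
            tree_path=ws / raw["tree"],
            animals_path=ws / raw["animals"],
            thresholds=[float(t) for t in raw.get("thresholds", DEFAULT_THRESHOLDS)],
            gates=gates,
            connectivity=int(raw.get("connectivity", 26)),
            qc_region_ids=[int(r) for r in raw.get("qc_region_ids", [])],
            reference_genotype=raw.get("reference_genotype", "WT"),
            alpha=float(raw.get("alpha", 0.01)),
            min_ref_count=int(raw.get("min_ref_count", 25)),
            denoise_method=raw.get("denoise", "none"),
            threshold_override=raw.get("threshold_override"),
            separate_families=[list(f) for f in raw.get("separate_families", [])],
            composite_defs_path=(ws / raw["composite_defs"]) if "composite_defs" in raw else None,
            voxel_size=tuple(raw.get("voxel_size_um", imaging.DEFAULT_VOXEL_SIZE_UM)),
            seed=int(raw.get("seed", 0)),
        )


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str = "0.1.0"
    stage_seconds: dict = field(default_factory=dict)
    cardinalities: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=1, default=str))


# ---------------------------------------------------------------------------
# Quantification stage
# ---------------------------------------------------------------------------

def _process_side(
    volume: Volume3D,
    config: PipelineConfig,
    labelmap: Labelmap,
    factor: int,
) -> tuple[dict[float, list], Volume3D]:
    """Downsample, denoise and sweep thresholds for one illumination side."""
    vol = imaging.downsample_xy(volume, factor)
    if config.denoise_method != "none":
        vol = imaging.denoise(vol, config.denoise_method)
    sweep = imaging.sweep_thresholds(vol, config.thresholds, config.connectivity)
    per_threshold: dict[float, list] = {}
    for t, dets in zip(sweep.thresholds, sweep.detections):
        dets = imaging.correct_and_convert(dets, factor, config.voxel_size)
        dets = quantify.assign_regions(dets, labelmap, keep_outside=True)
        per_threshold[t] = dets
    return per_threshold, vol


def run_quantification(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full quantification stage and persist all intermediates.

    Returns a dict with the count tables at each level, the gated detection
    frame, and the manifest.  Outputs under ``out_dir``: ``detections.csv``,
    ``counts_subregion.csv``, ``counts_composite.csv``, ``counts_major.csv``,
    ``thresholds.csv``, ``manifest.json``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    t0 = time.time()

    labelmap = Labelmap(np.asarray(tifffile.imread(config.labelmap_path)))
    tree = RegionTree.from_json(config.tree_path)
    animals = pd.read_csv(config.animals_path)
    composite_defs = None
    if config.composite_defs_path is not None:
        raw = json.loads(Path(config.composite_defs_path).read_text())
        composite_defs = {int(k): [int(s) for s in v] for k, v in raw.items()}
    manifest.stage_seconds["load"] = time.time() - t0

    all_region_ids = labelmap.region_ids()
    qc_ids = set(config.qc_region_ids or all_region_ids)
    side_tables = {"left": [], "right": []}
    gated_frames = []
    threshold_rows = []
    totals = {"detections_in": 0, "gate_rejected": 0, "out_of_atlas": 0, "gated": 0}

    t0 = time.time()
    for row in animals.itertuples():
        animal, genotype = str(row.animal_id), str(row.genotype)
        factor = int(getattr(row, "downsample_factor", 1))
        per_side: dict[str, dict[float, list]] = {}
        for side in ("left", "right"):
            path = config.workspace / f"{animal}_{side}.tif"
            if not path.exists():
                raise FileNotFoundError(f"missing volume for {animal} ({side}): {path}")
            vol = imaging.read_volume(path)
            per_side[side], _ = _process_side(vol, config, labelmap, factor)

        # one threshold per animal, from gated counts in the QC regions
        sweep_counts: dict[float, int] = {}
        for t in config.thresholds:
            n = 0
            for side in ("left", "right"):
                inside, _ = quantify.split_outside(per_side[side][t])
                gated = quantify.apply_gates(inside, config.gates)
                n += sum(1 for d in gated if d.region_id in qc_ids)
            sweep_counts[t] = n
        chosen = quantify.select_threshold(sweep_counts, override=config.threshold_override)
        threshold_rows.append(
            {"animal_id": animal, "genotype": genotype, "threshold": chosen,
             **{f"count_at_{t:g}": c for t, c in sweep_counts.items()}}
        )

        per_side_counts = {}
        for side in ("left", "right"):
            dets = per_side[side][chosen]
            inside, outside = quantify.split_outside(dets)
            gated = quantify.apply_gates(inside, config.gates)
            totals["detections_in"] += len(dets)
            totals["out_of_atlas"] += len(outside)
            totals["gate_rejected"] += len(inside) - len(gated)
            totals["gated"] += len(gated)
            gated_frames.append(imaging.detections_to_frame(gated))
            per_side_counts[side] = quantify.count_by_region(
                gated, animal, genotype, all_region_ids
            )
        side_tables["left"].append(per_side_counts["left"])
        side_tables["right"].append(per_side_counts["right"])
    manifest.stage_seconds["segment"] = time.time() - t0

    t0 = time.time()
    left = pd.concat(side_tables["left"], ignore_index=True)
    right = pd.concat(side_tables["right"], ignore_index=True)
    merged = quantify.merge_illumination(left, right)
    composite, audit = quantify.build_composites(
        merged, tree,
        min_ref_count=config.min_ref_count,
        reference_genotype=config.reference_genotype,
        composite_defs=composite_defs,
    )
    major = quantify.aggregate_major(composite, tree)
    manifest.stage_seconds["quantify"] = time.time() - t0

    manifest.cardinalities = {**totals, "composite_audit": audit}
    assert totals["detections_in"] == (
        totals["gated"] + totals["gate_rejected"] + totals["out_of_atlas"]
    ), "cardinality accounting failed"

    detections = (
        pd.concat(gated_frames, ignore_index=True)
        if gated_frames else pd.DataFrame(columns=imaging.DETECTION_COLUMNS)
    )
    detections.to_csv(out_dir / "detections.csv", index=False)
    merged.to_csv(out_dir / "counts_subregion.csv", index=False)
    composite.to_csv(out_dir / "counts_composite.csv", index=False)
    major.to_csv(out_dir / "counts_major.csv", index=False)
    pd.DataFrame(threshold_rows).to_csv(out_dir / "thresholds.csv", index=False)
    manifest.to_json(out_dir / "manifest.json")
    return {
        "subregion": merged, "composite": composite, "major": major,
        "detections": detections, "manifest": manifest, "tree": tree,
    }


# ---------------------------------------------------------------------------
# Statistics stage
# ---------------------------------------------------------------------------

def run_statistics(
    composite_counts: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path,
    tree: RegionTree | None = None,
    volume_table: pd.DataFrame | None = None,
) -> dict:
    """NB genotype contrasts, volcano table, Ward clustering, optional mixed model.

    Contrast families: by default every non-reference genotype is tested
    against the reference in one FDR family; ``config.separate_families``
    splits genotypes into separately-adjusted families (each listed family is
    fit and FDR-adjusted on its own, mirroring an acquisition-condition split
    such as a different optimal segmentation threshold).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotypes = sorted(composite_counts["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("statistics requires >= 2 genotypes")
    ref = config.reference_genotype
    non_ref = [g for g in genotypes if g != ref]
    families: list[list[str]] = []
    assigned = {g for fam in config.separate_families for g in fam}
    main = [g for g in non_ref if g not in assigned]
    if main:
        families.append(main)
    families.extend([list(f) for f in config.separate_families if f])

    major_of = None
    if tree is not None:
        major_of = {
            int(r): tree.major_of(int(r))
            for r in composite_counts["region_id"].unique()
            if int(r) in tree.nodes
        }

    all_tables = []
    exclusions = []
    for fam_idx, family in enumerate(families):
        sub = composite_counts[composite_counts["genotype"].isin([ref] + family)]
        fits = {}
        for region, grp in sub.groupby("region_id"):
            fits[int(region)] = stats.fit_nb_glm(
                grp["count"].tolist(), grp["genotype"].tolist(), reference=ref
            )
        table, excl = stats.rate_ratio_table(
            fits, alpha=config.alpha, major_of=major_of
        )
        table["family"] = fam_idx
        all_tables.append(table)
        exclusions.extend(excl)
    results = pd.concat(all_tables, ignore_index=True)
    volcano, meta = stats.volcano_table(results, alpha=config.alpha)

    mat = composite_counts.pivot_table(
        index="animal_id", columns="region_id", values="count", fill_value=0
    )
    cluster = stats.ward_two_way(mat.to_numpy(), transform="log1p")

    results.to_csv(out_dir / "rate_ratios.csv", index=False)
    volcano.to_csv(out_dir / "volcano.csv", index=False)
    (out_dir / "volcano_meta.json").write_text(json.dumps(meta, indent=1))
    (out_dir / "cluster.json").write_text(json.dumps({
        "row_linkage": cluster.row_linkage.tolist(),
        "col_linkage": cluster.col_linkage.tolist(),
        "row_order": cluster.row_order,
        "col_order": cluster.col_order,
        "row_labels": [str(a) for a in mat.index],
        "col_labels": [int(c) for c in mat.columns],
    }, indent=1))
    if exclusions:
        (out_dir / "exclusions.json").write_text(json.dumps(exclusions, indent=1))

    mixed = None
    if volume_table is not None:
        mixed = stats.fit_volume_mixed_model(volume_table)
        (out_dir / "mixed_model.json").write_text(json.dumps({
            "fixed_effects": mixed.fixed_effects.to_dict(),
            "random_intercept_var": mixed.random_intercept_var,
            "residual_var": mixed.residual_var,
            "interaction_lrt": mixed.interaction_lrt,
            "interaction_df": mixed.interaction_df,
            "interaction_p": mixed.interaction_p,
        }, indent=1))
    return {"rate_ratios": results, "volcano": volcano, "volcano_meta": meta,
            "cluster": cluster, "mixed_model": mixed, "exclusions": exclusions}


# ---------------------------------------------------------------------------
# Demo workspace
# ---------------------------------------------------------------------------

DEMO_REGIONS = {
    1: (4, 28, 4, 28, 4, 30),
    2: (4, 28, 4, 28, 34, 60),
    3: (36, 60, 4, 28, 4, 30),
    4: (36, 60, 4, 28, 34, 60),
    5: (4, 28, 36, 60, 4, 60),
}
DEMO_COUNTS = {1: 8, 2: 8, 3: 6, 4: 6, 5: 10}


def make_demo(seed: int = 0, workspace: str | Path = "demo_workspace") -> Path:
    """Build a small self-contained workspace the pipeline can run on.

    Writes a 64^3 five-region atlas, left/right illumination volumes for 2
    genotypes x 3 animals (with depth attenuation and mild Gaussian noise),
    the region-tree JSON, an animal metadata CSV, a pipeline YAML config, and
    ``expected_counts.csv`` holding the ground-truth per-region totals.
    """
    ws = Path(workspace)
    ws.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    atlas_spec = synthetic.SyntheticAtlasSpec(
        grid_shape=(64, 64, 64),
        regions=DEMO_REGIONS,
        composites={101: [1, 2], 102: [3, 4], 103: [5]},
        majors={201: [101, 102], 202: [103]},
    )
    labelmap, tree = synthetic.make_toy_atlas(atlas_spec)
    tifffile.imwrite(ws / "labelmap.tif", labelmap.voxels)
    tree.to_json(ws / "region_tree.json")

    render = synthetic.RenderSpec(
        background_level=100.0, noise=("gaussian", 20.0), decay_length=120.0
    )
    animals = []
    truth_rows = []
    for genotype, effect in (("WT", 1.0), ("CKO", 1.0)):
        for a in range(3):
            animal = f"{genotype}_{a + 1:02d}"
            counts = {
                r: max(1, int(rng.poisson(c * effect))) for r, c in DEMO_COUNTS.items()
            }
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cells = synthetic.sample_ground_truth_cells(
                labelmap, counts, radius_range=(2.0, 2.8), min_separation=7.0,
                seed=cell_seed,
            )
            left, right = synthetic.render_illumination_pair(
                cells, labelmap, render, seed=cell_seed, animal_id=animal
            )
            imaging.write_volume(left, ws / f"{animal}_left.tif")
            imaging.write_volume(right, ws / f"{animal}_right.tif")
            animals.append(
                {"animal_id": animal, "genotype": genotype, "downsample_factor": 1}
            )
            for r, c in counts.items():
                truth_rows.append(
                    {"animal_id": animal, "genotype": genotype, "region_id": r, "count": c}
                )
    pd.DataFrame(animals).to_csv(ws / "animals.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(ws / "expected_counts.csv", index=False)
    cfg = {
        "labelmap": "labelmap.tif",
        "tree": "region_tree.json",
        "animals": "animals.csv",
        "thresholds": [200, 300, 400, 500],
        "gates": {"default_min": 5, "max_voxels": 4000},
        "connectivity": 26,
        "reference_genotype": "WT",
        "alpha": 0.01,
        "min_ref_count": 25,
        "seed": seed,
        "voxel_size_um": [0.946, 0.946, 2.5],
    }
    (ws / "config.yaml").write_text(yaml.safe_dump(cfg))
    return ws
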