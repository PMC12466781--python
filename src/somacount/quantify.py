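"""Atlas-region quantification of segmented detections.

Takes detection tables from :mod:`somacount.imaging`, assigns each detection
to an atlas region via a co-registered integer labelmap, applies the
cell-volume gates that suppress false-positive puncta (vasculature, dense
innervation), merges the left/right illumination sides by taking the maximum
count per subregion, and pools subregions into composite and major regions
for statistics.

Count tables are long-format pandas DataFrames with columns
``animal_id, genotype, level, region_id, count`` where ``level`` is one of
``subregion | composite | major``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import Detection

COUNT_COLUMNS = ["animal_id", "genotype", "level", "region_id", "count"]

#: Default cell-volume gates, in corrected (acquisition-scale) voxels.
DEFAULT_MIN_VOXELS = 20
DEFAULT_MAX_VOXELS = 4000


@dataclass
class Labelmap:
    """Integer region-id grid co-registered to the (downsampled) image grid; 0 = outside."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("labelmap must be 3D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("labelmap must be integer-valued")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def region_ids(self) -> list[int]:
        ids = np.unique(self.voxels)
        return [int(i) for i in ids if i != 0]


@dataclass
class RegionNode:
    region_id: int
    name: str
    acronym: str
    level: str  # subregion | composite | major
    parent: int | None


class RegionTree:
    """Forest of atlas regions: subregion -> composite -> major.

    Every subregion must have exactly one composite ancestor and one major
    ancestor; composites hang off majors.  The tree is the unit-of-analysis
    map: statistics run at the composite level, heatmaps at the major level.
    """

    LEVELS = ("subregion", "composite", "major")

    def __init__(self, nodes: Iterable[RegionNode]):
        self.nodes: dict[int, RegionNode] = {}
        for node in nodes:
            if node.region_id in self.nodes:
                raise ValueError(f"duplicate region id {node.region_id}")
            if node.level not in self.LEVELS:
                raise ValueError(f"bad level {node.level!r} for region {node.region_id}")
            self.nodes[node.region_id] = node
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.level == "subregion":
                comp = self.composite_of(node.region_id)
                self.major_of(comp)
            elif node.level == "composite":
                self.major_of(node.region_id)

    def composite_of(self, subregion_id: int) -> int:
        node = self.nodes[subregion_id]
        if node.level == "composite":
            return node.region_id
        if node.level != "subregion" or node.parent is None:
            raise ValueError(f"region {subregion_id} has no composite ancestor")
        parent = self.nodes[node.parent]
        if parent.level != "composite":
            raise ValueError(f"parent of subregion {subregion_id} is not a composite")
        return parent.region_id

    def major_of(self, region_id: int) -> int:
        node = self.nodes[region_id]
        while node.level != "major":
            if node.parent is None:
                raise ValueError(f"region {region_id} has no major ancestor")
            node = self.nodes[node.parent]
        return node.region_id

    def children(self, region_id: int) -> list[int]:
        return sorted(
            n.region_id for n in self.nodes.values() if n.parent == region_id
        )

    def ids_at(self, level: str) -> list[int]:
        return sorted(n.region_id for n in self.nodes.values() if n.level == level)

    @property
    def n_composites(self) -> int:
        return len(self.ids_at("composite"))

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "id": n.region_id,
                "name": n.name,
                "acronym": n.acronym,
                "level": n.level,
                "parent": n.parent,
            }
            for n in sorted(self.nodes.values(), key=lambda n: n.region_id)
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionTree":
        payload = json.loads(Path(path).read_text())
        return cls(
            RegionNode(
                region_id=int(r["id"]),
                name=r["name"],
                acronym=r.get("acronym", r["name"]),
                level=r["level"],
                parent=None if r.get("parent") is None else int(r["parent"]),
            )
            for r in payload
        )


@dataclass
class GateSpec:
    """Inclusive cell-volume gates in corrected voxels.

    ``min_voxels`` maps region ids to region-specific minima (e.g. 12 for the
    medial habenula, whose somata are smaller); every other region uses
    ``default_min`` (20).  The maximum (4000) is global and suppresses fused
    vasculature-like components.
    """

    default_min: int = DEFAULT_MIN_VOXELS
    max_voxels: int = DEFAULT_MAX_VOXELS
    min_voxels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, lo in {**self.min_voxels, -1: self.default_min}.items():
            if not 1 <= lo <= self.max_voxels:
                raise ValueError(
                    f"gate for region {region}: need 1 <= min ({lo}) <= max ({self.max_voxels})"
                )

    def min_for(self, region_id: int | None) -> int:
        if region_id is None:
            return self.default_min
        return self.min_voxels.get(int(region_id), self.default_min)


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def _round_half_up(value: float) -> int:
    return int(np.floor(value + 0.5))


def assign_regions(
    detections: Iterable[Detection],
    labelmap: Labelmap,
    keep_outside: bool = False,
) -> list[Detection]:
    """Set ``region_id`` on each detection from the labelmap at its centroid.

    The centroid is rounded half-up per axis (so 3.5 -> voxel 4) and clipped
    to the grid.  Detections landing on background (id 0) are flagged with
    ``region_id = 0``; by default they are excluded from the returned list
    (``keep_outside=True`` retains them for QC accounting).
    """
    shape = labelmap.shape
    out: list[Detection] = []
    for det in detections:
        idx = tuple(
            min(max(_round_half_up(c), 0), s - 1) for c, s in zip(det.centroid, shape)
        )
        region = int(labelmap.voxels[idx])
        det = replace(det, region_id=region)
        if region == 0 and not keep_outside:
            continue
        out.append(det)
    return out


def split_outside(detections: Iterable[Detection]) -> tuple[list[Detection], list[Detection]]:
    """Partition assigned detections into (in-atlas, out-of-atlas)."""
    inside, outside = [], []
    for d in detections:
        (outside if d.region_id == 0 else inside).append(d)
    return inside, outside


# ---------------------------------------------------------------------------
# QC table and threshold selection
# ---------------------------------------------------------------------------

def count_volume_table(
    detections: Iterable[Detection],
    volume_bins: Sequence[float],
) -> pd.DataFrame:
    """Region x threshold x side x volume-bin counts for gate calibration plots.

    ``volume_bins`` are bin edges on ``n_voxels_corrected`` (right-open,
    last bin right-closed, numpy histogram convention).  Marginal sums over
    bins reproduce the per-(region, threshold, side) detection totals.
    """
    volume_bins = np.asarray(list(volume_bins), dtype=float)
    rows = []
    dets = list(detections)
    keys = sorted({(d.region_id or 0, d.threshold, d.side) for d in dets})
    for region, threshold, side in keys:
        volumes = [
            d.n_voxels_corrected
            for d in dets
            if (d.region_id or 0) == region and d.threshold == threshold and d.side == side
        ]
        hist, _ = np.histogram(volumes, bins=volume_bins)
        for lo, hi, n in zip(volume_bins[:-1], volume_bins[1:], hist):
            rows.append(
                {
                    "region_id": region,
                    "threshold": threshold,
                    "side": side,
                    "bin_low": lo,
                    "bin_high": hi,
                    "count": int(n),
                }
            )
    return pd.DataFrame(
        rows, columns=["region_id", "threshold", "side", "bin_low", "bin_high", "count"]
    )


def select_threshold(
    sweep_counts: Mapping[float, int],
    override: float | None = None,
) -> float:
    """Pick the per-animal segmentation threshold by a count-plateau rule.

    ``sweep_counts`` maps each candidate threshold to the total gated count in
    the QC regions at that threshold.  The chosen threshold ``t_i`` minimizes
    the forward relative change ``|C(t_{i+1}) - C(t_i)| / C(t_i)`` — i.e. it
    sits at the start of the flattest step of the count-vs-threshold curve,
    where segmentation is least sensitive to the exact cutoff.  Ties break
    toward the smaller threshold.  A manual ``override`` wins outright.
    """
    if override is not None:
        return float(override)
    thresholds = sorted(sweep_counts)
    if len(thresholds) < 2:
        raise ValueError("need >= 2 thresholds to select from")
    counts = [sweep_counts[t] for t in thresholds]
    if all(c == 0 for c in counts):
        raise ValueError("all QC-region counts are zero; supply a threshold override")
    best_t = None
    best_score = np.inf
    for i in range(len(thresholds) - 1):
        if counts[i] == 0:
            continue
        score = abs(counts[i + 1] - counts[i]) / counts[i]
        if score < best_score:  # strict: ties keep the earlier (smaller) threshold
            best_score = score
            best_t = thresholds[i]
    if best_t is None:
        raise ValueError("no usable threshold step; supply a threshold override")
    return float(best_t)


# ---------------------------------------------------------------------------
# Gating, merging, pooling
# ---------------------------------------------------------------------------

def apply_gates(
    detections: Iterable[Detection], gates: GateSpec | None = None
) -> list[Detection]:
    """Keep detections with min(region) <= n_voxels_corrected <= max (inclusive)."""
    gates = gates or GateSpec()
    return [
        d
        for d in detections
        if gates.min_for(d.region_id) <= d.n_voxels_corrected <= gates.max_voxels
    ]


def count_by_region(
    detections: Iterable[Detection],
    animal_id: str,
    genotype: str,
    all_region_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Subregion-level count table for one animal from gated, assigned detections.

    ``all_region_ids`` forces zero-count rows for regions with no detections.
    """
    counts: dict[int, int] = {}
    if all_region_ids is not None:
        counts = {int(r): 0 for r in all_region_ids}
    for d in detections:
        if d.region_id in (None, 0):
            continue
        counts[int(d.region_id)] = counts.get(int(d.region_id), 0) + 1
    rows = [
        {
            "animal_id": animal_id,
            "genotype": genotype,
            "level": "subregion",
            "region_id": r,
            "count": c,
        }
        for r, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def merge_illumination(counts_left: pd.DataFrame, counts_right: pd.DataFrame) -> pd.DataFrame:
    """Per-subregion maximum of the left- and right-illumination counts.

    Retaining the max compensates for attenuation on the side distal to the
    illumination source.  A region present on only one side keeps that side's
    count.  Both tables must describe the same animals and genotypes.
    """
    for col in ("animal_id", "genotype"):
        if set(counts_left[col].unique()) != set(counts_right[col].unique()):
            raise ValueError(f"left/right tables disagree on {col}")
    key = ["animal_id", "genotype", "level", "region_id"]
    merged = pd.merge(
        counts_left, counts_right, on=key, how="outer", suffixes=("_l", "_r")
    )
    merged["count"] = merged[["count_l", "count_r"]].max(axis=1).astype(int)
    out = merged[key + ["count"]].sort_values(key).reset_index(drop=True)
    return out


def build_composites(
    counts: pd.DataFrame,
    tree: RegionTree,
    min_ref_count: int = 25,
    reference_genotype: str = "WT",
    composite_defs: Mapping[int, Sequence[int]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Pool subregion counts into composite regions, enforcing a reference floor.

    Composite counts are sums of child-subregion counts per animal.  Pooling
    follows ``composite_defs`` (explicit ``{composite_id: [subregion_ids]}``
    map) when given, else the tree's parent edges.  Any composite whose total
    over all reference-genotype animals falls below ``min_ref_count`` is
    merged into a same-major sibling (iteratively, smallest deficient first,
    absorbed by the sibling with the smallest reference total, ties by id);
    a deficient composite with no sibling is flagged excluded.

    Returns the composite-level table and an audit dict with the merge map
    (absorbed composite -> surviving composite) and exclusions.
    """
    sub = counts[counts["level"] == "subregion"]
    if composite_defs is not None:
        sub_to_comp = {
            int(s): int(c) for c, subs in composite_defs.items() for s in subs
        }
    else:
        sub_to_comp = {}
    comp_ids: dict[int, int] = {}
    for region in sub["region_id"].unique():
        region = int(region)
        if region in sub_to_comp:
            comp_ids[region] = sub_to_comp[region]
        elif region in tree.nodes:
            comp_ids[region] = tree.composite_of(region)
        else:
            raise ValueError(f"subregion {region} absent from the region tree")

    pooled = sub.assign(composite=sub["region_id"].map(comp_ids))
    table = (
        pooled.groupby(["animal_id", "genotype", "composite"], as_index=False)["count"]
        .sum()
        .rename(columns={"composite": "region_id"})
    )
    # zero-fill: every composite gets a row for every animal
    animals = table[["animal_id", "genotype"]].drop_duplicates()
    composites = sorted(table["region_id"].unique())
    full = animals.merge(pd.DataFrame({"region_id": composites}), how="cross")
    table = full.merge(table, on=["animal_id", "genotype", "region_id"], how="left")
    table["count"] = table["count"].fillna(0).astype(int)

    # low-count merge on reference-genotype totals
    merge_map: dict[int, int] = {}
    excluded: list[int] = []
    current = {c: c for c in composites}

    def ref_totals() -> dict[int, int]:
        ref = table[table["genotype"] == reference_genotype]
        totals = ref.groupby("region_id")["count"].sum().to_dict()
        return {int(k): int(v) for k, v in totals.items()}

    while True:
        totals = ref_totals()
        deficient = sorted(
            (t, c) for c, t in totals.items() if t < min_ref_count and c not in excluded
        )
        if not deficient:
            break
        _, victim = deficient[0]
        major = tree.major_of(victim) if victim in tree.nodes else None
        siblings = [
            c
            for c in totals
            if c != victim
            and c not in excluded
            and (major is None or (c in tree.nodes and tree.major_of(c) == major))
        ]
        if not siblings:
            excluded.append(victim)
            continue
        host = min(siblings, key=lambda c: (totals[c], c))
        table.loc[table["region_id"] == victim, "region_id"] = host
        table = (
            table.groupby(["animal_id", "genotype", "region_id"], as_index=False)["count"]
            .sum()
        )
        for orig, cur in current.items():
            if cur == victim:
                current[orig] = host
        merge_map[victim] = host

    table = table[~table["region_id"].isin(excluded)]
    table["level"] = "composite"
    table = table[COUNT_COLUMNS].sort_values(
        ["animal_id", "region_id"]
    ).reset_index(drop=True)
    audit = {"merged": merge_map, "excluded": excluded, "n_composites": table["region_id"].nunique()}
    return table, audit


def aggregate_major(
    counts: pd.DataFrame,
    tree: RegionTree,
    value: str = "count",
    how: str = "sum",
) -> pd.DataFrame:
    """Aggregate a composite-level table to major regions.

    Counts are summed over composites; per-animal mean cell volumes are
    averaged *unweighted* over composites (``how='mean'``), matching how
    major-region volume means enter the mixed model.
    """
    comp = counts[counts["level"] == "composite"].copy()
    comp["major"] = comp["region_id"].map(lambda r: tree.major_of(int(r)))
    agg = getattr(
        comp.groupby(["animal_id", "genotype", "major"], as_index=False)[value], how
    )()
    agg = agg.rename(columns={"major": "region_id"})
    agg["level"] = "major"
    cols = ["animal_id", "genotype", "level", "region_id", value]
    return agg[cols].sort_values(["animal_id", "region_id"]).reset_index(drop=True)
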