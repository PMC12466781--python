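"""Synthetic volumes and count tables with known ground truth.

Every downstream stage — segmentation, region counting, illumination merging,
negative-binomial genotype contrasts — is tested against data generated here,
because the real cleared-brain light-sheet volumes this pipeline targets are
hundreds of gigabytes and not redistributable.  The generator emulates the
features the pipeline depends on:

* a cuboid-region integer atlas labelmap with a subregion/composite/major
  hierarchy,
* blob-like somata rendered as truncated 3D Gaussians,
* two illumination sides with exponential depth attenuation along x
  (fluorescence dims on the side distal to the light sheet),
* vasculature-like tubular false positives that the volume gates must reject,
* per-region cell counts with genotype rate ratios and negative-binomial
  overdispersion (variance = mu + mu^2/theta; larger theta = closer to
  Poisson).

It does not attempt optical realism: no refraction, stripe artifacts, tile
shading, or anisotropic point-spread calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import Volume3D, DEFAULT_VOXEL_SIZE_UM
from .quantify import Labelmap, RegionNode, RegionTree


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAtlasSpec:
    """Axis-aligned cuboid regions on a voxel grid; background id is 0.

    ``regions`` maps region id -> ``(z0, z1, y0, y1, x0, x1)`` half-open
    voxel extents.  ``composites``/``majors`` optionally group region ids into
    the two upper hierarchy levels; ungrouped regions get singleton parents.
    """

    grid_shape: tuple[int, int, int]
    regions: dict[int, tuple[int, int, int, int, int, int]]
    composites: dict[int, Sequence[int]] = field(default_factory=dict)
    majors: dict[int, Sequence[int]] = field(default_factory=dict)

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        boxes = []
        for rid, ext in self.regions.items():
            if rid <= 0:
                raise ValueError(f"region id must be positive, got {rid}")
            z0, z1, y0, y1, x0, x1 = ext
            if not (0 <= z0 < z1 <= self.grid_shape[0]
                    and 0 <= y0 < y1 <= self.grid_shape[1]
                    and 0 <= x0 < x1 <= self.grid_shape[2]):
                raise ValueError(f"region {rid} extent {ext} exceeds grid {self.grid_shape}")
            boxes.append((rid, ext))
        for i, (ra, a) in enumerate(boxes):
            for rb, b in boxes[i + 1:]:
                if (a[0] < b[1] and b[0] < a[1]
                        and a[2] < b[3] and b[2] < a[3]
                        and a[4] < b[5] and b[4] < a[5]):
                    raise ValueError(f"regions {ra} and {rb} overlap")


@dataclass
class GroundTruthCell:
    """A simulated soma: where it is, how big, how bright, and its true region."""

    centroid: tuple[float, float, float]  # (z, y, x) voxel units
    radius: float  # voxels; blob sigma = radius / sqrt(2 ln 2) so FWHM-volume matches
    peak_intensity: float
    region_id: int


@dataclass
class VesselSpec:
    """Random straight tubular segments that mimic labelled vasculature."""

    count: int = 4
    radius: float = 1.2
    intensity: float = 300.0


@dataclass
class RenderSpec:
    """How ground-truth cells become an intensity volume.

    ``decay_length`` is the depth constant (voxels) of the per-side
    exponential illumination attenuation along x; ``math.inf`` disables it.
    ``noise`` is ``none``, ``("gaussian", sd)`` or
    ``("poisson_gaussian", gain, sd)``.
    """

    psf_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_level: float = 100.0
    noise: tuple = ("none",)
    decay_length: float = math.inf
    vessel_spec: VesselSpec | None = None

    def validate(self) -> None:
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be nonnegative")
        if not (self.decay_length > 0):
            raise ValueError("decay_length must be positive (or inf)")
        kinds = {"none", "gaussian", "poisson_gaussian"}
        if self.noise[0] not in kinds:
            raise ValueError(f"noise kind must be one of {kinds}")


@dataclass
class CountSimSpec:
    """Simulation twin of the per-region negative-binomial genotype model.

    Counts for animal a of genotype g in region r are drawn
    ``NB(mean = baseline_mean[r] * rate_ratio[r][g], dispersion theta)`` with
    ``variance = mu + mu^2 / theta``.  The reference genotype's rate ratio is
    identically 1.
    """

    region_ids: Sequence[int]
    genotypes: Sequence[str]
    reference: str
    baseline_mean: Mapping[int, float]
    rate_ratio: Mapping[int, Mapping[str, float]]
    dispersion: float
    n_animals: Mapping[str, int]
    seed: int = 0

    def validate(self) -> None:
        if self.reference not in self.genotypes:
            raise ValueError("reference genotype must be listed in genotypes")
        if self.dispersion <= 0:
            raise ValueError("dispersion theta must be positive")
        for r in self.region_ids:
            if self.baseline_mean[r] <= 0:
                raise ValueError(f"baseline mean for region {r} must be positive")
            for g in self.genotypes:
                rr = self.rate_ratio[r][g]
                if rr <= 0:
                    raise ValueError(f"rate ratio for region {r}, genotype {g} must be positive")
                if g == self.reference and rr != 1:
                    raise ValueError("reference genotype must have rate ratio 1")


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def make_toy_atlas(spec: SyntheticAtlasSpec) -> tuple[Labelmap, RegionTree]:
    """Rasterize cuboid regions into a labelmap and build the region hierarchy.

    Region ids not covered by ``spec.composites`` get a singleton composite
    parent with id ``1000 + region_id``; composites not covered by
    ``spec.majors`` get a singleton major with id ``2000 + composite_id``.
    """
    spec.validate()
    grid = np.zeros(spec.grid_shape, dtype=np.int32)
    for rid, (z0, z1, y0, y1, x0, x1) in spec.regions.items():
        grid[z0:z1, y0:y1, x0:x1] = rid

    comp_of: dict[int, int] = {}
    for cid, members in spec.composites.items():
        for rid in members:
            comp_of[int(rid)] = int(cid)
    for rid in spec.regions:
        comp_of.setdefault(rid, 1000 + rid)

    major_of: dict[int, int] = {}
    for mid, members in spec.majors.items():
        for cid in members:
            major_of[int(cid)] = int(mid)
    for cid in set(comp_of.values()):
        major_of.setdefault(cid, 2000 + cid)

    nodes: list[RegionNode] = []
    for mid in sorted(set(major_of.values())):
        nodes.append(RegionNode(mid, f"major {mid}", f"M{mid}", "major", None))
    for cid in sorted(set(comp_of.values())):
        nodes.append(RegionNode(cid, f"composite {cid}", f"C{cid}", "composite", major_of[cid]))
    for rid in sorted(spec.regions):
        nodes.append(RegionNode(rid, f"subregion {rid}", f"R{rid}", "subregion", comp_of[rid]))
    return Labelmap(grid), RegionTree(nodes)


# ---------------------------------------------------------------------------
# Ground-truth cells
# ---------------------------------------------------------------------------

def sample_ground_truth_cells(
    labelmap: Labelmap,
    counts: Mapping[int, int],
    radius_range: tuple[float, float] = (2.0, 3.0),
    min_separation: float = 6.0,
    peak_range: tuple[float, float] = (800.0, 1200.0),
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[GroundTruthCell]:
    """Place cells uniformly inside each region, rejecting crowded placements.

    Each cell's continuous centroid lands inside a voxel of its region (a
    margin of one radius is kept from the grid faces).  Pairwise centroid
    distances are >= ``min_separation``; radii and peaks are uniform in their
    ranges.  Deterministic for a given (labelmap, counts, seed).
    """
    rng = np.random.default_rng(seed)
    placed: list[GroundTruthCell] = []
    shape = np.array(labelmap.shape, dtype=float)
    for region in sorted(counts):
        want = counts[region]
        if want == 0:
            continue
        voxel_idx = np.argwhere(labelmap.voxels == region)
        if voxel_idx.size == 0:
            raise ValueError(f"region {region} has no voxels in the labelmap")
        n_placed = 0
        attempts = 0
        while n_placed < want:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not place {want} cells in region {region} at "
                    f"min_separation {min_separation} ({n_placed} placed, cap {max_attempts})"
                )
            attempts += 1
            base = voxel_idx[rng.integers(len(voxel_idx))]
            jitter = rng.uniform(-0.5, 0.5, size=3)
            cen = base + jitter
            radius = rng.uniform(*radius_range)
            if ((cen < radius).any() or (cen > shape - 1 - radius).any()):
                continue
            nearest = np.round(cen).astype(int)
            if labelmap.voxels[tuple(nearest)] != region:
                continue
            if any(
                np.linalg.norm(cen - np.array(c.centroid)) < min_separation
                for c in placed
            ):
                continue
            placed.append(
                GroundTruthCell(
                    centroid=tuple(float(v) for v in cen),
                    radius=float(radius),
                    peak_intensity=float(rng.uniform(*peak_range)),
                    region_id=int(region),
                )
            )
            n_placed += 1
    return placed


def truth_voxel_count(cell: GroundTruthCell) -> int:
    """Noiseless ground-truth voxel count: voxels with intensity >= half peak.

    With blob sigma = radius / sqrt(2 ln 2), the half-peak isosurface of the
    Gaussian sits at distance ``radius`` from the centre, so the truth is the
    voxel count of a digital ball of that radius around the centroid.
    """
    r = cell.radius
    lo = np.floor(np.array(cell.centroid) - r).astype(int)
    hi = np.ceil(np.array(cell.centroid) + r).astype(int) + 1
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = ((zz - cell.centroid[0]) ** 2
          + (yy - cell.centroid[1]) ** 2
          + (xx - cell.centroid[2]) ** 2)
    return int((d2 <= r * r).sum())


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SIGMA_PER_RADIUS = 1.0 / math.sqrt(2.0 * math.log(2.0))


def _paint_blob(canvas: np.ndarray, cell: GroundTruthCell, scale: float) -> None:
    sigma = cell.radius * _SIGMA_PER_RADIUS
    support = 3.0 * sigma
    lo = np.maximum(np.floor(np.array(cell.centroid) - support).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.array(cell.centroid) + support).astype(int) + 1, canvas.shape
    )
    if (hi <= lo).any():
        return
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = ((zz - cell.centroid[0]) ** 2
          + (yy - cell.centroid[1]) ** 2
          + (xx - cell.centroid[2]) ** 2)
    blob = cell.peak_intensity * scale * np.exp(-d2 / (2.0 * sigma * sigma))
    blob[d2 > support * support] = 0.0  # truncate support at 3 sigma
    region = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, blob, out=region)


def _paint_vessels(canvas: np.ndarray, spec: VesselSpec, rng: np.random.Generator) -> None:
    shape = np.array(canvas.shape, dtype=float)
    for _ in range(spec.count):
        p0 = rng.uniform(0, shape - 1)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(0.3, 0.8) * shape.min()
        n_steps = max(int(length * 2), 2)
        ts = np.linspace(0.0, length, n_steps)
        r = spec.radius
        for t in ts:
            c = p0 + direction * t
            lo = np.maximum(np.floor(c - r).astype(int), 0)
            hi = np.minimum(np.ceil(c + r).astype(int) + 1, canvas.shape)
            if (hi <= lo).any():
                continue
            zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            seg = np.where(d2 <= r * r, spec.intensity, 0.0)
            region = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            np.maximum(region, seg, out=region)


def render_illumination_pair(
    cells: Sequence[GroundTruthCell],
    labelmap: Labelmap,
    render: RenderSpec,
    seed: int = 0,
    animal_id: str = "",
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
) -> tuple[Volume3D, Volume3D]:
    """Render the same cells as seen from the left and right illumination side.

    The left volume attenuates each cell's peak by ``exp(-d / decay_length)``
    with ``d`` the centroid's distance from the left (x=0) grid face; the
    right volume attenuates from the right face.  With infinite decay and no
    noise the two volumes are voxel-identical.  Vessels (if any) are painted
    identically on both sides; noise draws differ per side but derive from
    ``seed``.
    """
    render.validate()
    shape = labelmap.shape
    nx = shape[2]
    for cell in cells:
        if not all(0 <= c <= s - 1 for c, s in zip(cell.centroid, shape)):
            raise ValueError(f"cell centroid {cell.centroid} outside grid {shape}")

    volumes = []
    rng_master = np.random.default_rng(seed)
    side_seeds = rng_master.integers(0, 2**31 - 1, size=2)
    vessel_seed = int(rng_master.integers(0, 2**31 - 1))
    for side, side_seed in zip(("left", "right"), side_seeds):
        canvas = np.zeros(shape, dtype=np.float64)
        for cell in cells:
            x = cell.centroid[2]
            d = x if side == "left" else (nx - 1 - x)
            scale = 1.0 if math.isinf(render.decay_length) else math.exp(-d / render.decay_length)
            _paint_blob(canvas, cell, scale)
        if render.vessel_spec is not None:
            _paint_vessels(canvas, render.vessel_spec, np.random.default_rng(vessel_seed))
        if any(s > 0 for s in render.psf_sigma):
            from scipy import ndimage
            canvas = ndimage.gaussian_filter(canvas, sigma=render.psf_sigma)
        canvas = canvas + render.background_level
        kind = render.noise[0]
        rng = np.random.default_rng(int(side_seed))
        if kind == "gaussian":
            canvas = canvas + rng.normal(0.0, render.noise[1], size=shape)
        elif kind == "poisson_gaussian":
            gain, sd = render.noise[1], render.noise[2]
            canvas = rng.poisson(np.maximum(canvas / gain, 0)) * gain \
                + rng.normal(0.0, sd, size=shape)
        canvas = np.clip(canvas, 0, 65535)
        volumes.append(
            Volume3D(
                voxels=canvas.astype(np.uint16),
                voxel_size=voxel_size,
                bit_depth=16,
                side=side,
                animal_id=animal_id,
            )
        )
    return volumes[0], volumes[1]


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def simulate_count_table(spec: CountSimSpec) -> pd.DataFrame:
    """Draw a long-format count table from the negative-binomial genotype model.

    One row per animal x region at the subregion level (the simulated regions
    play the role of composites when fed straight to the statistics stage).
    NB draws use the gamma-Poisson mixture: lambda ~ Gamma(theta, mu/theta),
    count ~ Poisson(lambda), giving variance mu + mu^2/theta exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    theta = spec.dispersion
    rows = []
    for genotype in spec.genotypes:
        for a in range(spec.n_animals[genotype]):
            animal = f"{genotype}_{a + 1:02d}"
            for region in spec.region_ids:
                mu = spec.baseline_mean[region] * spec.rate_ratio[region][genotype]
                lam = rng.gamma(shape=theta, scale=mu / theta)
                count = int(rng.poisson(lam))
                rows.append(
                    {
                        "animal_id": animal,
                        "genotype": genotype,
                        "level": "composite",
                        "region_id": int(region),
                        "count": count,
                    }
                )
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "level", "region_id", "count"])
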