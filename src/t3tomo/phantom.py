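"""Seeded synthetic tumor-macrosection generator with complete ground truth.

The phantom emulates the structures the reconstruction pipeline is built to
measure in cleared mammary-tumor macrosections imaged in five channels:

* a tumor-marker channel (``her2``): a solid ellipsoid of tumor signal;
* a checkpoint-ligand channel (``pdl1``): a bright rim on the tumor surface
  plus perivascular sheaths around core vessels, so that a target fraction of
  tumor voxels is ligand-positive;
* an endothelium channel (``cd31``): a branching random-walk tube network,
  with larger, ligand-sheathed vessels in the tumor core and smaller bare
  vessels at the periphery;
* a leukocyte channel (``cd45``): membrane-labelled cells rendered as hollow
  spherical shells, mostly clustered just outside the tumor margin, plus a
  minority of filled blobs that act as distractors for the membrane
  classifier;
* a proliferation channel (``ki67``): small puncta inside the tumor.

The clean signal is blurred by a Gaussian PSF, attenuated per optical slice
with depth inside each slab (factor ``exp(-z * dz / tau)``), split into
serial macrosections that share one boundary slice (whose signal is halved in
each copy, so that boundary summation during fusion approximately restores
it), rigidly perturbed per section, split into overlapping tiles with
recorded offsets, and corrupted with Poisson + Gaussian read noise.

Every stochastic choice derives from a single integer seed, and the
:class:`PhantomTruth` object records all masks, transforms, offsets, counts
and fractions needed by recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .core import (
    DEFAULT_SPACING,
    LabelMask,
    MacrosectionStack,
    QuantRecord,
    RigidTransform2D,
    VoxelGrid,
)
from .stitching import TileLayout, nominal_tile_origins, tile_size_for_layout

CHANNELS = ["her2", "pdl1", "cd31", "cd45", "ki67"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic tumor; defaults are the package's
    reference study condition (a down-scaled whole-tumor reconstruction:
    3 serial slabs of 48 optical slices, 2x2 tile mosaics, 5 channels)."""

    shape: tuple[int, int, int] = (142, 256, 256)  # full volume (z, y, x)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    # tumor geometry
    tumor_center_um: tuple[float, float, float] | None = None  # default: centre
    tumor_semiaxes_um: tuple[float, float, float] = (330.0, 165.0, 165.0)
    target_ligand_fraction: float = 0.43  # tumor voxels that are ligand-positive
    rim_thickness_um: float | None = None  # overrides target_ligand_fraction
    # vessels
    n_vessels_core: int = 10
    n_vessels_peripheral: int = 10
    vessel_radius_core_um: tuple[float, float] = (6.0, 8.0)
    vessel_radius_peripheral_um: tuple[float, float] = (4.0, 6.0)
    vessel_length_um: float = 220.0
    vessel_branch_prob: float = 0.03
    core_sheath_prob: float = 1.0
    peripheral_sheath_prob: float = 0.0
    core_depth_um: float = 80.0  # distance-to-margin beyond which a voxel is "core"
    # immune cells
    n_immune_cells: int = 150
    n_distractor_blobs: int = 30
    ring_radius_um: float = 9.0
    ring_thickness_um: float = 3.0
    marginal_cluster_fraction: float = 0.7
    n_margin_clusters: int = 6
    infiltration_scale_um: float = 50.0  # exponential depth scale of cells inside
    # proliferation puncta
    n_puncta: int = 250
    punctum_radius_um: float = 2.2
    # optics / noise
    # emulates deconvolved stacks (deconvolution precedes analysis upstream
    # of this pipeline), hence the near-isotropic effective PSF
    psf_sigma_um: tuple[float, float, float] = (2.0, 1.5, 1.5)
    attenuation_tau_um: float = 400.0
    poisson_scale: float = 0.8  # photons per intensity unit; 0 disables
    read_noise_sd: float = 2.0  # additive Gaussian sd; 0 disables
    # sectioning / tiling
    n_sections: int = 3
    max_shift_vox: float = 6.0
    max_rotation_deg: float = 3.0
    tile_rows: int = 2
    tile_cols: int = 2
    tile_overlap: float = 0.1
    tile_jitter_vox: int = 2
    # amplitudes (arbitrary intensity units on a 16-bit scale)
    background_tissue: float = 6.0
    background_outside: float = 0.5
    amp_tumor: float = 150.0
    amp_ligand: float = 180.0
    amp_vessel: float = 200.0
    amp_immune: float = 200.0
    amp_puncta: float = 220.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tile_overlap <= 0.5:
            raise ValueError("tile overlap must be in (0, 0.5]")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.rim_thickness_um is not None and self.rim_thickness_um >= min(
            self.tumor_semiaxes_um
        ):
            raise ValueError("rim thickness must be below the smallest tumor semi-axis")
        depth = self.shape[0]
        if self.n_sections > 1 and (depth + self.n_sections - 1) % self.n_sections:
            raise ValueError(
                f"depth {depth} cannot be split into {self.n_sections} sections "
                "sharing one boundary slice (need (depth + n - 1) % n == 0)"
            )

    @property
    def section_depth(self) -> int:
        return (self.shape[0] + self.n_sections - 1) // self.n_sections

    @property
    def channel_names(self) -> list[str]:
        return list(CHANNELS)


@dataclass
class TileSet:
    """The tiles of one macrosection, as acquired (uint16, noisy)."""

    tiles: list[VoxelGrid]
    layout: TileLayout
    section_index: int


@dataclass
class PhantomTruth:
    """Generator-side ground truth for all recovery tests."""

    spec: PhantomSpec
    masks: dict[str, np.ndarray]  # tumor, ligand, vessels (labels), immune (labels), distractors, puncta, tissue
    transforms: list[RigidTransform2D]  # absolute per-section perturbations
    tile_offsets: list[np.ndarray]  # per section, (n_tiles, 3) true (z0, y0, x0)
    immune_centroids_um: np.ndarray  # (n, 3) in the unsplit frame, (z, y, x)
    immune_count: int
    immune_inside: np.ndarray  # bool per cell: centroid inside the tumor mask
    immune_margin_distance_um: np.ndarray  # per cell distance to the tumor outline
    vessel_regions: list[str]  # per vessel id (1-based): core | periphery | stroma
    vessel_sheathed: np.ndarray  # bool per vessel id
    dp_voxel_fraction: float
    dp_object_fraction: float
    rim_thickness_um: float
    volume_clean: np.ndarray | None  # (c, z, y, x) float32, post-PSF, pre-attenuation
    sections_clean: list[np.ndarray] | None  # per section, post-everything-but-noise

    @property
    def median_inside_distance_um(self) -> float:
        d = self.immune_margin_distance_um[self.immune_inside]
        return float(np.median(d)) if d.size else math.nan

    def vessel_positive_fraction(self, region: str | None = None) -> float:
        idx = np.arange(len(self.vessel_regions))
        if region is not None:
            idx = idx[[r == region for r in self.vessel_regions]]
        if idx.size == 0:
            return math.nan
        return float(self.vessel_sheathed[idx].mean())


# ---------------------------------------------------------------------------
# rendering helpers

def _ball_region(shape, spacing, center_um, radius_um):
    """Bounding-box slices and the um-distance field around a centre point."""
    lo, hi, axes = [], [], []
    for ax in range(3):
        c, s, n = center_um[ax], spacing[ax], shape[ax]
        a = max(0, int(math.floor((c - radius_um) / s)) - 1)
        b = min(n, int(math.ceil((c + radius_um) / s)) + 2)
        if a >= b:
            return None, None
        lo.append(a)
        hi.append(b)
        axes.append((np.arange(a, b) * s - c) ** 2)
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return sl, np.sqrt(d2)


def _stamp_ball(mask, spacing, center_um, radius_um, inner_um=0.0, value=True):
    sl, d = _ball_region(mask.shape, spacing, center_um, radius_um)
    if sl is None:
        return
    sel = d <= radius_um
    if inner_um > 0:
        sel &= d >= inner_um
    mask[sl][sel] = value


def _inplane_disk(radius_vox: int) -> np.ndarray:
    """3D structuring element: a disk in (y, x), single plane in z."""
    r = int(radius_vox)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return ((yy**2 + xx**2) <= r**2)[None]


def _ellipsoid_mask(shape, spacing, center_um, semiaxes_um):
    zz = (np.arange(shape[0]) * spacing[0] - center_um[0]) / semiaxes_um[0]
    yy = (np.arange(shape[1]) * spacing[1] - center_um[1]) / semiaxes_um[1]
    xx = (np.arange(shape[2]) * spacing[2] - center_um[2]) / semiaxes_um[2]
    return (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ) <= 1.0


def _grow_vessel(rng, start_um, radius_um, labels, vid, spacing, allowed, length_um, branch_prob):
    """Random-walk tube: stamp spheres along a persistent walk inside `allowed`."""
    shape = labels.shape
    step = 4.0  # um

    def in_allowed(p):
        v = tuple(int(round(p[a] / spacing[a])) for a in range(3))
        if any(v[a] < 0 or v[a] >= shape[a] for a in range(3)):
            return False
        return bool(allowed[v])

    stack = [(np.asarray(start_um, float), _random_dir(rng), length_um)]
    n_branches = 0
    while stack:
        pos, d, budget = stack.pop()
        while budget > 0:
            _stamp_vessel_ball(labels, spacing, pos, radius_um, vid)
            # persistent direction with in-plane bias
            d = d + 0.45 * _random_dir(rng)
            d[0] *= 0.35
            d /= np.linalg.norm(d) + 1e-12
            nxt = pos + step * d
            if not in_allowed(nxt):
                ok = False
                for _ in range(8):
                    d = _random_dir(rng)
                    d[0] *= 0.35
                    d /= np.linalg.norm(d) + 1e-12
                    nxt = pos + step * d
                    if in_allowed(nxt):
                        ok = True
                        break
                if not ok:
                    break
            if n_branches < 2 and rng.random() < branch_prob:
                bd = d + 0.8 * _random_dir(rng)
                bd /= np.linalg.norm(bd) + 1e-12
                stack.append((pos.copy(), bd, budget * 0.5))
                n_branches += 1
            pos = nxt
            budget -= step


def _random_dir(rng):
    v = rng.normal(size=3)
    return v / (np.linalg.norm(v) + 1e-12)


def _stamp_vessel_ball(labels, spacing, center_um, radius_um, vid):
    sl, d = _ball_region(labels.shape, spacing, center_um, radius_um)
    if sl is None:
        return
    sub = labels[sl]
    sel = (d <= radius_um) & (sub == 0)
    sub[sel] = vid


# ---------------------------------------------------------------------------
# generation

def generate_phantom(spec: PhantomSpec, keep_clean: bool = True):
    """Render the phantom and return ``(sections, truth)``.

    ``sections`` is a list of :class:`TileSet`, one per macrosection, holding
    uint16 tiles exactly as the pipeline would receive them from the
    microscope.  ``truth`` is the matching :class:`PhantomTruth`.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    sp = tuple(spec.spacing)
    extent = tuple(shape[a] * sp[a] for a in range(3))
    center = spec.tumor_center_um or tuple(e / 2 for e in extent)
    if any(
        center[a] + spec.tumor_semiaxes_um[a] > extent[a]
        or center[a] - spec.tumor_semiaxes_um[a] < 0
        for a in range(3)
    ):
        raise ValueError("tumor ellipsoid exceeds the volume")

    tumor = _ellipsoid_mask(shape, sp, center, spec.tumor_semiaxes_um)

    # distance to the tumor margin, positive on both sides (um)
    dist_in = ndi.distance_transform_edt(tumor, sampling=sp)
    dist_out = ndi.distance_transform_edt(~tumor, sampling=sp)
    core = dist_in > spec.core_depth_um

    # tissue envelope: tumor plus a stromal margin; autofluorescent background
    tissue = dist_out <= 80.0
    tissue |= tumor

    # ---- vessels ------------------------------------------------------
    vessel_labels = np.zeros(shape, dtype=np.int16)
    vessel_regions: list[str] = []
    vessel_sheathed: list[bool] = []
    # peripheral vessels live between the ligand-positive surface rim and the
    # core, with a buffer so their perivascular shells stay out of rim signal
    rim_guess = float(
        np.quantile(dist_in[tumor], spec.target_ligand_fraction)
        if spec.rim_thickness_um is None
        else spec.rim_thickness_um
    )
    buffer_um = spec.vessel_radius_peripheral_um[1] + 6.0
    periph_allowed = tumor & ~core & (dist_in > rim_guess + buffer_um)
    if not periph_allowed.any():
        periph_allowed = tumor & ~core
    vid = 0
    for kind in ("core", "peripheral"):
        n = spec.n_vessels_core if kind == "core" else spec.n_vessels_peripheral
        rlo, rhi = (
            spec.vessel_radius_core_um
            if kind == "core"
            else spec.vessel_radius_peripheral_um
        )
        allowed = core if kind == "core" else periph_allowed
        seeds = np.argwhere(allowed)
        for _ in range(n):
            vid += 1
            seed_vox = seeds[rng.integers(len(seeds))]
            start = seed_vox * np.asarray(sp)
            radius = rng.uniform(rlo, rhi)
            _grow_vessel(
                rng, start, radius, vessel_labels, vid, sp, allowed,
                spec.vessel_length_um, spec.vessel_branch_prob,
            )
            p = spec.core_sheath_prob if kind == "core" else spec.peripheral_sheath_prob
            vessel_sheathed.append(bool(rng.random() < p))
    # realized region per vessel from its rendered voxels
    for v in range(1, vid + 1):
        vox = vessel_labels == v
        if not vox.any():
            vessel_regions.append("stroma")
            continue
        frac_in = tumor[vox].mean()
        if frac_in < 0.5:
            vessel_regions.append("stroma")
        elif core[vox].mean() >= 0.5:
            vessel_regions.append("core")
        else:
            vessel_regions.append("periphery")
    vessel_sheathed = np.asarray(vessel_sheathed, dtype=bool)

    # perivascular ligand sheaths: a shell 1-2 voxels outside the surface
    vessel_any = vessel_labels > 0
    sheath = np.zeros(shape, dtype=bool)
    struct = _inplane_disk(2)
    objects = ndi.find_objects(vessel_labels)
    for v in range(1, vid + 1):
        if not vessel_sheathed[v - 1] or objects[v - 1] is None:
            continue
        sl = tuple(
            slice(max(0, s.start - 3), min(n, s.stop + 3))
            for s, n in zip(objects[v - 1], shape)
        )
        vmask = vessel_labels[sl] == v
        sheath[sl] |= ndi.binary_dilation(vmask, structure=struct) & ~vessel_any[sl]

    # ---- ligand rim: thickness set so that the requested fraction of tumor
    # voxels ends up ligand-positive (rim plus in-tumor sheath voxels)
    n_tumor = int(tumor.sum())
    sheath_in_tumor = sheath & tumor
    if spec.rim_thickness_um is not None:
        rim_t = float(spec.rim_thickness_um)
    else:
        target = int(round(spec.target_ligand_fraction * n_tumor))
        d_free = np.sort(dist_in[tumor & ~sheath_in_tumor])
        k = target - int(sheath_in_tumor.sum())
        k = min(max(k, 1), d_free.size)
        rim_t = float(d_free[k - 1])
    rim = tumor & (dist_in <= rim_t)
    ligand = rim | sheath

    # ---- immune cells -------------------------------------------------
    n_marginal = int(round(spec.marginal_cluster_fraction * spec.n_immune_cells))
    n_inside = spec.n_immune_cells - n_marginal
    centers: list[np.ndarray] = []
    min_sep = 2.4 * spec.ring_radius_um

    def too_close(p):
        return any(np.linalg.norm(p - q) < min_sep for q in centers)

    def sample_at_margin_depth(depth_um, outside):
        """Random point at a given distance from the margin (um coords)."""
        field_mask = dist_out if outside else dist_in
        band = np.abs(field_mask - depth_um) < 4.0
        band &= tissue
        cand = np.argwhere(band)
        if len(cand) == 0:
            return None
        return cand[rng.integers(len(cand))] * np.asarray(sp)

    margin_lo = spec.ring_radius_um + 2.0
    cluster_anchors = []
    for _ in range(spec.n_margin_clusters):
        p = sample_at_margin_depth(rng.uniform(margin_lo, 30.0), outside=True)
        if p is not None:
            cluster_anchors.append(p)
    guard = 0
    while len(centers) < n_marginal and guard < 20000:
        guard += 1
        anchor = cluster_anchors[rng.integers(len(cluster_anchors))]
        p = anchor + rng.normal(scale=30.0, size=3) * np.array([0.5, 1.0, 1.0])
        v = tuple(int(round(p[a] / sp[a])) for a in range(3))
        if any(v[a] < 0 or v[a] >= shape[a] for a in range(3)):
            continue
        if tumor[v] or not tissue[v] or dist_out[v] < margin_lo:
            continue
        if _near_volume_edge(p, extent, spec.ring_radius_um + 4.0):
            continue
        if not too_close(p):
            centers.append(p)
    while len(centers) < n_marginal + n_inside and guard < 40000:
        guard += 1
        depth = rng.exponential(spec.infiltration_scale_um) + margin_lo
        p = sample_at_margin_depth(depth, outside=False)
        if p is None or _near_volume_edge(p, extent, spec.ring_radius_um + 4.0):
            continue
        if not too_close(p):
            centers.append(p)
    immune_centroids = np.asarray(centers)
    n_cells = len(centers)

    immune_labels = np.zeros(shape, dtype=np.int16)
    r_out = spec.ring_radius_um
    r_in = r_out - spec.ring_thickness_um
    for i, c in enumerate(immune_centroids, start=1):
        sl, d = _ball_region(shape, sp, c, r_out)
        sel = (d <= r_out) & (d >= r_in)
        immune_labels[sl][sel] = i

    distractors = np.zeros(shape, dtype=bool)
    n_blobs = 0
    guard = 0
    while n_blobs < spec.n_distractor_blobs and guard < 20000:
        guard += 1
        vox = np.array([rng.integers(n) for n in shape])
        p = vox * np.asarray(sp)
        if not tissue[tuple(vox)] or too_close(p):
            continue
        if _near_volume_edge(p, extent, spec.ring_radius_um + 4.0):
            continue
        centers.append(p)
        _stamp_ball(distractors, sp, p, 6.0)
        n_blobs += 1

    # ---- proliferation puncta -----------------------------------------
    puncta = np.zeros(shape, dtype=bool)
    tumor_vox = np.argwhere(tumor)
    for _ in range(spec.n_puncta):
        c = tumor_vox[rng.integers(len(tumor_vox))] * np.asarray(sp)
        _stamp_ball(puncta, sp, c, spec.punctum_radius_um)

    # ---- clean channels ------------------------------------------------
    bg = np.where(tissue, spec.background_tissue, spec.background_outside).astype(
        np.float32
    )
    channels = np.empty((5,) + shape, dtype=np.float32)
    channels[0] = bg + spec.amp_tumor * tumor
    channels[1] = bg + spec.amp_ligand * ligand
    channels[2] = bg + spec.amp_vessel * (vessel_labels > 0)
    channels[3] = bg + spec.amp_immune * ((immune_labels > 0) | distractors)
    channels[4] = bg + spec.amp_puncta * puncta

    sigma_vox = tuple(s / p for s, p in zip(spec.psf_sigma_um, sp))
    for c in range(5):
        ndi.gaussian_filter(channels[c], sigma=sigma_vox, output=channels[c])

    volume_clean = channels.copy() if keep_clean else None

    # ---- truth quantities ---------------------------------------------
    outline = tumor & ~ndi.binary_erosion(
        tumor, structure=ndi.generate_binary_structure(3, 1)
    )
    dist_to_outline = ndi.distance_transform_edt(~outline, sampling=sp)
    cell_vox = np.round(immune_centroids / np.asarray(sp)).astype(int)
    cell_vox = np.clip(cell_vox, 0, np.asarray(shape) - 1)
    immune_inside = tumor[tuple(cell_vox.T)]
    immune_dist = dist_to_outline[tuple(cell_vox.T)]

    dp_vox = float((tumor & ligand).sum() / n_tumor)
    lbl, n_obj = ndi.label(tumor)
    pos_obj = 0
    for o in range(1, n_obj + 1):
        sel = lbl == o
        if ligand[sel].mean() >= 0.5:
            pos_obj += 1
    dp_obj = pos_obj / n_obj if n_obj else math.nan

    transforms = [RigidTransform2D.identity()]
    for _ in range(1, spec.n_sections):
        transforms.append(
            RigidTransform2D(
                dy=float(rng.uniform(-spec.max_shift_vox, spec.max_shift_vox)),
                dx=float(rng.uniform(-spec.max_shift_vox, spec.max_shift_vox)),
                theta_deg=float(
                    rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
                ),
            )
        )

    # ---- sectioning, perturbation, tiling, noise ----------------------
    d = spec.section_depth
    sections: list[TileSet] = []
    tile_offsets: list[np.ndarray] = []
    sections_clean: list[np.ndarray] | None = [] if keep_clean else None
    layout = TileLayout(
        rows=spec.tile_rows, cols=spec.tile_cols, overlap=spec.tile_overlap
    )
    z_factors = np.exp(
        -np.arange(d) * sp[0] / spec.attenuation_tau_um
    ).astype(np.float32)
    for k in range(spec.n_sections):
        z0 = k * (d - 1)
        block = channels[:, z0 : z0 + d].copy()
        block *= z_factors[None, :, None, None]
        if k > 0:
            block[:, 0] *= 0.5
        if k < spec.n_sections - 1:
            block[:, -1] *= 0.5
        if not transforms[k].is_identity():
            block = transforms[k].apply(block, order=1)
        if sections_clean is not None:
            sections_clean.append(block.astype(np.float32))
        th, tw = tile_size_for_layout(layout, block.shape[-2:])
        origins = nominal_tile_origins(layout, block.shape[-2:])
        true_offsets = []
        tiles = []
        for t, (oy, ox) in enumerate(origins):
            if t > 0 and spec.tile_jitter_vox > 0:
                oy = int(
                    np.clip(
                        oy + rng.integers(-spec.tile_jitter_vox, spec.tile_jitter_vox + 1),
                        0, block.shape[-2] - th,
                    )
                )
                ox = int(
                    np.clip(
                        ox + rng.integers(-spec.tile_jitter_vox, spec.tile_jitter_vox + 1),
                        0, block.shape[-1] - tw,
                    )
                )
            true_offsets.append((0, oy, ox))
            tile = block[:, :, oy : oy + th, ox : ox + tw].copy()
            if spec.poisson_scale > 0:
                tile = rng.poisson(tile * spec.poisson_scale).astype(
                    np.float32
                ) / spec.poisson_scale
            if spec.read_noise_sd > 0:
                tile += rng.normal(scale=spec.read_noise_sd, size=tile.shape).astype(
                    np.float32
                )
            tile = np.clip(np.round(tile), 0, 65535).astype(np.uint16)
            tiles.append(VoxelGrid(tile, sp, list(CHANNELS)))
        sections.append(TileSet(tiles=tiles, layout=layout, section_index=k))
        tile_offsets.append(np.asarray(true_offsets, dtype=int))

    truth = PhantomTruth(
        spec=spec,
        masks={
            "tumor": tumor,
            "ligand": ligand,
            "rim": rim,
            "vessels": vessel_labels,
            "immune": immune_labels,
            "distractors": distractors,
            "puncta": puncta,
            "tissue": tissue,
            "outline": outline,
        },
        transforms=transforms,
        tile_offsets=tile_offsets,
        immune_centroids_um=immune_centroids,
        immune_count=n_cells,
        immune_inside=np.asarray(immune_inside, dtype=bool),
        immune_margin_distance_um=np.asarray(immune_dist, dtype=float),
        vessel_regions=vessel_regions,
        vessel_sheathed=vessel_sheathed,
        dp_voxel_fraction=dp_vox,
        dp_object_fraction=dp_obj,
        rim_thickness_um=rim_t,
        volume_clean=volume_clean,
        sections_clean=sections_clean,
    )
    return sections, truth


def _near_volume_edge(p_um, extent, margin_um):
    return any(p_um[a] < margin_um or p_um[a] > extent[a] - margin_um for a in range(3))


def truth_report(truth: PhantomTruth):
    """Ground-truth quantities as a QuantRecord table, in the same schema as
    the analysis outputs, so truth and recovery can be diffed directly."""
    n_tumor = int(truth.masks["tumor"].sum())
    records = [
        QuantRecord(
            "her2+pdl1+_voxels",
            truth.dp_voxel_fraction * n_tumor,
            n_tumor,
        ),
        QuantRecord(
            "her2+pdl1-_voxels",
            (1 - truth.dp_voxel_fraction) * n_tumor,
            n_tumor,
        ),
        QuantRecord("cd45_count", truth.immune_count, 1),
        QuantRecord(
            "cd45_median_margin_distance_um", truth.median_inside_distance_um, 1
        ),
    ]
    for region in ("whole", "core", "periphery", "stroma"):
        reg = None if region == "whole" else region
        ids = [
            i
            for i, r in enumerate(truth.vessel_regions)
            if reg is None or r == reg
        ]
        pos = int(truth.vessel_sheathed[ids].sum()) if ids else 0
        records.append(
            QuantRecord("cd31+pdl1+_vessels", pos, len(ids), region=region)
        )
    return records


def truth_masks_as_labelmasks(truth: PhantomTruth) -> dict[str, LabelMask]:
    sp = truth.spec.spacing
    out = {}
    for name, arr in truth.masks.items():
        out[name] = LabelMask(arr, source_channel=name, rule="phantom truth", spacing=sp)
    return out


__all__ = [
    "CHANNELS",
    "PhantomSpec",
    "PhantomTruth",
    "TileSet",
    "generate_phantom",
    "truth_report",
    "truth_masks_as_labelmasks",
]
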