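"""Serial-section registration and whole-tumor fusion.

Consecutive 400 um slabs share structure only at their touching faces, so
registration works on maximum-intensity projections of the three boundary
slices: translation by phase correlation, rotation by a coarse-to-fine search
maximizing normalized cross-correlation.  Fusion concatenates the rigidly
resampled slabs in z and closes the cut gaps by replacing the two touching
boundary slices with one voxelwise-summed slice (clipped at the intensity
type's maximum), so the fused depth is ``sum(depths) - (n - 1)``.  Finally,
background outside the stained tissue is cleared with a morphological tissue
mask to aid visualization and downstream segmentation.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .core import MacrosectionStack, RigidTransform2D, TumorVolume, VoxelGrid


def _boundary_mip(stack: MacrosectionStack, reference_channel: str, top: bool, n: int = 3):
    grid = stack.grid
    img = (
        grid.channel_sum()
        if reference_channel == "sum"
        else grid.channel(reference_channel).astype(np.float32)
    )
    slab = img[:n] if top else img[-n:]
    return slab.max(axis=0)


def _pad_to(img: np.ndarray, shape_yx) -> np.ndarray:
    """Zero-pad the trailing (y, x) axes at the bottom/right to a target shape."""
    pad = [(0, 0)] * (img.ndim - 2) + [
        (0, shape_yx[0] - img.shape[-2]),
        (0, shape_yx[1] - img.shape[-1]),
    ]
    if any(p[1] < 0 for p in pad):
        raise ValueError("cannot pad to a smaller shape")
    if all(p[1] == 0 for p in pad):
        return img
    return np.pad(img, pad)


def _gradient_magnitude(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    gy, gx = np.gradient(ndi.gaussian_filter(img, sigma))
    return np.sqrt(gy * gy + gx * gx)


def _ncc_masked(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x = a[mask].astype(np.float64)
    y = b[mask].astype(np.float64)
    if x.size < 64:
        return -np.inf
    x -= x.mean()
    y -= y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / denom) if denom else 0.0


def _score_transform(fixed: np.ndarray, moving: np.ndarray, t: RigidTransform2D) -> float:
    moved = t.apply(moving)
    support = t.apply(np.ones_like(moving), order=0).astype(bool)
    return _ncc_masked(fixed, moved, support)


def register_sections(
    fixed: MacrosectionStack,
    moving: MacrosectionStack,
    reference_channel: str = "sum",
    rotation_search: bool = True,
    max_rotation_deg: float = 10.0,
    score_threshold: float = 0.2,
    n_boundary_slices: int = 1,
    use_gradient: bool = True,
) -> RigidTransform2D:
    """Estimate the in-plane rigid transform mapping ``moving`` onto ``fixed``.

    The bottom boundary image of ``fixed`` (MIP of ``n_boundary_slices``) is
    matched against the top boundary image of ``moving``: translation by
    phase correlation, rotation by a coarse-to-fine search maximizing
    normalized cross-correlation.  Only the touching faces of adjoining
    slabs share structure, so a single boundary slice is the default — a
    deeper projection mixes in content the other section does not contain
    and flattens the rotation optimum.  ``use_gradient`` registers
    gradient-magnitude images, which weight the rim, vessels and cells over
    the broad smooth tumor body.  If the best score falls below
    ``score_threshold`` the identity is returned (with the failing score
    recorded) and a warning is emitted.
    """
    if fixed.grid.spacing != moving.grid.spacing:
        raise ValueError("sections have different voxel spacing")
    if fixed.grid.channel_names != moving.grid.channel_names:
        raise ValueError("sections have different channel sets")
    f = _boundary_mip(fixed, reference_channel, top=False, n=n_boundary_slices)
    m = _boundary_mip(moving, reference_channel, top=True, n=n_boundary_slices)
    common = (max(f.shape[0], m.shape[0]), max(f.shape[1], m.shape[1]))
    f = _pad_to(f, common)
    m = _pad_to(m, common)
    if use_gradient:
        f = _gradient_magnitude(f)
        m = _gradient_magnitude(m)

    def best_at_angle(theta: float) -> RigidTransform2D:
        rot = RigidTransform2D(0.0, 0.0, theta).apply(m) if theta else m
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shift, _, _ = phase_cross_correlation(
                f, rot, upsample_factor=10, normalization=None
            )
        t = RigidTransform2D(dy=float(shift[0]), dx=float(shift[1]), theta_deg=theta)
        return RigidTransform2D(t.dy, t.dx, t.theta_deg, score=_score_transform(f, m, t))

    candidates = [best_at_angle(0.0)]
    if rotation_search:
        coarse = np.arange(-max_rotation_deg, max_rotation_deg + 0.5, 1.0)
        candidates += [best_at_angle(float(th)) for th in coarse if th != 0.0]
        best = max(candidates, key=lambda t: t.score)
        fine = np.arange(best.theta_deg - 0.9, best.theta_deg + 0.95, 0.1)
        candidates += [best_at_angle(float(th)) for th in fine]
    best = max(candidates, key=lambda t: t.score)
    if not np.isfinite(best.score) or best.score < score_threshold:
        warnings.warn(
            f"section registration score {best.score:.3f} below "
            f"{score_threshold}; returning identity",
            stacklevel=2,
        )
        return RigidTransform2D(0.0, 0.0, 0.0, score=best.score)
    return best


def fuse_volume(
    sections: list[MacrosectionStack],
    transforms: list[RigidTransform2D],
) -> TumorVolume:
    """Concatenate registered sections, merging each junction into one slice.

    ``transforms`` holds one transform per section relative to its
    predecessor's frame (the first must be the identity); they are chained
    cumulatively so every section lands in the first section's frame.  At
    each junction the last slice of section ``k`` and the first slice of
    section ``k+1`` are replaced by one slice holding their voxelwise sum,
    clipped to the maximum of the input intensity type.
    """
    if not sections:
        raise ValueError("no sections given")
    if len(transforms) != len(sections):
        raise ValueError("one transform per section required")
    if not transforms[0].is_identity(1e-3):
        raise ValueError("the first section's transform must be the identity")
    order = [s.section_index for s in sections]
    if order != sorted(order):
        raise ValueError("sections must be ordered by section_index")
    first = sections[0].grid
    for s in sections[1:]:
        if s.grid.spacing != first.spacing or s.grid.channel_names != first.channel_names:
            raise ValueError("sections have mismatched spacing or channels")
    # stitched canvases may differ by a few voxels; bring all to a common plane
    plane = (
        max(s.grid.data.shape[2] for s in sections),
        max(s.grid.data.shape[3] for s in sections),
    )

    dtype = first.data.dtype
    integer = np.issubdtype(dtype, np.integer)
    hi = float(np.iinfo(dtype).max) if integer else np.inf

    depths = [s.grid.data.shape[1] for s in sections]
    out_depth = sum(depths) - (len(sections) - 1)
    nch = first.n_channels
    out = np.zeros((nch, out_depth) + plane, dtype=np.float32)

    cumulative = [transforms[0]]
    for t in transforms[1:]:
        cumulative.append(cumulative[-1].compose(t))

    boundaries: list[int] = []
    z = 0
    pending = None  # held last slice of the previous section
    for k, (sec, ct) in enumerate(zip(sections, cumulative)):
        block = _pad_to(sec.grid.data, plane).astype(np.float32)
        if not ct.is_identity():
            block = ct.apply(block, order=1)
        if pending is not None:
            merged = pending + block[:, 0]
            if integer:
                np.clip(merged, 0, hi, out=merged)
            out[:, z] = merged
            boundaries.append(z)
            z += 1
            block = block[:, 1:]
        last = len(sections) - 1
        stop = block.shape[1] - (1 if k < last else 0)
        out[:, z : z + stop] = block[:, :stop]
        z += stop
        pending = block[:, -1] if k < last else None

    if integer:
        out = np.clip(np.round(out), 0, hi).astype(dtype)
    grid = VoxelGrid(out, first.spacing, list(first.channel_names))
    return TumorVolume(grid=grid, section_boundaries=boundaries, transforms=cumulative)


def tissue_mask(
    volume: TumorVolume,
    reference_channel: str = "sum",
    close_radius_vox: int = 10,
    smooth_sigma_vox: float = 2.0,
) -> np.ndarray:
    """Boolean stained-tissue mask: global Otsu on the smoothed reference
    channel, then per-slice closing and hole filling, then the largest
    3D connected component."""
    grid = volume.grid
    ref = (
        grid.channel_sum()
        if reference_channel == "sum"
        else grid.channel(reference_channel).astype(np.float32)
    )
    sm = np.empty_like(ref)
    for z in range(ref.shape[0]):
        ndi.gaussian_filter(ref[z], sigma=smooth_sigma_vox, output=sm[z])
    if np.ptp(sm) == 0:
        raise ValueError("empty tissue mask: reference channel is constant")
    # 3-class Otsu on log intensities: dark mountant / autofluorescent
    # tissue / bright stain.  The lowest cut separates tissue from outside;
    # a plain 2-class Otsu on raw intensities would instead split stained
    # from unstained and clear away the stroma.  Log scaling is what makes
    # the dim outside/tissue boundary visible next to the bright stain.
    lg = np.log1p(sm)
    try:
        from skimage.filters import threshold_multiotsu

        t = float(threshold_multiotsu(lg, classes=3)[0])
    except ValueError:
        t = float(threshold_otsu(lg))
    mask = lg >= t
    # mountant outside the tissue is orders of magnitude darker than tissue;
    # if the rejected class is not clearly darker there is no outside at all
    if mask.any() and not mask.all():
        below = float(lg[~mask].mean())
        above = float(lg[mask].mean())
        if above - below < np.log(4.0):
            mask = np.ones_like(mask)
    if not mask.any():
        raise ValueError("empty tissue mask")
    selem = disk(close_radius_vox)
    r = close_radius_vox
    for z in range(mask.shape[0]):
        # pad before closing: zero padding would erode genuine tissue that
        # touches the image border
        padded = np.pad(mask[z], r, mode="edge")
        sl = ndi.binary_closing(padded, structure=selem)[r:-r, r:-r]
        mask[z] = ndi.binary_fill_holes(sl)
    lbl, n = ndi.label(mask)
    if n == 0:
        raise ValueError("empty tissue mask")
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        mask = lbl == (int(np.argmax(sizes)) + 1)
    return mask


def clear_background(
    volume: TumorVolume,
    reference_channel: str = "sum",
    close_radius_vox: int = 10,
    smooth_sigma_vox: float = 2.0,
) -> tuple[TumorVolume, np.ndarray]:
    """Zero all channels outside the stained-tissue mask."""
    mask = tissue_mask(volume, reference_channel, close_radius_vox, smooth_sigma_vox)
    data = volume.grid.data.copy()
    data[:, ~mask] = 0
    grid = VoxelGrid(data, volume.grid.spacing, list(volume.grid.channel_names))
    return (
        TumorVolume(
            grid=grid,
            section_boundaries=list(volume.section_boundaries),
            transforms=list(volume.transforms),
        ),
        mask,
    )


__all__ = ["register_sections", "fuse_volume", "clear_background", "tissue_mask"]
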