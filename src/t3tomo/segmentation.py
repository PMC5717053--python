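"""Marker segmentation: global thresholds, tubular vessel extraction,
membrane-labelled cell detection, and tumor-outline extraction.

All geometric parameters are physical (micrometres); the strongly
anisotropic voxel grid (6.25 um axial vs 1.78 um lateral by default) is
handled by computing derivatives and structuring elements in physical units.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.segmentation import watershed

from .core import LabelMask, TumorVolume, VoxelGrid


def _get_channel(volume, channel: str) -> tuple[np.ndarray, tuple]:
    grid: VoxelGrid = getattr(volume, "grid", volume)
    return grid.channel(channel).astype(np.float32), grid.spacing


# ---------------------------------------------------------------------------
# global thresholding

def threshold_channel(volume, channel: str, method_or_value="otsu") -> LabelMask:
    """Binary mask of a channel by global Otsu (over nonzero voxels) or a
    manual cutoff applied as ``>=``."""
    from .depthnorm import otsu_threshold

    grid = getattr(volume, "grid", volume)
    src_dtype = grid.channel(channel).dtype
    img, spacing = _get_channel(volume, channel)
    if isinstance(method_or_value, str):
        if method_or_value != "otsu":
            raise ValueError(f"unknown threshold method {method_or_value!r}")
        nz = img[img > 0]
        if nz.size == 0 or np.ptp(nz) == 0:
            mask = np.zeros(img.shape, dtype=bool)
            t = np.inf
        else:
            t = otsu_threshold(nz)
            mask = img >= t
        rule = f"otsu(nonzero)={t:.4g}"
    else:
        t = float(method_or_value)
        # reject cutoffs the pixel type cannot represent; a cutoff above the
        # observed maximum is legitimate and yields an empty mask
        hi = float(np.iinfo(src_dtype).max) if np.issubdtype(
            src_dtype, np.integer
        ) else np.inf
        if not np.isfinite(t) or t < 0 or t > hi:
            raise ValueError(
                f"manual cutoff {t} outside the representable intensity "
                f"range [0, {hi}]"
            )
        mask = img >= t
        rule = f"manual>={t:g}"
    return LabelMask(mask, source_channel=channel, rule=rule, spacing=spacing)


# ---------------------------------------------------------------------------
# vessels: multiscale Hessian vesselness with anisotropy-corrected derivatives

def _eigvals_sym3(h):
    """Eigenvalues of a field of symmetric 3x3 matrices, closed form.

    ``h`` maps (i, j) -> array.  Returns three arrays sorted by eigenvalue
    magnitude (|l1| <= |l2| <= |l3|).
    """
    a, b, c = h[(0, 0)], h[(1, 1)], h[(2, 2)]
    d, e, f = h[(0, 1)], h[(0, 2)], h[(1, 2)]
    q = (a + b + c) / 3.0
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * (d**2 + e**2 + f**2)
    p = np.sqrt(np.maximum(p2, 0.0) / 6.0)
    safe = p > 1e-12
    ps = np.where(safe, p, 1.0)
    ba, bb, bc = (a - q) / ps, (b - q) / ps, (c - q) / ps
    bd, be, bf = d / ps, e / ps, f / ps
    detB = (
        ba * (bb * bc - bf * bf)
        - bd * (bd * bc - bf * be)
        + be * (bd * bf - bb * be)
    )
    r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    l_hi = q + 2.0 * p * np.cos(phi)
    l_lo = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    l_mid = 3.0 * q - l_hi - l_lo
    l_hi = np.where(safe, l_hi, q)
    l_lo = np.where(safe, l_lo, q)
    l_mid = np.where(safe, l_mid, q)
    lam = np.stack([l_lo, l_mid, l_hi])
    order = np.argsort(np.abs(lam), axis=0)
    return tuple(np.take_along_axis(lam, order[i : i + 1], axis=0)[0] for i in range(3))


def vesselness(
    image: np.ndarray,
    spacing,
    sigmas_um,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> np.ndarray:
    """Frangi-style bright-tube likelihood, maximum over physical scales.

    The Hessian is computed with Gaussian derivatives whose widths are given
    in micrometres and converted per axis to voxels, and its entries are
    rescaled to um^-2, so tubes are detected by their physical radius
    regardless of grid anisotropy.
    """
    img = image.astype(np.float32)
    spacing = np.asarray(spacing, dtype=float)
    out = np.zeros(img.shape, dtype=np.float32)
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for sigma_um in sigmas_um:
        sig_vox = tuple(sigma_um / s for s in spacing)
        h = {}
        for i, j in pairs:
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            h[(i, j)] = (
                ndi.gaussian_filter(img, sig_vox, order=tuple(order))
                * (sigma_um**2 / (spacing[i] * spacing[j]))
            ).astype(np.float32)
        l1, l2, l3 = _eigvals_sym3(h)
        del h
        tube = (l2 < 0) & (l3 < 0)
        eps = 1e-12
        ra2 = (l2 / (l3 + np.where(l3 == 0, eps, 0))) ** 2
        rb2 = l1**2 / np.abs(l2 * l3 + eps)
        s2 = l1**2 + l2**2 + l3**2
        c2 = max(float(s2.max()), eps) / 4.0
        v = (
            (1.0 - np.exp(-ra2 / (2 * alpha**2)))
            * np.exp(-rb2 / (2 * beta**2))
            * (1.0 - np.exp(-s2 / (2 * c2)))
        )
        v = np.where(tube, v, 0.0).astype(np.float32)
        np.maximum(out, v, out=out)
    return out


def extract_vessels(
    volume,
    vessel_channel: str,
    radius_range_um: tuple[float, float],
    n_scales: int = 3,
    low: float = 0.07,
    high: float = 0.25,
    min_component_volume_um3: float = 2000.0,
) -> LabelMask:
    """Segment and label tubular structures in the vessel channel.

    Multiscale vesselness over scales spanning ``radius_range_um``,
    hysteresis thresholding (``low``/``high`` relative to the vesselness
    maximum), small-component removal, connected-component labelling.  A
    per-label mean radius estimate (from the anisotropic distance transform)
    is attached to the returned mask as ``.radii_um``.
    """
    img, spacing = _get_channel(volume, vessel_channel)
    rmin, rmax = float(radius_range_um[0]), float(radius_range_um[1])
    if not 0 < rmin < rmax:
        raise ValueError("radius range must be positive with min < max")
    if rmin < min(spacing):
        raise ValueError(
            f"minimum radius {rmin} um is finer than the voxel spacing "
            f"{min(spacing)} um; try radius_range_um=({min(spacing):.2f}, {rmax})"
        )
    sigmas = np.geomspace(0.6 * rmin, 0.6 * rmax, n_scales)
    v = vesselness(img, spacing, sigmas)
    vmax = float(v.max())
    voxel_um3 = float(np.prod(spacing))
    if vmax <= 0:
        return LabelMask(
            np.zeros(img.shape, dtype=np.int16),
            source_channel=vessel_channel,
            rule="vesselness: empty",
            spacing=spacing,
        )
    mask = apply_hysteresis_threshold(v, low * vmax, high * vmax)
    lbl, n = ndi.label(mask, structure=ndi.generate_binary_structure(3, 2))
    if n:
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * voxel_um3 >= min_component_volume_um3) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, len(keep) + 1)
        lbl = relabel[lbl]
    radii = []
    if lbl.max():
        edt = ndi.distance_transform_edt(lbl > 0, sampling=spacing)
        for v_id in range(1, int(lbl.max()) + 1):
            vals = edt[lbl == v_id]
            radii.append(float(np.percentile(vals, 95)) if vals.size else 0.0)
    out = LabelMask(
        lbl.astype(np.int32),
        source_channel=vessel_channel,
        rule=(
            f"vesselness scales={np.round(sigmas, 2).tolist()} um, "
            f"hysteresis=({low},{high})xmax, min_vol={min_component_volume_um3} um3"
        ),
        spacing=spacing,
    )
    out.radii_um = radii
    return out


# ---------------------------------------------------------------------------
# membrane-labelled cells

def _fill_2d(comp: np.ndarray) -> np.ndarray:
    """Hole filling applied slice by slice: robust to shells that are open
    along z (coarse axial sampling and the axial PSF dim the polar caps of a
    membrane ring, so a 3D fill would often leak)."""
    out = np.empty_like(comp)
    for z in range(comp.shape[0]):
        out[z] = ndi.binary_fill_holes(comp[z])
    return out


def _hollowness_score(comp: np.ndarray) -> float:
    """Largest per-slice interior fraction of a component.

    A membrane ring shows a dark enclosed interior on its equatorial slices;
    a solid blob fills every slice.  Scoring slice-wise (after a small
    closing that removes noise pinholes) avoids dilution by the polar cap
    slices, which have no interior even for a perfect shell.
    """
    best = 0.0
    se = np.ones((3, 3), dtype=bool)
    for z in range(comp.shape[0]):
        sl = ndi.binary_closing(comp[z], structure=se)
        filled = ndi.binary_fill_holes(sl)
        area = int(filled.sum())
        if area < 9:
            continue
        interior = int((filled & ~sl).sum())
        best = max(best, interior / area)
    return best


def _hollowness_filter(
    mask: np.ndarray,
    hollowness_min: float,
    min_voxels: int,
    intensity: np.ndarray | None = None,
    half_max: float = 0.5,
):
    """Keep only components with a hollow interior (rings / shells),
    dropping filled blobs.

    When ``intensity`` is given, each component is re-thresholded locally at
    ``half_max`` times its own peak (95th percentile) before scoring: the
    detection threshold sits near the background, where the blurred halo of
    a membrane shell is thick enough to seal its interior, whereas at
    half-maximum the shell thins back to its true geometry.
    """
    lbl, n = ndi.label(mask)
    kept_filled = np.zeros(mask.shape, dtype=bool)
    objects = ndi.find_objects(lbl)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = lbl[sl] == i
        if comp.sum() < min_voxels:
            continue
        if intensity is not None:
            local = intensity[sl]
            t = half_max * float(np.percentile(local[comp], 95))
            shape_mask = comp & (local >= t)
            if shape_mask.sum() < min_voxels:
                continue
        else:
            shape_mask = comp
        if _hollowness_score(shape_mask) >= hollowness_min:
            kept_filled[sl] |= _fill_2d(shape_mask)
    return kept_filled


def _split_and_measure(filled: np.ndarray, spacing, split_distance_um: float, min_voxels: int):
    """Watershed-split touching cells on the interior distance transform."""
    if not filled.any():
        return np.zeros(filled.shape, dtype=np.int32), np.zeros((0, 3))
    edt = ndi.distance_transform_edt(filled, sampling=spacing)
    # markers: connected cores deep inside each cell.  Touching cells pinch
    # the distance transform at their neck, so the cores stay separate;
    # using whole cores (not point maxima) avoids splitting one cell when
    # the anisotropic grid quantizes its distance plateau into several peaks.
    markers, n_mark = ndi.label(edt >= 0.55 * split_distance_um)
    if n_mark == 0:
        lbl, _ = ndi.label(filled)
    else:
        lbl = watershed(-edt, markers, mask=filled)
    # compact labels, drop slivers
    ids = [i for i in range(1, int(lbl.max()) + 1) if (lbl == i).sum() >= min_voxels]
    relabel = np.zeros(int(lbl.max()) + 1, dtype=np.int32)
    relabel[ids] = np.arange(1, len(ids) + 1)
    lbl = relabel[lbl]
    if lbl.max():
        coms = ndi.center_of_mass(lbl > 0, lbl, index=np.arange(1, int(lbl.max()) + 1))
        centroids = np.asarray(coms) * np.asarray(spacing)
    else:
        centroids = np.zeros((0, 3))
    return lbl, centroids


def _feature_stack(img: np.ndarray, spacing, sigmas_um=(1.5, 3.0, 6.0)):
    feats = [img]
    smoothed = []
    for s_um in sigmas_um:
        sig = tuple(s_um / sp for sp in spacing)
        sm = ndi.gaussian_filter(img, sig)
        smoothed.append(sm)
        feats.append(sm)
        gz, gy, gx = np.gradient(sm, *spacing)
        feats.append(np.sqrt(gz**2 + gy**2 + gx**2))
        feats.append(ndi.gaussian_laplace(img, sig))
    for a in range(len(smoothed) - 1):
        feats.append(smoothed[a] - smoothed[a + 1])
    return np.stack([f.astype(np.float32) for f in feats], axis=-1)


def segment_membrane_cells(
    volume,
    immune_channel: str,
    training_labels: np.ndarray | None = None,
    hollowness_min: float = 0.1,
    min_voxels: int = 30,
    split_distance_um: float = 9.0,
    background_k_sigma: float = 8.0,
    classifier_seed: int = 7,
):
    """Detect cells showing signal only on the membrane (hollow shells).

    With ``training_labels`` (sparse annotations: 1 = membrane, 2 = not
    membrane, 0 = unlabelled) a random-forest pixel classifier on a
    multiscale feature stack produces the foreground; otherwise (fallback
    mode) a global Otsu threshold does.  In both modes only components with a
    sufficiently hollow interior survive, touching cells are split by
    watershed on the interior distance transform, and centroids are returned
    in micrometres ``(z, y, x)``.

    Returns ``(LabelMask, centroids_um)``.
    """
    img, spacing = _get_channel(volume, immune_channel)
    sm = ndi.gaussian_filter(img, tuple(1.0 / s for s in spacing))
    if training_labels is not None:
        classes = np.unique(training_labels[training_labels > 0])
        if classes.size < 2:
            raise ValueError("training labels must contain both classes")
        from sklearn.ensemble import RandomForestClassifier

        feats = _feature_stack(img, spacing)
        sel = training_labels > 0
        clf = RandomForestClassifier(
            n_estimators=50, random_state=classifier_seed, n_jobs=1
        )
        clf.fit(feats[sel], training_labels[sel])
        prob = clf.predict_proba(feats.reshape(-1, feats.shape[-1]))
        membrane_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        fg = prob[:, membrane_col].reshape(img.shape) >= 0.5
        rule = f"rf(seed={classifier_seed}) prob>=0.5, hollowness>={hollowness_min}"
    else:
        # fallback: light smoothing, then a robust background threshold.
        # Membrane signal occupies well under 1% of the voxels, so any
        # histogram-partition threshold (Otsu and relatives) collapses into
        # the background mode; median + k*MAD of the nonzero voxels tracks
        # the background level and noise width instead.
        # slice-wise statistics: depth-gain correction rescales whole slices,
        # so the background level (and its noise width) varies with z
        fg = np.zeros(img.shape, dtype=bool)
        for z in range(sm.shape[0]):
            nz = sm[z][sm[z] > 0]
            if nz.size < 100 or np.ptp(nz) == 0:
                continue
            med = float(np.median(nz))
            mad = float(np.median(np.abs(nz - med)))
            if mad > 0:
                t = med + background_k_sigma * 1.4826 * mad
            else:
                t = float(threshold_otsu(nz))
            fg[z] = sm[z] >= t
        if not fg.any():
            empty = np.zeros(img.shape, dtype=np.int32)
            return (
                LabelMask(empty, immune_channel, "fallback: empty", spacing),
                np.zeros((0, 3)),
            )
        rule = (
            f"fallback per-slice bg+{background_k_sigma}sigma, "
            f"hollowness>={hollowness_min}"
        )
    kept = _hollowness_filter(fg, hollowness_min, min_voxels, intensity=sm)
    lbl, centroids = _split_and_measure(kept, spacing, split_distance_um, min_voxels)
    return (
        LabelMask(lbl, source_channel=immune_channel, rule=rule, spacing=spacing),
        centroids,
    )


# ---------------------------------------------------------------------------
# tumor outline

def _anisotropic_ball(radius_um: float, spacing) -> np.ndarray:
    r_vox = [max(1, int(round(radius_um / s))) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) * s for r, s in zip(r_vox, spacing)], indexing="ij"
    )
    d2 = sum(g**2 for g in grids)
    return d2 <= radius_um**2


def extract_tumor_outline(
    tumor_mask,
    closing_radius_um: float = 10.0,
    min_component_volume_um3: float = 10000.0,
    spacing=None,
) -> LabelMask:
    """Boundary voxel shell of the closed, hole-filled tumor mask.

    Closing uses a physical-radius ellipsoidal element; holes are filled per
    slice; components below ``min_component_volume_um3`` are dropped; the
    outline is the mask minus its 6-connected one-voxel erosion.
    """
    if isinstance(tumor_mask, LabelMask):
        mask = tumor_mask.binary()
        spacing = tumor_mask.spacing
        src = tumor_mask.source_channel
    else:
        if spacing is None:
            raise ValueError("spacing required for a bare array mask")
        mask = np.asarray(tumor_mask) > 0
        src = "mask"
    if not mask.any():
        raise ValueError("empty tumor mask")
    closed = ndi.binary_closing(
        mask, structure=_anisotropic_ball(closing_radius_um, spacing)
    )
    for z in range(closed.shape[0]):
        closed[z] = ndi.binary_fill_holes(closed[z])
    lbl, n = ndi.label(closed)
    voxel_um3 = float(np.prod(spacing))
    if n:
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * voxel_um3 >= min_component_volume_um3) + 1
        closed = np.isin(lbl, keep)
    if not closed.any():
        raise ValueError("no tumor component above the minimum volume")
    eroded = ndi.binary_erosion(
        closed, structure=ndi.generate_binary_structure(3, 1)
    )
    outline = closed & ~eroded
    out = LabelMask(
        outline,
        source_channel=src,
        rule=f"outline: close {closing_radius_um} um, fill, minvol "
        f"{min_component_volume_um3} um3, shell = mask - erosion",
        spacing=spacing,
    )
    out.filled_mask = closed
    return out


__all__ = [
    "threshold_channel",
    "vesselness",
    "extract_vessels",
    "segment_membrane_cells",
    "extract_tumor_outline",
]
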