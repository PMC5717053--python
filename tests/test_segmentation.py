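import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from t3tomo.core import VoxelGrid
from t3tomo.segmentation import (
    extract_tumor_outline,
    extract_vessels,
    segment_membrane_cells,
    threshold_channel,
)

ISO = (2.0, 2.0, 2.0)
ANISO = (6.25, 1.78, 1.78)


def _vol(data, spacing=ISO, name="ch"):
    return VoxelGrid(data[None].astype(np.float32), spacing, [name])


# ---------------------------------------------------------------------------
# thresholding

def test_otsu_matches_exhaustive_sweep_oracle():
    rng = np.random.default_rng(0)
    img = np.where(rng.random((6, 20, 20)) < 0.3, 200.0, 10.0)
    img += rng.normal(scale=3, size=img.shape)

    # oracle: exhaustive threshold sweep maximizing between-class variance
    vals = img[img > 0]
    candidates = np.unique(np.round(vals))
    best = (None, -1.0)
    for t in candidates:
        lo, hi = vals[vals < t], vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best[1]:
            best = (t, var)

    mask = threshold_channel(_vol(img), "ch", "otsu")
    oracle_mask = img >= best[0]
    agree = (mask.mask == oracle_mask).mean()
    assert agree > 0.999


def test_manual_cutoff_semantics():
    img = np.full((2, 4, 4), 100.0)
    vol = _vol(img)
    assert threshold_channel(vol, "ch", 150.0).mask.sum() == 0  # above constant
    assert threshold_channel(vol, "ch", 0.0).mask.all()  # cutoff 0 -> full
    assert threshold_channel(vol, "ch", 100.0).mask.all()


def test_cutoff_outside_representable_range_errors():
    data = np.full((1, 2, 4, 4), 100, np.uint8)
    vol = VoxelGrid(data, ISO, ["ch"])
    with pytest.raises(ValueError, match="range"):
        threshold_channel(vol, "ch", 300.0)
    with pytest.raises(ValueError, match="range"):
        threshold_channel(vol, "ch", -1.0)


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), t1=st.floats(1, 100), t2=st.floats(1, 100))
def test_threshold_monotonicity(seed, t1, t2):
    """Raising a manual cutoff never adds voxels."""
    rng = np.random.default_rng(seed)
    img = rng.random((3, 8, 8)) * 120
    vol = _vol(img)
    lo, hi = sorted((t1, t2))
    m_lo = threshold_channel(vol, "ch", lo).mask
    m_hi = threshold_channel(vol, "ch", hi).mask
    assert not (m_hi & ~m_lo).any()


# ---------------------------------------------------------------------------
# vessels

def _cylinder(shape, center_yx, radius, axis="x", value=200.0, bg=5.0):
    img = np.full(shape, bg, np.float32)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    if axis == "x":
        d2 = (zz - center_yx[0]) ** 2 + (yy - center_yx[1]) ** 2
    else:
        d2 = (zz - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2
    img[d2 <= radius**2] = value
    return img


def test_empty_channel_gives_empty_mask():
    mask = extract_vessels(_vol(np.zeros((8, 16, 16))), "ch", (4.0, 10.0))
    assert mask.mask.sum() == 0


def test_single_cylinder_segmented_as_one_component():
    img = _cylinder((24, 40, 60), (12, 20), radius=3)
    mask = extract_vessels(_vol(img), "ch", (4.0, 10.0))
    truth = img > 100
    inter = (mask.binary() & truth).sum()
    dice = 2 * inter / (mask.binary().sum() + truth.sum())
    assert dice >= 0.8
    assert mask.mask.max() == 1


def test_two_radii_ordered_correctly():
    img = np.maximum(
        _cylinder((40, 80, 80), (12, 20), radius=2),
        _cylinder((40, 80, 80), (28, 60), radius=6),
    )
    mask = extract_vessels(
        _vol(img), "ch", (3.0, 14.0), min_component_volume_um3=500.0
    )
    assert mask.mask.max() == 2
    # match labels to the two cylinders by position, then compare radii
    lbl_small = mask.mask[12, 20, 40]
    lbl_big = mask.mask[28, 60, 40]
    assert lbl_small != 0 and lbl_big != 0 and lbl_small != lbl_big
    assert mask.radii_um[lbl_big - 1] > mask.radii_um[lbl_small - 1]


def test_vesselness_rotation_covariance():
    img_x = _cylinder((40, 60, 60), (20, 30), radius=3, axis="x")
    img_y = _cylinder((40, 60, 60), (20, 30), radius=3, axis="y")
    m_x = extract_vessels(_vol(img_x), "ch", (4.0, 10.0)).binary()
    m_y = extract_vessels(_vol(img_y), "ch", (4.0, 10.0)).binary()
    rotated = np.swapaxes(m_y, 1, 2)  # 90 degree in-plane rotation
    dice = 2 * (m_x & rotated).sum() / (m_x.sum() + rotated.sum())
    assert dice >= 0.9


def test_scale_finer_than_spacing_errors():
    with pytest.raises(ValueError, match="spacing"):
        extract_vessels(_vol(np.zeros((4, 8, 8))), "ch", (0.5, 10.0))
    with pytest.raises(ValueError, match="radius"):
        extract_vessels(_vol(np.zeros((4, 8, 8))), "ch", (10.0, 4.0))


def test_phantom_vessels_recovered(small_pipeline):
    result, truth = small_pipeline
    n_det = int(result.vessel_labels.mask.max())
    assert n_det >= 1
    det = result.vessel_labels.binary()
    tru = truth.masks["vessels"] > 0
    h = min(det.shape[1], tru.shape[1])
    w = min(det.shape[2], tru.shape[2])
    inter = (det[:, :h, :w] & tru[:, :h, :w]).sum()
    assert inter / tru.sum() > 0.5  # majority of true vessel voxels found


# ---------------------------------------------------------------------------
# membrane cells

def _ring_scene(n_rings=25, n_blobs=8, seed=0, noise=2.0):
    """Rings (hollow shells) and filled blobs on a quiet background."""
    rng = np.random.default_rng(seed)
    shape = (28, 120, 120)
    img = np.full(shape, 6.0, np.float32)
    sp = np.asarray(ANISO)
    centers = []
    truth_rings = []
    while len(centers) < n_rings + n_blobs:
        c = np.array(
            [
                rng.uniform(15, shape[0] * sp[0] - 15),
                rng.uniform(15, shape[1] * sp[1] - 15),
                rng.uniform(15, shape[2] * sp[2] - 15),
            ]
        )
        if centers and min(np.linalg.norm(c - q) for q in centers) < 24:
            continue
        centers.append(c)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(np.float32)
    zz *= sp[0]; yy *= sp[1]; xx *= sp[2]
    for i, c in enumerate(centers):
        d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        if i < n_rings:
            img[(d <= 9.0) & (d >= 6.0)] = 200.0
            truth_rings.append(c)
        else:
            img[d <= 6.0] = 200.0
    img = ndi.gaussian_filter(img, tuple(1.8 / s for s in sp))
    img += rng.normal(scale=noise, size=shape).astype(np.float32)
    return img, np.asarray(truth_rings), centers[n_rings:]


def test_uniform_image_yields_no_detections():
    img = np.full((8, 32, 32), 5.0, np.float32)
    mask, cents = segment_membrane_cells(_vol(img, ANISO), "ch")
    assert len(cents) == 0
    assert mask.mask.sum() == 0


def test_rings_kept_blobs_rejected_fallback_mode():
    img, rings, blobs = _ring_scene()
    mask, cents = segment_membrane_cells(_vol(img, ANISO), "ch")
    from scipy.spatial import cKDTree

    d_ring, _ = cKDTree(cents).query(rings)
    detected_rings = (d_ring < 9.0).sum()
    assert detected_rings >= 0.9 * len(rings)
    if len(blobs):
        d_blob, _ = cKDTree(cents).query(np.asarray(blobs))
        rejected = (d_blob > 9.0).sum()
        assert rejected >= 0.9 * len(blobs)
    # detected count within +-10% of the number of rings
    assert abs(len(cents) - len(rings)) <= 0.1 * len(rings)


def test_trainable_mode_learns_membrane_signal():
    img, rings, _ = _ring_scene(n_rings=12, n_blobs=0, seed=3)
    # sparse annotations from the scene itself: bright voxels = membrane
    labels = np.zeros(img.shape, np.uint8)
    bright = img > 100
    dark = img < 20
    rng = np.random.default_rng(0)
    pick = rng.random(img.shape)
    labels[bright & (pick < 0.05)] = 1
    labels[dark & (pick < 0.002)] = 2
    mask, cents = segment_membrane_cells(
        _vol(img, ANISO), "ch", training_labels=labels
    )
    from scipy.spatial import cKDTree

    d_ring, _ = cKDTree(cents).query(rings)
    assert (d_ring < 9.0).sum() >= 0.75 * len(rings)


def test_single_class_training_labels_rejected():
    img = np.zeros((4, 16, 16), np.float32)
    labels = np.zeros(img.shape, np.uint8)
    labels[0, 0, 0] = 1
    with pytest.raises(ValueError, match="both classes"):
        segment_membrane_cells(_vol(img, ANISO), "ch", training_labels=labels)


def test_phantom_cell_recall_and_precision(small_pipeline):
    result, truth = small_pipeline
    from scipy.spatial import cKDTree

    det = result.immune_centroids_um
    d_truth, _ = cKDTree(det).query(truth.immune_centroids_um)
    assert (d_truth < 12).sum() >= 0.85 * truth.immune_count
    assert abs(len(det) - truth.immune_count) <= 0.15 * truth.immune_count


# ---------------------------------------------------------------------------
# tumor outline

def test_solid_ellipsoid_outline_equals_shell_oracle():
    zz, yy, xx = np.mgrid[:20, :40, :40].astype(float)
    mask = ((zz - 10) / 8) ** 2 + ((yy - 20) / 15) ** 2 + (
        (xx - 20) / 15
    ) ** 2 <= 1
    out = extract_tumor_outline(mask, closing_radius_um=4.0, spacing=ISO,
                                min_component_volume_um3=100.0)
    # closing barely perturbs a solid convex body
    dice = 2 * (out.filled_mask & mask).sum() / (out.filled_mask.sum() + mask.sum())
    assert dice > 0.99
    # oracle: set difference filled \ its 6-connected erosion
    eroded = ndi.binary_erosion(
        out.filled_mask, ndi.generate_binary_structure(3, 1)
    )
    np.testing.assert_array_equal(out.mask, out.filled_mask & ~eroded)


def test_internal_cavity_is_filled():
    mask = np.zeros((10, 30, 30), bool)
    mask[2:8, 5:25, 5:25] = True
    mask[4:6, 12:18, 12:18] = False  # cavity
    out = extract_tumor_outline(mask, closing_radius_um=4.0, spacing=ISO,
                                min_component_volume_um3=100.0)
    assert out.filled_mask[5, 15, 15]
    # one shell: outline voxels all touch the outside boundary region
    lbl, n = ndi.label(out.mask, ndi.generate_binary_structure(3, 2))
    assert n == 1


def test_small_components_are_dropped():
    mask = np.zeros((10, 40, 40), bool)
    mask[2:8, 5:25, 5:25] = True
    mask[4, 33, 33] = True  # speck
    out = extract_tumor_outline(mask, closing_radius_um=4.0, spacing=ISO,
                                min_component_volume_um3=200.0)
    assert not out.mask[4, 33, 33]
    assert out.mask.any()


def test_empty_mask_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        extract_tumor_outline(np.zeros((4, 8, 8), bool), spacing=ISO)
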