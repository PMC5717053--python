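import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t3tomo.core import LabelMask, VoxelGrid
from t3tomo.quantify import (
    core_periphery_partition,
    distance_profile,
    double_positive_fraction,
    intensity_line_profile,
    outline_distance_map,
    pdm_analysis,
    vessel_ligand_fraction,
)

from conftest import brute_force_outline_distance

ISO = (1.0, 1.0, 1.0)
ANISO = (6.25, 1.78, 1.78)


# ---------------------------------------------------------------------------
# double positivity

def test_subset_and_disjoint_masks():
    a = np.zeros((4, 8, 8), bool)
    a[1:3, 2:6, 2:6] = True
    b_sup = np.ones_like(a)
    pos, neg = double_positive_fraction(a, b_sup)
    assert (pos.fraction, neg.fraction) == (1.0, 0.0)
    pos, neg = double_positive_fraction(a, ~a)
    assert (pos.fraction, neg.fraction) == (0.0, 1.0)


def test_empty_mask_is_flagged():
    a = np.zeros((2, 4, 4), bool)
    pos, neg = double_positive_fraction(a, a)
    assert not pos.defined and math.isnan(pos.fraction)


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), mode=st.sampled_from(["voxel", "object"]))
def test_fractions_sum_to_one(seed, mode):
    rng = np.random.default_rng(seed)
    a = rng.random((4, 10, 10)) < 0.3
    b = rng.random((4, 10, 10)) < 0.5
    if not a.any():
        a[0, 0, 0] = True
    pos, neg = double_positive_fraction(a, b, mode=mode)
    assert pos.fraction + neg.fraction == pytest.approx(1.0)


def test_phantom_truth_fraction_recovered_from_masks(small_phantom):
    _, truth = small_phantom
    pos, _ = double_positive_fraction(truth.masks["tumor"], truth.masks["ligand"])
    assert pos.fraction == pytest.approx(0.43, abs=0.02)


def test_object_mode_counts_components():
    a = np.zeros((1, 10, 20), bool)
    a[0, 2:5, 2:6] = True   # fully covered by b
    a[0, 2:5, 12:16] = True  # uncovered
    b = np.zeros_like(a)
    b[0, :, :8] = True
    pos, neg = double_positive_fraction(a, b, mode="object")
    assert (pos.numerator, pos.denominator) == (1, 2)


# ---------------------------------------------------------------------------
# vessel positivity

def _vessel_scene():
    lbl = np.zeros((3, 20, 40), np.int16)
    lbl[1, 8:12, 2:18] = 1
    lbl[1, 8:12, 22:38] = 2
    mask = LabelMask(lbl, "cd31", "test", ANISO)
    sheath = np.zeros(lbl.shape, bool)
    sheath[1, 6:8, 2:18] = True  # hugs vessel 1 only
    return mask, sheath


def test_sheathed_vessel_detected_by_dilated_surface():
    mask, sheath = _vessel_scene()
    records, table = vessel_ligand_fraction(mask, sheath)
    assert len(table) == 2
    assert table.set_index("vessel_id")["positive"].to_dict() == {1: True, 2: False}
    pos = [r for r in records if r.measure.endswith("+_vessels")][0]
    assert pos.fraction == pytest.approx(0.5)


def test_empty_ligand_gives_zero_fraction():
    mask, _ = _vessel_scene()
    records, _ = vessel_ligand_fraction(mask, np.zeros(mask.mask.shape, bool))
    pos = [r for r in records if r.measure.endswith("+_vessels")][0]
    assert pos.fraction == 0.0


def test_all_sheathed_gives_one():
    mask, _ = _vessel_scene()
    records, _ = vessel_ligand_fraction(mask, np.ones(mask.mask.shape, bool))
    pos = [r for r in records if r.measure.endswith("+_vessels")][0]
    assert pos.fraction == 1.0


def test_no_vessels_is_an_error():
    empty = LabelMask(np.zeros((2, 4, 4), np.int16), "cd31", "t", ISO)
    with pytest.raises(ValueError, match="no vessel"):
        vessel_ligand_fraction(empty, np.zeros((2, 4, 4), bool))


# ---------------------------------------------------------------------------
# PDM / intensity correlation

def _volume_from_channels(a, b):
    data = np.stack([a, b]).astype(np.float32)
    return VoxelGrid(data, ISO, ["a", "b"])


def test_pdm_worked_example():
    """A = [1,2,3,4], B = [2,1,4,3]: brute-force covariance oracle gives
    PDM = +0.75 everywhere, r = 0.6, ICQ = +0.5."""
    a = np.array([1.0, 2, 3, 4]).reshape(1, 2, 2)
    b = np.array([2.0, 1, 4, 3]).reshape(1, 2, 2)
    # oracle recomputation
    da, db = a - a.mean(), b - b.mean()
    oracle_pdm = da * db
    oracle_r = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
    assert np.allclose(oracle_pdm, 0.75)
    assert oracle_r == pytest.approx(0.6)

    result = pdm_analysis(_volume_from_channels(a, b), "a", "b")
    np.testing.assert_allclose(result.pdm, oracle_pdm)
    assert result.pearson_r == pytest.approx(0.6)
    assert result.icq == pytest.approx(0.5)


def test_constant_channel_flags_r_but_computes_pdm():
    a = np.arange(8.0).reshape(2, 2, 2)
    b = np.full((2, 2, 2), 3.0)
    result = pdm_analysis(_volume_from_channels(a, b), "a", "b")
    assert np.all(result.pdm == 0)
    assert not result.r_defined


def test_identical_channels_are_perfectly_correlated():
    rng = np.random.default_rng(0)
    a = rng.random((3, 5, 5))
    result = pdm_analysis(_volume_from_channels(a, a), "a", "b")
    assert (result.pdm >= 0).all()
    assert result.pearson_r == pytest.approx(1.0)
    assert result.icq == pytest.approx(0.5)


@settings(derandomize=True, max_examples=25)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.1, 50),
    offset=st.floats(-100, 100),
)
def test_pdm_sum_equals_n_covariance_and_r_affine_invariant(seed, scale, offset):
    rng = np.random.default_rng(seed)
    a = rng.random((2, 6, 6)) * 10
    b = rng.random((2, 6, 6)) * 10
    mask = rng.random((2, 6, 6)) < 0.7
    if mask.sum() < 4:
        mask[:] = True
    res = pdm_analysis(_volume_from_channels(a, b), "a", "b", mask=mask)
    n = mask.sum()
    cov = np.cov(a[mask], b[mask], bias=True)[0, 1]
    assert res.pdm[mask].sum() == pytest.approx(n * cov, rel=1e-4, abs=1e-4)
    assert -1.0 <= res.pearson_r <= 1.0
    assert -0.5 <= res.icq <= 0.5
    res2 = pdm_analysis(
        _volume_from_channels(a * scale + offset, b), "a", "b", mask=mask
    )
    # float32 storage limits the attainable agreement
    assert res2.pearson_r == pytest.approx(res.pearson_r, abs=1e-5)


def test_empty_mask_is_an_error():
    a = np.zeros((1, 2, 2))
    with pytest.raises(ValueError, match="mask"):
        pdm_analysis(_volume_from_channels(a, a), "a", "b", mask=a > 1)


# ---------------------------------------------------------------------------
# line profiles

def test_constant_channel_gives_flat_profile():
    a = np.full((4, 10, 10), 7.0)
    vol = _volume_from_channels(a, a)
    prof = intensity_line_profile(vol, (0, 0, 0), (3, 9, 9), ["a"], 0.5)
    assert np.allclose(prof["a"], 7.0)
    assert prof["distance_um"].iloc[-1] <= np.linalg.norm([3, 9, 9])


def test_zero_length_line_gives_single_sample():
    a = np.arange(4 * 100.0).reshape(4, 10, 10)
    vol = _volume_from_channels(a, a)
    prof = intensity_line_profile(vol, (1, 5, 5), (1, 5, 5), ["a"])
    assert len(prof) == 1
    assert prof["a"].iloc[0] == pytest.approx(a[1, 5, 5])


def test_endpoints_outside_volume_rejected():
    a = np.zeros((4, 10, 10))
    vol = _volume_from_channels(a, a)
    with pytest.raises(ValueError, match="outside"):
        intensity_line_profile(vol, (0, 0, 0), (50, 5, 5))


def test_rim_peak_location(small_phantom_clean):
    """A profile across the ligand rim peaks at the rim's true centre."""
    _, truth = small_phantom_clean
    spec = truth.spec
    clean = truth.volume_clean
    grid = VoxelGrid(clean, spec.spacing, spec.channel_names)
    center = np.array(spec.shape) * np.array(spec.spacing) / 2
    b = spec.tumor_semiaxes_um[1]
    start = center.copy()
    end = center + np.array([0.0, b + 30.0, 0.0])
    prof = intensity_line_profile(grid, start, end, ["pdl1"], 0.5)
    vals = prof["pdl1"].to_numpy()
    half = (vals.max() + vals.min()) / 2
    above = np.flatnonzero(vals >= half)
    peak_at = prof["distance_um"].iloc[[above[0], above[-1]]].mean()
    expected = b - truth.rim_thickness_um / 2
    assert peak_at == pytest.approx(expected, abs=2.0)


# ---------------------------------------------------------------------------
# distance profiles

def test_cell_on_outline_voxel_has_zero_distance():
    outline = np.zeros((8, 8, 8), bool)
    outline[4, 4, 4] = True
    prof = distance_profile(np.array([[4.0, 4.0, 4.0]]), outline, spacing=ISO)
    assert prof.distances_um[0] == 0.0


def test_three_four_five_triangle():
    outline = np.zeros((8, 8, 8), bool)
    outline[0, 0, 0] = True
    prof = distance_profile(np.array([[0.0, 3.0, 4.0]]), outline, spacing=ISO)
    assert prof.distances_um[0] == pytest.approx(5.0, abs=1e-9)


def test_one_slice_displacement_is_one_z_spacing():
    outline = np.zeros((8, 16, 16), bool)
    outline[3, :, :] = True
    cell = np.array([[4 * 6.25, 8 * 1.78, 8 * 1.78]])
    prof = distance_profile(cell, outline, spacing=ANISO)
    assert prof.distances_um[0] == pytest.approx(6.25, abs=1e-9)


@pytest.mark.parametrize("spacing", [ISO, ANISO])
def test_distance_map_matches_brute_force(spacing):
    rng = np.random.default_rng(7)
    outline = rng.random((12, 14, 10)) < 0.02
    outline[5, 7, 3] = True  # guarantee nonempty
    dmap = outline_distance_map(outline, spacing=spacing)
    for _ in range(25):
        p = tuple(rng.integers(s) for s in outline.shape)
        assert dmap[p] == pytest.approx(
            brute_force_outline_distance(outline, spacing, p), abs=1e-6
        )


def test_stromal_cells_are_flagged_separately():
    outline = np.zeros((6, 10, 10), bool)
    outline[2:4, 3, 3:7] = True
    inside = np.zeros_like(outline)
    inside[2:4, 3:7, 3:7] = True
    cells = np.array([[2.0, 5.0, 5.0], [2.0, 0.0, 0.0]])
    prof = distance_profile(cells, outline, spacing=ISO, inside_mask=inside)
    assert prof.inside_count == 1
    assert len(prof.stromal_distances_um) == 1
    assert prof.total_count == 2
    assert prof.counts.sum() == prof.inside_count


def test_no_centroids_gives_empty_profile():
    outline = np.zeros((4, 4, 4), bool)
    outline[1, 1, 1] = True
    prof = distance_profile(np.zeros((0, 3)), outline, spacing=ISO)
    assert prof.total_count == 0


# ---------------------------------------------------------------------------
# core / periphery partition

def test_spherical_shell_volume_fraction():
    """Sphere r=50 um, depth 10 um: periphery fraction = 1-(40/50)^3."""
    n, h = 214, 0.5  # 0.5 um grid so the outline shell is thin
    ax = (np.arange(n) - (n - 1) / 2) * h
    r = np.sqrt(
        ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    )
    tumor = r <= 50.0
    outline = tumor & (r > 50.0 - h)
    region = core_periphery_partition(
        tumor, outline, spacing=(h, h, h), depth_um=10.0
    )
    frac = (region.mask == 1).sum() / tumor.sum()
    assert frac == pytest.approx(1 - 0.8**3, abs=0.03)


def test_huge_depth_makes_everything_periphery():
    tumor = np.zeros((6, 10, 10), bool)
    tumor[2:4, 3:7, 3:7] = True
    outline = tumor.copy()
    with pytest.warns(UserWarning, match="core is empty"):
        region = core_periphery_partition(tumor, outline, spacing=ISO, depth_um=1e6)
    assert set(np.unique(region.mask)) == {0, 1}


def test_partition_labels_cover_tumor(small_phantom):
    _, truth = small_phantom
    tumor = truth.masks["tumor"]
    outline = truth.masks["outline"]
    region = core_periphery_partition(
        tumor, outline, spacing=truth.spec.spacing, depth_um=60.0
    )
    assert ((region.mask > 0) == tumor).all()
    assert (region.mask == 2).any()  # a real core exists at this depth
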