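import numpy as np
import pytest

from t3tomo.phantom import PhantomSpec, generate_phantom
from t3tomo.pipeline import analyze_sections


def small_spec(**overrides) -> PhantomSpec:
    """A fast two-section phantom used across the suite."""
    kw = dict(
        shape=(63, 160, 160),
        tumor_semiaxes_um=(160.0, 110.0, 110.0),
        n_sections=2,
        n_vessels_core=4,
        n_vessels_peripheral=4,
        n_immune_cells=40,
        n_distractor_blobs=8,
        n_puncta=60,
        core_depth_um=60.0,
        seed=1,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_phantom_clean():
    """Noise-free, single-section, untiled variant for oracle comparisons."""
    spec = small_spec(
        n_sections=1,
        tile_rows=1,
        tile_cols=1,
        tile_jitter_vox=0,
        poisson_scale=0.0,
        read_noise_sd=0.0,
        max_shift_vox=0.0,
        max_rotation_deg=0.0,
        seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_pipeline(small_phantom):
    sections, truth = small_phantom
    result = analyze_sections(
        sections, params={"quantify": {"core_depth_um": 60.0}}
    )
    return result, truth


@pytest.fixture(scope="session")
def reference_phantom():
    """The package's reference study condition (3 sections, 2x2 tiles)."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def reference_pipeline(reference_phantom):
    sections, truth = reference_phantom
    return analyze_sections(sections), truth


def brute_force_outline_distance(outline: np.ndarray, spacing, point_vox):
    """Exhaustive nearest-outline-voxel distance in um (test oracle)."""
    pts = np.argwhere(outline).astype(float)
    d = (pts - np.asarray(point_vox, dtype=float)) * np.asarray(spacing)
    return float(np.sqrt((d**2).sum(axis=1)).min())
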