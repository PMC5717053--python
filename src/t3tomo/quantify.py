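"""Spatial quantification of the fused tumor volume.

Implements the downstream measurements: double-positive fractions (voxel and
object mode), per-vessel ligand positivity (overall and by region),
intensity-correlation analysis (voxelwise product of the differences from
the mean, Pearson r, intensity correlation quotient), intensity line
profiles, anisotropic distance-to-margin profiling of cell centroids, and
core/periphery partitioning of the tumor by distance from its outline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .core import LabelMask, QuantRecord


def _binary(mask) -> tuple[np.ndarray, tuple | None]:
    if isinstance(mask, LabelMask):
        return mask.binary(), mask.spacing
    return np.asarray(mask) > 0, None


# ---------------------------------------------------------------------------
# double positivity

def double_positive_fraction(
    mask_a,
    mask_b,
    mode: str = "voxel",
    name_a: str = "A",
    name_b: str = "B",
    object_positive_fraction: float = 0.5,
) -> tuple[QuantRecord, QuantRecord]:
    """Fractions of marker-A-positive signal that is / is not B-positive.

    ``voxel`` mode counts voxels of ``A & B`` against ``A``; ``object`` mode
    counts connected components of A positive when at least
    ``object_positive_fraction`` of their voxels lie in B.  The two returned
    records (A+B+ and A+B-) sum to 1 whenever A is nonempty; an empty A
    yields flagged records with denominator 0.
    """
    a, _ = _binary(mask_a)
    b, _ = _binary(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    pos_name = f"{name_a}+{name_b}+"
    neg_name = f"{name_a}+{name_b}-"
    if mode == "voxel":
        den = int(a.sum())
        num = int((a & b).sum())
    elif mode == "object":
        lbl, n = ndi.label(a)
        den = n
        num = 0
        for sl, i in zip(ndi.find_objects(lbl), range(1, n + 1)):
            comp = lbl[sl] == i
            if b[sl][comp].mean() >= object_positive_fraction:
                num += 1
    else:
        raise ValueError(f"mode must be 'voxel' or 'object', got {mode!r}")
    return (
        QuantRecord(pos_name, num, den),
        QuantRecord(neg_name, den - num, den),
    )


def vessel_ligand_fraction(
    vessel_labels: LabelMask,
    ligand_mask,
    region_mask: np.ndarray | None = None,
    dilation_vox_inplane: int = 2,
    min_shell_overlap: float = 0.1,
    region_names: dict[int, str] | None = None,
) -> tuple[list[QuantRecord], pd.DataFrame]:
    """Per-vessel ligand positivity by dilated-surface overlap.

    A vessel is positive when at least ``min_shell_overlap`` of the shell
    obtained by dilating it ``dilation_vox_inplane`` voxels in-plane (the
    perivascular compartment, where ligand sits between the endothelium and
    the smooth-muscle layer) overlaps the ligand mask.  Returns positive /
    negative QuantRecords overall and per region (region 0 is reported as
    ``stroma``), plus a per-vessel table.
    """
    if not isinstance(vessel_labels, LabelMask) or vessel_labels.is_binary:
        raise ValueError("vessel_labels must be a labelled LabelMask")
    lbl = vessel_labels.mask
    n = int(lbl.max())
    if n == 0:
        raise ValueError("no vessel labels")
    lig, _ = _binary(ligand_mask)
    region_names = region_names or {0: "stroma", 1: "periphery", 2: "core"}
    r = int(dilation_vox_inplane)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    struct = ((yy**2 + xx**2) <= r**2)[None]
    rows = []
    objects = ndi.find_objects(lbl)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = tuple(
            slice(max(0, s.start - r - 1), min(dim, s.stop + r + 1))
            for s, dim in zip(sl, lbl.shape)
        )
        comp = lbl[pad] == i
        shell = ndi.binary_dilation(comp, structure=struct) & ~(lbl[pad] > 0)
        shell_n = int(shell.sum())
        overlap = float(lig[pad][shell].mean()) if shell_n else 0.0
        if region_mask is not None:
            vals = region_mask[pad][comp]
            region = region_names.get(int(np.bincount(vals).argmax()), "stroma")
        else:
            region = "whole"
        rows.append(
            {
                "vessel_id": i,
                "region": region,
                "shell_overlap": overlap,
                "positive": overlap >= min_shell_overlap,
                "voxels": int(comp.sum()),
            }
        )
    table = pd.DataFrame(rows)
    records = []
    groups = [("whole", table)]
    if region_mask is not None:
        groups += [(reg, g) for reg, g in table.groupby("region")]
    for reg, g in groups:
        pos = int(g["positive"].sum())
        records.append(QuantRecord("cd31+ligand+_vessels", pos, len(g), region=reg))
        records.append(
            QuantRecord("cd31+ligand-_vessels", len(g) - pos, len(g), region=reg)
        )
    return records, table


# ---------------------------------------------------------------------------
# intensity correlation (PDM)

@dataclass
class PDMMap:
    """Voxelwise product of the differences from the mean of two channels.

    ``pdm[i] = (A[i] - mean_A) * (B[i] - mean_B)`` over the analysis mask;
    positive values mark covarying (colocalized) signal, negative values
    mutually exclusive signal.  ``icq`` is the fraction of mask voxels with
    positive PDM minus 0.5 (range -0.5 .. +0.5); ``pearson_r`` is NaN
    (flagged) when either channel has zero variance over the mask.
    """

    pdm: np.ndarray
    channel_a: str
    channel_b: str
    mask: np.ndarray
    mean_a: float
    mean_b: float
    pearson_r: float
    icq: float
    #: symmetric signed scale for export/colormapping
    vmax: float = field(default=0.0)

    @property
    def r_defined(self) -> bool:
        return not math.isnan(self.pearson_r)


def pdm_analysis(volume, channel_a: str, channel_b: str, mask=None) -> PDMMap:
    """Intensity correlation analysis of two channels over a mask."""
    grid = getattr(volume, "grid", volume)
    a = grid.channel(channel_a).astype(np.float64)
    b = grid.channel(channel_b).astype(np.float64)
    if mask is None:
        m = np.ones(a.shape, dtype=bool)
    else:
        m, _ = _binary(mask)
    if not m.any():
        raise ValueError("analysis mask is empty")
    av = a[m]
    bv = b[m]
    mean_a = float(av.mean())
    mean_b = float(bv.mean())
    da = av - mean_a
    db = bv - mean_b
    pdm_vals = da * db
    pdm = np.zeros(a.shape, dtype=np.float32)
    pdm[m] = pdm_vals
    sa = float(np.sqrt((da * da).sum()))
    sb = float(np.sqrt((db * db).sum()))
    r = float((da * db).sum() / (sa * sb)) if sa > 0 and sb > 0 else math.nan
    icq = float((pdm_vals > 0).mean() - 0.5)
    return PDMMap(
        pdm=pdm,
        channel_a=channel_a,
        channel_b=channel_b,
        mask=m,
        mean_a=mean_a,
        mean_b=mean_b,
        pearson_r=r,
        icq=icq,
        vmax=float(np.abs(pdm_vals).max()) if pdm_vals.size else 0.0,
    )


# ---------------------------------------------------------------------------
# line profiles

def intensity_line_profile(
    volume,
    start_point_um,
    end_point_um,
    channels: list[str] | None = None,
    sampling_step_um: float = 2.0,
) -> pd.DataFrame:
    """Linearly interpolated intensities along a physical segment.

    Returns a DataFrame with ``distance_um`` and one column per channel.  A
    zero-length segment yields a single sample at the point.
    """
    grid = getattr(volume, "grid", volume)
    sp = np.asarray(grid.spacing)
    p0 = np.asarray(start_point_um, dtype=float)
    p1 = np.asarray(end_point_um, dtype=float)
    hi = (np.asarray(grid.shape_zyx) - 1) * sp
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > hi):
            raise ValueError(f"endpoint {p.tolist()} um outside the volume")
    length = float(np.linalg.norm(p1 - p0))
    n = max(1, int(math.floor(length / sampling_step_um)) + 1)
    t = np.linspace(0.0, 1.0, n) if length > 0 else np.array([0.0])
    pts_um = p0[None] + t[:, None] * (p1 - p0)[None]
    coords = (pts_um / sp).T  # (3, n) voxel coordinates
    out = {"distance_um": t * length}
    names = channels or list(grid.channel_names)
    for name in names:
        out[name] = ndi.map_coordinates(
            grid.channel(name).astype(np.float32), coords, order=1, mode="nearest"
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# distance-to-margin profiling

@dataclass
class DistanceProfile:
    """Per-cell distances from the tumor outline, measured inward, with a
    histogram; cells outside the tumor are binned separately as stromal."""

    distances_um: np.ndarray  # cells inside the tumor
    stromal_distances_um: np.ndarray  # cells outside, distance to the outline
    bin_width_um: float
    bin_edges_um: np.ndarray
    counts: np.ndarray

    @property
    def total_count(self) -> int:
        return int(self.distances_um.size + self.stromal_distances_um.size)

    @property
    def inside_count(self) -> int:
        return int(self.distances_um.size)

    @property
    def median_um(self) -> float:
        return float(np.median(self.distances_um)) if self.distances_um.size else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_um": self.bin_edges_um[:-1],
                "bin_end_um": self.bin_edges_um[1:],
                "count": self.counts,
            }
        )


def outline_distance_map(outline_mask, spacing=None) -> np.ndarray:
    """Anisotropic Euclidean distance of every voxel to the nearest outline
    voxel, in micrometres."""
    outline, sp = _binary(outline_mask)
    sp = sp or spacing
    if sp is None:
        raise ValueError("spacing required")
    if not outline.any():
        raise ValueError("empty outline")
    return ndi.distance_transform_edt(~outline, sampling=sp)


def distance_profile(
    cell_centroids_um: np.ndarray,
    outline_mask,
    spacing=None,
    bin_width_um: float = 25.0,
    inside_mask: np.ndarray | None = None,
) -> DistanceProfile:
    """Distance of each cell centroid from the tumor outline, inward.

    Centroids are in micrometre ``(z, y, x)`` coordinates.  Each cell is
    assigned the distance value of its containing voxel.  When
    ``inside_mask`` (the filled tumor mask) is given, cells outside it are
    flagged stromal and excluded from the histogram.
    """
    outline, sp = _binary(outline_mask)
    sp = sp or spacing
    if sp is None:
        raise ValueError("spacing required")
    dmap = outline_distance_map(outline, spacing=sp)
    cells = np.atleast_2d(np.asarray(cell_centroids_um, dtype=float))
    if cells.size == 0:
        edges = np.array([0.0, bin_width_um])
        return DistanceProfile(
            np.zeros(0), np.zeros(0), bin_width_um, edges, np.zeros(1, dtype=int)
        )
    vox = np.round(cells / np.asarray(sp)).astype(int)
    vox = np.clip(vox, 0, np.asarray(outline.shape) - 1)
    idx = tuple(vox.T)
    dist = dmap[idx]
    if inside_mask is not None:
        inside = np.asarray(inside_mask)[idx]
    else:
        inside = np.ones(len(cells), dtype=bool)
    d_in = dist[inside]
    d_out = dist[~inside]
    top = float(d_in.max()) if d_in.size else 0.0
    n_bins = max(1, int(math.ceil((top + 1e-9) / bin_width_um)))
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(d_in, bins=edges)
    return DistanceProfile(d_in, d_out, bin_width_um, edges, counts)


# ---------------------------------------------------------------------------
# core / periphery partition

def core_periphery_partition(
    tumor_mask,
    outline_mask,
    spacing=None,
    depth_um: float = 80.0,
) -> LabelMask:
    """Partition tumor voxels into periphery (1: within ``depth_um`` of the
    outline) and core (2: deeper).  If the depth exceeds the tumor radius the
    whole tumor is periphery (with a warning)."""
    import warnings

    if depth_um <= 0:
        raise ValueError("depth_um must be positive")
    tumor, sp = _binary(tumor_mask)
    if sp is None and isinstance(outline_mask, LabelMask):
        sp = outline_mask.spacing
    sp = sp or spacing
    if sp is None:
        raise ValueError("spacing required")
    dmap = outline_distance_map(outline_mask, spacing=sp)
    labels = np.zeros(tumor.shape, dtype=np.uint8)
    labels[tumor & (dmap <= depth_um)] = 1
    labels[tumor & (dmap > depth_um)] = 2
    if tumor.any() and not (labels == 2).any():
        warnings.warn(
            f"partition depth {depth_um} um exceeds the tumor radius: "
            "core is empty",
            stacklevel=2,
        )
    return LabelMask(
        labels,
        source_channel="tumor",
        rule=f"periphery<= {depth_um} um from outline; core beyond",
        spacing=sp,
    )


__all__ = [
    "double_positive_fraction",
    "vessel_ligand_fraction",
    "PDMMap",
    "pdm_analysis",
    "intensity_line_profile",
    "DistanceProfile",
    "distance_profile",
    "outline_distance_map",
    "core_periphery_partition",
]
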