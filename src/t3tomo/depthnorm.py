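"""Depth-dependent intensity normalization.

Deep optical slices of a cleared slab are dimmer than shallow ones because of
residual scattering and absorption.  Per channel, each slice's foreground
mean (voxels at or above the channel's Otsu threshold) is rescaled to the mean
of all foreground voxels of the whole slab, with the gain capped at 3x by
default — matching the per-slice constant-mean gain correction used for
cleared macrosection stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MacrosectionStack, VoxelGrid


@dataclass
class SliceGain:
    channel: str
    z: int
    foreground_mean: float
    gain: float
    clamped: bool
    flagged: bool  # too little foreground: gain forced to 1
    inherited: bool = False  # boundary slice: gain taken from a neighbour


def otsu_threshold(values: np.ndarray, nbins: int = 1024) -> float:
    """Otsu threshold returned as a bin EDGE, for use with ``>=``.

    ``skimage.filters.threshold_otsu`` returns the centre of the last
    background bin; any value sharing that bin (e.g. an exact background
    level) then lands on the foreground side of a ``>=`` comparison.
    Returning the upper edge of the winning background bin gives unambiguous
    ``foreground = values >= t`` semantics.
    """
    values = np.asarray(values).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    p = hist.astype(np.float64)
    total = p.sum()
    if total == 0:
        raise ValueError("empty input")
    p /= total
    centers = (edges[:-1] + edges[1:]) / 2
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    valid = (omega > 0) & (omega < 1)
    sigma_b = np.zeros_like(omega)
    sigma_b[valid] = (mu[-1] * omega[valid] - mu[valid]) ** 2 / (
        omega[valid] * (1 - omega[valid])
    )
    if not valid.any():
        raise ValueError("constant input has no threshold")
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def foreground_stats(
    stack: MacrosectionStack,
    min_foreground_voxels: int = 50,
    global_mean_all_voxels: bool = False,
):
    """Per-channel foreground statistics of a macrosection.

    Returns ``(global_means, slice_means, fg_masks)`` where ``global_means``
    maps channel name to the mean over all foreground voxels,
    ``slice_means[name]`` is an array of per-slice foreground means (NaN
    where foreground is too small), and ``fg_masks[name]`` the per-slice
    foreground masks.

    Foreground is defined by one Otsu threshold per channel computed over
    the whole stack and applied to every slice.  A slice-wise threshold
    would redefine "foreground" from slice to slice on sparse channels
    (background on empty slices, stained objects on occupied ones), which
    makes the gain series meaningless; one consistent cutoff keeps the
    per-slice means comparable across depth.
    """
    grid = stack.grid
    nz = grid.data.shape[1]
    global_means: dict[str, float] = {}
    slice_means: dict[str, np.ndarray] = {}
    fg_masks: dict[str, list[np.ndarray]] = {}
    for ci, name in enumerate(grid.channel_names):
        chan = grid.data[ci]
        t = None
        if np.ptp(chan) > 0:
            try:
                t = otsu_threshold(np.asarray(chan))
            except ValueError:
                pass
        masks = []
        means = np.full(nz, np.nan)
        for z in range(nz):
            sl = chan[z]
            fg = (
                sl >= t if t is not None else np.zeros(sl.shape, dtype=bool)
            )
            masks.append(fg)
            if fg.sum() >= min_foreground_voxels:
                means[z] = float(sl[fg].mean())
        if global_mean_all_voxels:
            big_m = float(chan.mean())
        else:
            tot = sums = 0.0
            for z in range(nz):
                if not np.isnan(means[z]):
                    n = masks[z].sum()
                    sums += means[z] * n
                    tot += n
            big_m = sums / tot if tot else np.nan
        global_means[name] = big_m
        slice_means[name] = means
        fg_masks[name] = masks
    return global_means, slice_means, fg_masks


def normalize_depth(
    stack: MacrosectionStack,
    max_gain: float = 3.0,
    min_foreground_voxels: int = 50,
    global_mean_all_voxels: bool = False,
    target_mean: dict[str, float] | None = None,
    boundary_slices: tuple[int, ...] = (),
) -> tuple[MacrosectionStack, list[SliceGain]]:
    """Equalize per-slice foreground means across depth, channel by channel.

    For each channel: the channel's global Otsu threshold defines the
    foreground of every slice;
    ``m_z`` is the slice's foreground mean and ``M`` the mean over the
    foreground voxels of all slices (or over all voxels when
    ``global_mean_all_voxels``).  Each slice is multiplied by
    ``g_z = clamp(M / m_z, 1/max_gain, max_gain)``.  Slices with fewer than
    ``min_foreground_voxels`` above threshold keep ``g_z = 1`` and are
    flagged.  Returns the normalized stack (float32) and the per-slice gain
    audit trail.

    ``target_mean`` (channel name -> value) replaces each channel's own
    global mean as the normalization target; a multi-slab reconstruction
    passes a shared target so serial sections land on a common intensity
    scale.

    ``boundary_slices`` marks cut-face slices whose foreground mean is
    corrupted by sectioning loss: they inherit the gain of the nearest
    interior slice (compensating attenuation without re-amplifying the cut
    loss, which the boundary-summation step of fusion restores instead).
    """
    if max_gain < 1:
        raise ValueError("max_gain must be >= 1")
    grid = stack.grid
    data = grid.data.astype(np.float32, copy=True)
    gains: list[SliceGain] = []
    nz = data.shape[1]
    global_means, slice_means, _ = foreground_stats(
        stack, min_foreground_voxels, global_mean_all_voxels
    )
    for ci, name in enumerate(grid.channel_names):
        chan = data[ci]
        means = slice_means[name]
        big_m = global_means[name]
        if target_mean is not None and name in target_mean:
            big_m = target_mean[name]
        slice_gains: dict[int, SliceGain] = {}
        for z in range(nz):
            if z in boundary_slices:
                continue
            if np.isnan(means[z]) or np.isnan(big_m) or means[z] <= 0:
                slice_gains[z] = SliceGain(name, z, means[z], 1.0, False, True)
                continue
            raw = big_m / means[z]
            g = float(np.clip(raw, 1.0 / max_gain, max_gain))
            chan[z] *= g
            slice_gains[z] = SliceGain(name, z, means[z], g, g != raw, False)
        for z in boundary_slices:
            interior = [
                q for q in slice_gains
                if not slice_gains[q].flagged
            ]
            if interior:
                src = min(interior, key=lambda q: abs(q - z))
                g = slice_gains[src].gain
            else:
                g = 1.0
            chan[z] *= g
            slice_gains[z] = SliceGain(
                name, z, means[z] if z < nz else np.nan, g, False, False,
                inherited=True,
            )
        gains.extend(slice_gains[z] for z in sorted(slice_gains))
    out = MacrosectionStack(
        grid=VoxelGrid(data, grid.spacing, list(grid.channel_names)),
        section_index=stack.section_index,
        nominal_thickness_um=stack.nominal_thickness_um,
    )
    return out, gains


def gains_to_frame(gains: list[SliceGain]) -> pd.DataFrame:
    """Gain audit trail as a DataFrame ready for CSV export."""
    return pd.DataFrame(
        [
            {
                "channel": g.channel,
                "z": g.z,
                "foreground_mean": g.foreground_mean,
                "gain": g.gain,
                "clamped": g.clamped,
                "flagged": g.flagged,
                "inherited": g.inherited,
            }
            for g in gains
        ]
    )


__all__ = ["normalize_depth", "SliceGain", "gains_to_frame"]
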