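"""Core domain types shared by every pipeline stage.

Conventions
-----------
* Volumes are channel-major 4D arrays with axis order ``(channel, z, y, x)``;
  coordinates are 0-based voxel indices, ``z`` increases with imaging depth.
* Physical voxel spacing is ``(z, y, x)`` in micrometres.  All distances
  reported by the package are in micrometres, never in voxels, because the
  default grid is strongly anisotropic (6.25 um axially vs 1.78 um laterally).
* Intensities are stored as unsigned integers on disk and processed as
  floating point internally; casting back to the input integer type happens
  only on write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

#: 10x confocal acquisition grid of the original protocol, (z, y, x) in um.
DEFAULT_SPACING = (6.25, 1.78, 1.78)

#: Nominal vibratome slab thickness in um.
DEFAULT_SECTION_THICKNESS_UM = 400.0


def _as_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (z, y, x), got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing values must be positive, got {spacing!r}")
    return spacing


@dataclass
class VoxelGrid:
    """A multi-channel 3D voxel grid with physical spacing.

    Parameters
    ----------
    data : ndarray
        Array of shape ``(channel, z, y, x)``.
    spacing : tuple of float
        Physical voxel size ``(z, y, x)`` in micrometres.
    channel_names : list of str
        Ordered marker labels, one per channel.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4D (channel, z, y, x), got {self.data.ndim}D"
            )
        self.spacing = _as_spacing(self.spacing)
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def channel_sum(self) -> np.ndarray:
        """Sum of all channels as float32 (the default registration image)."""
        return self.data.sum(axis=0, dtype=np.float32)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.spacing, list(self.channel_names))


@dataclass
class MacrosectionStack:
    """One cleared tissue slab imaged as a single multi-channel z-stack."""

    grid: VoxelGrid
    section_index: int = 0
    nominal_thickness_um: float = DEFAULT_SECTION_THICKNESS_UM

    def __post_init__(self) -> None:
        if self.section_index < 0:
            raise ValueError("section_index must be >= 0")
        if self.nominal_thickness_um <= 0:
            raise ValueError("nominal_thickness_um must be positive")


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: rotation about the image centre, then translation.

    The forward map acts on ``(y, x)`` points as
    ``p' = R(theta) (p - c) + c + (dy, dx)`` where ``c`` is the image centre.
    Translations are in voxels and may be fractional; ``theta_deg`` is
    counter-clockwise in array coordinates.
    """

    dy: float = 0.0
    dx: float = 0.0
    theta_deg: float = 0.0
    score: float = math.nan

    def matrix(self) -> np.ndarray:
        t = math.radians(self.theta_deg)
        return np.array(
            [[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]]
        )

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``other`` first, then self."""
        r = self.matrix()
        t = r @ np.array([other.dy, other.dx]) + np.array([self.dy, self.dx])
        return RigidTransform2D(
            dy=float(t[0]), dx=float(t[1]), theta_deg=self.theta_deg + other.theta_deg
        )

    def inverse(self) -> "RigidTransform2D":
        rinv = self.matrix().T
        t = -rinv @ np.array([self.dy, self.dx])
        return RigidTransform2D(
            dy=float(t[0]), dx=float(t[1]), theta_deg=-self.theta_deg
        )

    def is_identity(self, tol: float = 1e-6) -> bool:
        return (
            abs(self.dy) <= tol
            and abs(self.dx) <= tol
            and abs(self.theta_deg) <= tol
        )

    def apply(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Apply the transform to the trailing (y, x) axes of ``image``.

        Uses linear interpolation by default; pass ``order=0`` for label
        images.  Works on 2D slices, 3D stacks and 4D channel stacks alike.
        """
        if self.is_identity():
            return image.copy()
        yx = image.shape[-2:]
        c = np.array([(yx[0] - 1) / 2.0, (yx[1] - 1) / 2.0])
        rinv = self.matrix().T
        # output(p) = input(T^-1 p);  T^-1 p = Rinv p - Rinv (c + t) + c
        offset = c - rinv @ (c + np.array([self.dy, self.dx]))
        flat = image.reshape((-1,) + yx)
        out = np.empty_like(flat, dtype=np.float32 if order > 0 else flat.dtype)
        for i in range(flat.shape[0]):
            out[i] = ndi.affine_transform(
                flat[i].astype(out.dtype, copy=False),
                rinv,
                offset=offset,
                order=order,
                mode="constant",
                cval=cval,
            )
        return out.reshape(image.shape)

    def apply_to_points(self, points_yx: np.ndarray, shape_yx: Sequence[int]) -> np.ndarray:
        """Forward-map (y, x) voxel coordinates through the transform."""
        pts = np.atleast_2d(np.asarray(points_yx, dtype=float))
        c = np.array([(shape_yx[0] - 1) / 2.0, (shape_yx[1] - 1) / 2.0])
        out = (self.matrix() @ (pts - c).T).T + c + np.array([self.dy, self.dx])
        return out.reshape(np.asarray(points_yx, dtype=float).shape)

    def to_dict(self) -> dict:
        return {
            "dy": self.dy,
            "dx": self.dx,
            "theta_deg": self.theta_deg,
            "score": None if math.isnan(self.score) else self.score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        score = d.get("score")
        return cls(
            dy=float(d["dy"]),
            dx=float(d["dx"]),
            theta_deg=float(d["theta_deg"]),
            score=math.nan if score is None else float(score),
        )

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)


@dataclass
class TumorVolume:
    """Fused whole-tumor volume with section bookkeeping."""

    grid: VoxelGrid
    section_boundaries: list[int] = field(default_factory=list)
    transforms: list[RigidTransform2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.section_boundaries = sorted(int(z) for z in self.section_boundaries)
        depth = self.grid.shape_zyx[0]
        for z in self.section_boundaries:
            if not 0 <= z < depth:
                raise ValueError(f"section boundary z={z} outside depth {depth}")


@dataclass
class LabelMask:
    """Binary or labelled voxel mask tied to the channel and rule that made it."""

    mask: np.ndarray
    source_channel: str
    rule: str
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if self.mask.dtype != bool and not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("mask must be boolean or integer-labelled")
        if self.mask.dtype != bool and self.mask.size and self.mask.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.spacing = _as_spacing(self.spacing)

    @property
    def is_binary(self) -> bool:
        return self.mask.dtype == bool

    def binary(self) -> np.ndarray:
        return self.mask if self.is_binary else self.mask > 0

    @property
    def n_labels(self) -> int:
        return int(self.mask.max()) if not self.is_binary and self.mask.size else int(self.binary().any())


@dataclass
class QuantRecord:
    """One quantification result expressed as a fraction of a denominator."""

    measure: str
    numerator: float
    denominator: float
    region: str = "whole"

    @property
    def fraction(self) -> float:
        """numerator/denominator, or NaN (undefined) when the denominator is 0."""
        if self.denominator > 0:
            return self.numerator / self.denominator
        return math.nan

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "fraction": self.fraction,
            "region": self.region,
            "defined": self.defined,
        }


def records_to_frame(records: Sequence[QuantRecord]):
    """QuantRecords as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in records])


__all__ = [
    "DEFAULT_SPACING",
    "DEFAULT_SECTION_THICKNESS_UM",
    "VoxelGrid",
    "MacrosectionStack",
    "RigidTransform2D",
    "TumorVolume",
    "LabelMask",
    "QuantRecord",
    "records_to_frame",
    "replace",
]
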