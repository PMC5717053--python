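"""Reading and writing multi-channel volumes as OME-TIFF with a JSON sidecar.

Stacks are written as uncompressed OME-TIFF in ``CZYX`` order so that voxel
data round-trips bit-exactly for 8- and 16-bit input.  Spacing and channel
names are stored both in the OME metadata and in a ``<stem>.json`` sidecar;
on read, explicit arguments override the sidecar, which overrides embedded
metadata.  Missing spacing or channel names is an error — downstream stages
never assume defaults silently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .core import MacrosectionStack, TumorVolume, VoxelGrid


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix == "" else Path(
        str(path)[: -len(path.suffix)] + ".json"
    )


def write_stack(stack, path) -> Path:
    """Write a :class:`MacrosectionStack`, :class:`TumorVolume` or
    :class:`VoxelGrid` to ``path`` as OME-TIFF plus a JSON sidecar.

    Integer input is written at its native bit depth (no silent downcast);
    floating-point data is written as float32.
    """
    grid: VoxelGrid = getattr(stack, "grid", stack)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = grid.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    sz, sy, sx = grid.spacing
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": sy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": sx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(grid.channel_names)},
        },
    )
    sidecar = {
        "spacing_um_zyx": list(grid.spacing),
        "channel_names": list(grid.channel_names),
    }
    if hasattr(stack, "section_index"):
        sidecar["section_index"] = stack.section_index
    if hasattr(stack, "section_boundaries"):
        sidecar["section_boundaries"] = list(stack.section_boundaries)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _metadata_from_tiff(tif: tifffile.TiffFile):
    """Best-effort (spacing, channel_names) from embedded OME metadata."""
    spacing = None
    names = None
    if tif.ome_metadata:
        try:
            from xml.etree import ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                z = px.get("PhysicalSizeZ")
                y = px.get("PhysicalSizeY")
                x = px.get("PhysicalSizeX")
                if z and y and x:
                    spacing = (float(z), float(y), float(x))
                ch = [c.get("Name") for c in px.findall("ome:Channel", ns)]
                if ch and all(ch):
                    names = ch
        except Exception:
            pass
    return spacing, names


def read_stack(
    path,
    spacing: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
    section_index: int = 0,
) -> MacrosectionStack:
    """Read a multi-page TIFF / OME-TIFF into a :class:`MacrosectionStack`.

    Voxel intensities are preserved bit-exactly.  ``spacing`` and
    ``channel_names`` arguments override sidecar and embedded metadata; if a
    value is available from none of the three sources an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "C")
        meta_spacing, meta_names = _metadata_from_tiff(tif)

    sidecar = _sidecar_path(path)
    sc_spacing = sc_names = None
    sc_index = None
    if sidecar.exists():
        sc = json.loads(sidecar.read_text())
        sc_spacing = sc.get("spacing_um_zyx")
        sc_names = sc.get("channel_names")
        sc_index = sc.get("section_index")

    names = list(channel_names) if channel_names is not None else (sc_names or meta_names)

    # Normalize the pixel array to (C, Z, Y, X).
    if data.ndim == 2:
        data = data[None, None]
        axes = "CZYX"
    elif data.ndim == 3:
        if names is not None and len(names) > 1:
            # pages are interleaved channel planes: (n_pages, y, x)
            n = len(names)
            if data.shape[0] % n != 0:
                raise ValueError(
                    f"{data.shape[0]} pages not divisible by {n} declared channels"
                )
            if axes.startswith("C"):
                data = data.reshape(n, data.shape[0] // n, *data.shape[1:])
            else:
                data = data.reshape(data.shape[0] // n, n, *data.shape[1:])
                data = np.moveaxis(data, 1, 0)
        else:
            data = data[None]
        axes = "CZYX"
    elif data.ndim == 4:
        if axes in ("ZCYX", "TCYX"):
            data = np.moveaxis(data, 1, 0)
        elif axes not in ("CZYX", "CTYX"):
            # trust channel-major if ambiguous but validate against names below
            pass
    else:
        raise ValueError(f"cannot interpret {data.ndim}D TIFF as (C, Z, Y, X)")

    if not (np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.floating)):
        raise ValueError(f"unsupported pixel type {data.dtype}")

    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{len(names)} channel names declared for {data.shape[0]} channels in {path.name}"
        )

    use_spacing = spacing if spacing is not None else (sc_spacing or meta_spacing)
    if use_spacing is None:
        raise ValueError(
            f"no voxel spacing found for {path.name}: pass spacing=, or provide "
            "a JSON sidecar / OME metadata"
        )
    grid = VoxelGrid(data, tuple(use_spacing), list(names))
    return MacrosectionStack(
        grid=grid,
        section_index=section_index if sc_index is None else int(sc_index),
    )


def read_volume(path, **kw) -> TumorVolume:
    """Read a fused volume written by :func:`write_stack`."""
    stack = read_stack(path, **kw)
    sidecar = _sidecar_path(Path(path))
    boundaries = []
    if sidecar.exists():
        boundaries = json.loads(sidecar.read_text()).get("section_boundaries", [])
    return TumorVolume(grid=stack.grid, section_boundaries=boundaries)


__all__ = ["read_stack", "write_stack", "read_volume"]
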