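"""End-to-end orchestration: stitch -> normalize -> register -> fuse ->
clear background -> segment -> quantify, with a run manifest for provenance.

The orchestrator only sequences the stage functions (each is independently
invokable from the library or CLI) and records every stage's parameters and
input hashes so a run is reproducible from its manifest.  Fixed inputs and
seed give byte-identical quantification tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    LabelMask,
    MacrosectionStack,
    QuantRecord,
    RigidTransform2D,
    TumorVolume,
    records_to_frame,
)
from .depthnorm import gains_to_frame, normalize_depth
from .fusion import clear_background, fuse_volume, register_sections
from .phantom import PhantomSpec, PhantomTruth, TileSet, generate_phantom
from .quantify import (
    DistanceProfile,
    PDMMap,
    core_periphery_partition,
    distance_profile,
    double_positive_fraction,
    pdm_analysis,
    vessel_ligand_fraction,
)
from .segmentation import (
    extract_tumor_outline,
    extract_vessels,
    segment_membrane_cells,
    threshold_channel,
)
from .stitching import stitch_tiles

DEFAULT_PARAMS: dict = {
    "stitch": {"reference_channel": "sum", "ncc_threshold": 0.3},
    "normalize": {"max_gain": 3.0},
    "register": {"rotation_search": True, "max_rotation_deg": 10.0},
    "fuse": {},
    "clearbg": {"close_radius_vox": 10},
    "segment": {
        "tumor_channel": "her2",
        "ligand_channel": "pdl1",
        "vessel_channel": "cd31",
        "immune_channel": "cd45",
        "threshold_method": "otsu",
        "vessel_radius_um": (4.0, 10.0),
        "outline_closing_um": 10.0,
    },
    "quantify": {
        "core_depth_um": 80.0,
        "bin_width_um": 25.0,
        "vessel_dilation_vox": 2,
    },
}


def _merge_params(overrides: dict | None) -> dict:
    params = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
    for stage, kv in (overrides or {}).items():
        params.setdefault(stage, {}).update(kv)
    return params


def _hash_arrays(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    volume: TumorVolume
    tissue: np.ndarray
    tumor_mask: LabelMask
    ligand_mask: LabelMask
    vessel_labels: LabelMask
    immune_labels: LabelMask
    immune_centroids_um: np.ndarray
    outline: LabelMask
    region_labels: LabelMask
    records: list[QuantRecord]
    vessel_table: pd.DataFrame
    profile: DistanceProfile
    pdm: PDMMap
    transforms: list[RigidTransform2D]
    tile_positions: list[np.ndarray]
    gains: list[pd.DataFrame]
    manifest: dict

    @property
    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def record(self, measure: str, region: str = "whole") -> QuantRecord:
        for r in self.records:
            if r.measure == measure and r.region == region:
                return r
        raise KeyError(f"no record {measure!r} for region {region!r}")


def analyze_sections(
    sections: list[TileSet | MacrosectionStack],
    params: dict | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full reconstruction and quantification on in-memory sections.

    Each entry is either a :class:`TileSet` (stitched here) or an already
    stitched :class:`MacrosectionStack`.
    """
    p = _merge_params(params)
    manifest: dict = {"version": __version__, "seed": seed, "stages": []}

    # 1. stitch
    stacks: list[MacrosectionStack] = []
    tile_positions: list[np.ndarray] = []
    for sec in sections:
        if isinstance(sec, TileSet):
            in_hash = _hash_arrays(t.data for t in sec.tiles)
            stack, _, positions = stitch_tiles(
                sec.tiles, sec.layout, section_index=sec.section_index, **p["stitch"]
            )
        else:
            in_hash = _hash_arrays([sec.grid.data])
            stack, positions = sec, np.zeros((1, 3), dtype=int)
        stacks.append(stack)
        tile_positions.append(positions)
        manifest["stages"].append(
            {"stage": "stitch", "section": stack.section_index,
             "params": p["stitch"], "input_hash": in_hash}
        )

    # 2. depth normalization, toward a target shared by all sections so the
    # serial slabs land on one intensity scale
    from .depthnorm import foreground_stats

    per_section = [foreground_stats(st)[0] for st in stacks]
    target: dict[str, float] = {}
    for name in stacks[0].grid.channel_names:
        vals = [s[name] for s in per_section if not np.isnan(s[name])]
        if vals:
            target[name] = float(np.mean(vals))
    gains_frames = []
    normed = []
    n_sec = len(stacks)
    for k, stack in enumerate(stacks):
        boundary = []
        if k > 0:
            boundary.append(0)
        if k < n_sec - 1:
            boundary.append(stack.grid.data.shape[1] - 1)
        nstack, gains = normalize_depth(
            stack, target_mean=target, boundary_slices=tuple(boundary),
            **p["normalize"],
        )
        normed.append(nstack)
        gains_frames.append(gains_to_frame(gains))
    manifest["stages"].append(
        {"stage": "normalize", "params": p["normalize"], "target_mean": target}
    )

    # 3. registration (relative to predecessor)
    rel = [RigidTransform2D.identity()]
    for k in range(1, len(normed)):
        rel.append(register_sections(normed[k - 1], normed[k], **p["register"]))
    manifest["stages"].append(
        {"stage": "register", "params": p["register"],
         "transforms": [t.to_dict() for t in rel]}
    )

    # 4. fusion
    volume = fuse_volume(normed, rel)
    manifest["stages"].append({"stage": "fuse", "params": p["fuse"]})

    # 5. background clearing
    volume, tissue = clear_background(volume, **p["clearbg"])
    manifest["stages"].append({"stage": "clearbg", "params": p["clearbg"]})

    # 6. segmentation
    sp = p["segment"]
    tumor = threshold_channel(volume, sp["tumor_channel"], sp["threshold_method"])
    ligand = threshold_channel(volume, sp["ligand_channel"], sp["threshold_method"])
    vessels = extract_vessels(
        volume, sp["vessel_channel"], tuple(sp["vessel_radius_um"])
    )
    immune, centroids = segment_membrane_cells(volume, sp["immune_channel"])
    outline = extract_tumor_outline(tumor, closing_radius_um=sp["outline_closing_um"])
    manifest["stages"].append({"stage": "segment", "params": sp})

    # 7. quantification
    q = p["quantify"]
    region = core_periphery_partition(
        outline.filled_mask, outline, depth_um=q["core_depth_um"]
    )
    records = list(
        double_positive_fraction(
            tumor, ligand, mode="voxel",
            name_a=sp["tumor_channel"], name_b=sp["ligand_channel"],
        )
    )
    vessel_records, vessel_table = vessel_ligand_fraction(
        vessels, ligand, region_mask=region.mask,
        dilation_vox_inplane=q["vessel_dilation_vox"],
    )
    records += vessel_records
    profile = distance_profile(
        centroids, outline, bin_width_um=q["bin_width_um"],
        inside_mask=outline.filled_mask,
    )
    records.append(QuantRecord("cd45_count", profile.total_count, 1))
    records.append(
        QuantRecord("cd45_median_margin_distance_um", profile.median_um, 1)
    )
    pdm = pdm_analysis(
        volume, sp["tumor_channel"], sp["ligand_channel"], mask=tissue
    )
    manifest["stages"].append({"stage": "quantify", "params": q})

    return PipelineResult(
        volume=volume,
        tissue=tissue,
        tumor_mask=tumor,
        ligand_mask=ligand,
        vessel_labels=vessels,
        immune_labels=immune,
        immune_centroids_um=centroids,
        outline=outline,
        region_labels=region,
        records=records,
        vessel_table=vessel_table,
        profile=profile,
        pdm=pdm,
        transforms=volume.transforms,
        tile_positions=tile_positions,
        gains=gains_frames,
        manifest=manifest,
    )


def write_outputs(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write quantification tables, transforms and the manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _csv(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path

    _csv("quant_records.csv", result.records_frame)
    _csv("vessels.csv", result.vessel_table)
    _csv("distance_histogram.csv", result.profile.to_frame())
    _csv(
        "distance_cells.csv",
        pd.DataFrame(
            {
                "z_um": result.immune_centroids_um[:, 0]
                if len(result.immune_centroids_um)
                else [],
                "y_um": result.immune_centroids_um[:, 1]
                if len(result.immune_centroids_um)
                else [],
                "x_um": result.immune_centroids_um[:, 2]
                if len(result.immune_centroids_um)
                else [],
            }
        ),
    )
    _csv(
        "colocalization.csv",
        pd.DataFrame(
            [
                {
                    "channel_a": result.pdm.channel_a,
                    "channel_b": result.pdm.channel_b,
                    "mean_a": result.pdm.mean_a,
                    "mean_b": result.pdm.mean_b,
                    "pearson_r": result.pdm.pearson_r,
                    "icq": result.pdm.icq,
                    "n_mask_voxels": int(result.pdm.mask.sum()),
                }
            ]
        ),
    )
    for k, g in enumerate(result.gains):
        _csv(f"gains_section{k}.csv", g)
    tpath = outdir / "transforms.json"
    tpath.write_text(
        json.dumps([t.to_dict() for t in result.transforms], indent=1)
    )
    paths["transforms.json"] = tpath
    result.manifest["outputs"] = sorted(paths)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(result.manifest, indent=1, default=str))
    paths["manifest.json"] = mpath
    return paths


def run_phantom_pipeline(
    spec: PhantomSpec | None = None,
    params: dict | None = None,
    outdir=None,
) -> tuple[PipelineResult, PhantomTruth]:
    """Generate the phantom and run the full pipeline on its tiles."""
    spec = spec or PhantomSpec()
    sections, truth = generate_phantom(spec)
    result = analyze_sections(sections, params=params, seed=spec.seed)
    if outdir is not None:
        write_outputs(result, outdir)
    return result, truth


def load_config(path) -> dict:
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def run_pipeline(config, outdir=None) -> PipelineResult:
    """Run from a configuration mapping (or YAML path).

    The config lists either ``phantom`` parameters or ``sections`` (each with
    ``tiles`` file paths plus a ``layout``, or a pre-stitched ``stack``), and
    optional per-stage ``params``.  Validation happens before any
    computation.
    """
    from .io import read_stack
    from .stitching import TileLayout

    if not isinstance(config, dict):
        config = load_config(config)
    params = config.get("params")
    seed = int(config.get("seed", 0))

    if "phantom" in config:
        spec = PhantomSpec(**{**config["phantom"], "seed": seed})
        result, _ = run_phantom_pipeline(spec, params=params, outdir=outdir)
        return result

    if "sections" not in config:
        raise ValueError("config must define 'phantom' or 'sections'")
    spacing = config.get("spacing")
    channels = config.get("channels")
    if spacing is None:
        raise ValueError("config missing 'spacing' (z, y, x in um)")
    sections: list[TileSet | MacrosectionStack] = []
    for k, entry in enumerate(config["sections"]):
        if "stack" in entry:
            sections.append(
                read_stack(entry["stack"], spacing=spacing, channel_names=channels,
                           section_index=k)
            )
        elif "tiles" in entry:
            layout = TileLayout(**config["layout"])
            tiles = [
                read_stack(pth, spacing=spacing, channel_names=channels).grid
                for pth in entry["tiles"]
            ]
            sections.append(TileSet(tiles=tiles, layout=layout, section_index=k))
        else:
            raise ValueError(f"section {k} defines neither 'stack' nor 'tiles'")
    result = analyze_sections(sections, params=params, seed=seed)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


__all__ = [
    "DEFAULT_PARAMS",
    "PipelineResult",
    "analyze_sections",
    "run_phantom_pipeline",
    "run_pipeline",
    "write_outputs",
    "load_config",
]
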