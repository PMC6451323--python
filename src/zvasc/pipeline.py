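"""Experiment-level pipeline: stitch → project → segment → quantify → fit.

An experiment folder holds one subfolder per fish, angle, timepoint and
channel, with the tiles of one acquisition mosaic plus a stage-position
CSV per timepoint:

    experiment/
      <fish>/<angle>/<timepoint>/
        positions.csv                 # tile_id, z_um, y_um, x_um
        <channel>/tile_<id>.tif       # channel in {endothelial, rbc}

``run_pipeline`` walks this hierarchy: per timepoint it stitches both
channels (registration on the endothelial MIPs, parameters re-applied to
both 3D stacks), segments the fused stack with the RBC-trained model,
and measures the vascular volume; per fish it averages the angles,
applies the per-fish temporal alignment shift, and — given enough
timepoints — fits the requested growth models. Every stage logs its
inputs, parameters, seed and output hashes, failures are recorded per
item without stopping the run, and a re-run skips items whose outputs
already exist (byte-identical, since every stochastic stage is seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import growth, quantify, stitching
from .features import ChannelVolume
from .segmentation import BinaryMask, SegmentationConfig, segment_volume

__all__ = ["PipelineConfig", "run_pipeline", "read_positions_csv",
           "read_channel_tiles", "write_mask_tiff"]

log = logging.getLogger("zvasc")

CHANNELS = ("endothelial", "rbc")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML/JSON."""

    experiment_dir: str
    output_dir: str
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # segmentation
    n_samples: int = 5000
    seed: int = 0
    proxy_sigma: float = 2.0
    # stitching
    search_radius: int = 20
    score_floor: float = 0.3
    # annotation (template matching windows, px)
    template_size: int = 70
    search_size: int = 140
    # growth analysis
    models: tuple = ("log_logistic", "log_normal", "gompertz", "logistic",
                     "weibull", "richards")
    n_restarts: int = 10
    time_step_hours: float = 1.0
    time_start_hpf: float = 17.0
    time_shifts: dict = field(default_factory=dict)  # fish_id -> hours

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = asdict(self)
        data["voxel_spacing"] = list(self.voxel_spacing)
        data["models"] = list(self.models)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))


def read_positions_csv(path, voxel_spacing) -> tuple[list, np.ndarray]:
    """Stage positions (µm) → integer voxel offsets via the spacing."""
    df = pd.read_csv(path)
    required = {"tile_id", "z_um", "y_um", "x_um"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: positions CSV needs columns {sorted(required)}")
    df = df.sort_values("tile_id")
    um = df[["z_um", "y_um", "x_um"]].to_numpy(dtype=np.float64)
    voxels = np.round(um / np.asarray(voxel_spacing)).astype(np.int64)
    return df["tile_id"].tolist(), voxels


def read_channel_tiles(channel_dir: Path, tile_ids) -> list[np.ndarray]:
    tiles = []
    for tid in tile_ids:
        p = channel_dir / f"tile_{tid}.tif"
        if not p.exists():
            raise FileNotFoundError(p)
        tiles.append(tifffile.imread(p).astype(np.float64))
    return tiles


def write_mask_tiff(mask: BinaryMask, path) -> None:
    """Binary mask as 8-bit TIFF, foreground = 255."""
    tifffile.imwrite(path, mask.voxels.astype(np.uint8) * 255)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stitch_timepoint(tp_dir: Path, config: PipelineConfig) -> dict[str, np.ndarray]:
    """Stitch both channels of one timepoint; registration from the
    endothelial channel is re-applied to the RBC channel."""
    tile_ids, positions = read_positions_csv(tp_dir / "positions.csv",
                                             config.voxel_spacing)
    fused = {}
    refined = None
    for channel in CHANNELS:
        tiles = read_channel_tiles(tp_dir / channel, tile_ids)
        tileset = stitching.TileSet(tiles, positions.copy())
        if refined is None:
            fused[channel], refined = stitching.stitch_dataset(
                tileset, config.search_radius, config.score_floor
            )
        else:
            fused[channel] = stitching.fuse_linear_blending(tiles, refined)
    return fused


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full processing pipeline over an experiment folder.

    Returns a report dict: per-item status, output hashes, volume tables
    and growth fits. Items that fail record their error and stage; the
    run continues. Completed items (mask + volume row already on disk)
    are skipped on re-run.
    """
    exp = Path(config.experiment_dir)
    out = Path(config.output_dir)
    fish_dirs = sorted(d for d in exp.iterdir() if d.is_dir()) if exp.is_dir() else []
    if not fish_dirs:
        raise ValueError(f"experiment folder {exp} is empty or missing")
    out.mkdir(parents=True, exist_ok=True)

    report = {"items": [], "volumes": [], "fits": []}
    per_fish_angle: dict[tuple, list] = {}

    for fish_dir in fish_dirs:
        for angle_dir in sorted(d for d in fish_dir.iterdir() if d.is_dir()):
            for tp_dir in sorted(d for d in angle_dir.iterdir() if d.is_dir()):
                item = {
                    "fish": fish_dir.name, "angle": angle_dir.name,
                    "timepoint": tp_dir.name, "status": "ok", "stage": None,
                }
                item_out = out / fish_dir.name / angle_dir.name / tp_dir.name
                mask_path = item_out / "mask.tif"
                vol_path = item_out / "volume.json"
                try:
                    if mask_path.exists() and vol_path.exists():
                        item["status"] = "skipped"
                        volume = json.loads(vol_path.read_text())["volume_um3"]
                    else:
                        item_out.mkdir(parents=True, exist_ok=True)
                        item["stage"] = "stitch"
                        fused = _stitch_timepoint(tp_dir, config)
                        item["stage"] = "mip"
                        tifffile.imwrite(
                            item_out / "mip_endothelial.tif",
                            stitching.max_project(fused["endothelial"]).astype(
                                np.float32),
                        )
                        item["stage"] = "segment"
                        seg_cfg = SegmentationConfig(
                            n_samples=config.n_samples, seed=config.seed,
                            proxy_sigma=config.proxy_sigma,
                        )
                        mask, model = segment_volume(
                            ChannelVolume(fused["endothelial"],
                                          config.voxel_spacing, "endothelial"),
                            ChannelVolume(fused["rbc"],
                                          config.voxel_spacing, "rbc"),
                            seg_cfg,
                        )
                        write_mask_tiff(mask, mask_path)
                        (item_out / "model.json").write_text(
                            json.dumps(model.to_dict(), indent=2))
                        item["stage"] = "quantify"
                        volume = quantify.measure_volume(mask)
                        vol_path.write_text(json.dumps(
                            {"volume_um3": volume, "voxels": mask.count()}))
                    item["hashes"] = {
                        "mask": _sha256(mask_path), "volume": _sha256(vol_path)}
                    key = (fish_dir.name, angle_dir.name)
                    per_fish_angle.setdefault(key, []).append(
                        (tp_dir.name, volume))
                    report["volumes"].append({
                        "fish_id": fish_dir.name, "angle": angle_dir.name,
                        "timepoint": tp_dir.name, "volume_um3": volume,
                    })
                except Exception as e:  # record and continue with other items
                    item["status"] = "failed"
                    item["error"] = str(e)
                    log.error("item %s/%s/%s failed at %s: %s", fish_dir.name,
                              angle_dir.name, tp_dir.name, item["stage"], e)
                report["items"].append(item)

    # per fish: average angles, align time, fit growth models
    fish_ids = sorted({k[0] for k in per_fish_angle})
    for fish in fish_ids:
        angle_series = []
        for (f, angle), rows in sorted(per_fish_angle.items()):
            if f != fish:
                continue
            rows = sorted(rows)
            times = config.time_start_hpf + config.time_step_hours * np.arange(
                len(rows))
            angle_series.append(quantify.VolumeSeries(
                fish, "whole", times, [v for _, v in rows], angle_ids=(angle,)))
        if not angle_series:
            continue
        series = angle_series[0]
        for other in angle_series[1:]:
            series = quantify.combine_angles(series, other)
        series = quantify.align_time(
            series, float(config.time_shifts.get(fish, 0.0)))
        series.to_frame().to_csv(out / f"volumes_{fish}.csv", index=False)

        max_free = max(len(growth.MODELS[m].param_names) for m in config.models)
        if len(series) > max_free:
            fits = growth.compare_models(series, config.models,
                                         config.n_restarts, config.seed)
            fit_rows = [{
                "fish_id": fish, "model": f.model_id, "rss": f.rss,
                "converged": f.converged, **f.params} for f in fits]
            pd.DataFrame(fit_rows).to_csv(out / f"fits_{fish}.csv", index=False)
            report["fits"].extend(fit_rows)
        else:
            log.info("fish %s: %d timepoints, too few for growth fitting",
                     fish, len(series))

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
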