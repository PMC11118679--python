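"""End-to-end screen orchestration, file formats and the simulated stage.

`run_screen` drives a whole simulated culture plate through the acquisition
pipeline: wells are visited in row-major order starting at A1; each well
image is checked for tissue (empty wells are logged as void and skipped);
the detected centroid is converted to stage voltages and the simulated
X/Y stages are moved; the Z stage is swept for the optimal depth (once per
plate when sweep caching is on); a phantom OCT volume is acquired and
segmented; and the morphometric readouts are appended to the screen table.
When both control groups are present, the assay-quality report (Z', SSMD,
repeatability, reproducibility, Welch p-value) is computed per readout.

File formats: multi-page TIFF for volumes (uint16) and masks (uint8,
{0,255} on disk), PNG for well images, JSONL for boxes, CSV for readout
tables, JSON for QC reports and ground-truth sidecars, YAML for configs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import assay_stats, morphometry, segmentation
from .depth_sweep import find_optimal_depth
from .errors import ConfigError, ParameterError
from .phantom import GroundTruth, PhantomSpec, make_depth_stack, \
    make_oct_volume, make_well_image
from .plate_detection import StageCalibration, centroid_to_stage, \
    detect_tissue_baseline

logger = logging.getLogger("octscreen")

SCREEN_COLUMNS = ["sample_id", "group", "timepoint", "repetition",
                  "thickness_um", "area_mm2", "volume_mm3"]
READOUT_COLUMNS = ["thickness_um", "area_mm2", "volume_mm3"]


# ---------------------------------------------------------------------------
# Simulated motorized stage
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStage:
    """Idealized 3-axis stage: every commanded move lands exactly and is
    recorded in the motion log so the pipeline's ordering is auditable."""

    voltages: tuple[float, float, float] = (0.0, 0.0, 0.0)
    motion_log: list = field(default_factory=list)

    def move_to(self, x: Optional[float] = None, y: Optional[float] = None,
                z: Optional[float] = None, note: str = "") -> None:
        new = (
            self.voltages[0] if x is None else float(x),
            self.voltages[1] if y is None else float(y),
            self.voltages[2] if z is None else float(z),
        )
        self.motion_log.append({"from": self.voltages, "to": new,
                                "note": note})
        self.voltages = new


# ---------------------------------------------------------------------------
# Screen configuration
# ---------------------------------------------------------------------------

def _default_groups() -> dict:
    return {"A1": "negative", "A2": "negative",
            "A3": "positive", "B1": "positive",
            "B2": "positive", "B3": "positive"}


def _default_phantom() -> dict:
    # Reduced-resolution acquisition defaults so a six-well screen with five
    # repeats per well runs in seconds; full 500x500x512 geometry remains
    # available through the overrides.
    return {"n_alines": 96, "n_bscans": 32, "axial_px": 128, "dz_um": 4.0,
            "tissue_radii_mm": (2.4, 2.0), "image_size_px": (300, 300)}


def _default_group_overrides() -> dict:
    return {
        "negative": {"thickness_profile": "uniform",
                     "profile_params": {"thickness_um": 134.0}},
        "positive": {"thickness_profile": "uniform",
                     "profile_params": {"thickness_um": 190.0}},
    }


@dataclass
class ScreenConfig:
    """Layout, per-well phantom parameters and acquisition settings."""

    n_rows: int = 2
    n_cols: int = 3
    groups: dict = field(default_factory=_default_groups)
    phantom_defaults: dict = field(default_factory=_default_phantom)
    group_overrides: dict = field(default_factory=_default_group_overrides)
    well_overrides: dict = field(default_factory=dict)
    calibration: StageCalibration = field(default_factory=StageCalibration)
    n_repeats: int = 5
    sweep_n_positions: int = 11
    sweep_skip_after_first: bool = True
    segmentation_method: str = "classical"
    center_jitter_mm: float = 2.0
    timepoint: str = "t0"
    save_volumes: bool = False
    seed: int = 0

    def well_ids(self) -> list[str]:
        return [f"{chr(ord('A') + r)}{c + 1}"
                for r in range(self.n_rows) for c in range(self.n_cols)]

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("plate layout must have >= 1 row and column")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.segmentation_method != "classical":
            raise ConfigError(
                f"unknown segmentation method {self.segmentation_method!r}")
        wells = set(self.well_ids())
        for wid in self.groups:
            if wid not in wells:
                raise ConfigError(f"well {wid!r} outside the plate layout")
        for wid in self.well_overrides:
            if wid not in wells:
                raise ConfigError(f"override for unknown well {wid!r}")


_CONFIG_KEYS = {f.name for f in dataclasses.fields(ScreenConfig)}


def screen_config_from_dict(d: dict) -> ScreenConfig:
    """Build a ScreenConfig from a plain dict (e.g. parsed YAML).

    Unknown keys are warned about and ignored for forward compatibility.
    """
    if not isinstance(d, dict):
        raise ConfigError("screen config must be a mapping")
    kwargs = {}
    for key, value in d.items():
        if key not in _CONFIG_KEYS:
            logger.warning("ignoring unknown config key %r", key)
            continue
        if key == "calibration" and isinstance(value, dict):
            value = StageCalibration(**{
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in value.items()
            })
        kwargs[key] = value
    try:
        cfg = ScreenConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def load_screen_config(path) -> ScreenConfig:
    """Load a screen config from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return screen_config_from_dict(data or {})


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_volume(path, data: np.ndarray, dx_um: float, dy_um: float,
                 dz_um: float) -> None:
    """Write an OCT volume as a multi-page TIFF (one page per B-scan)."""
    meta = {"dx_um": dx_um, "dy_um": dy_um, "dz_um": dz_um}
    tifffile.imwrite(path, np.asarray(data), photometric="minisblack",
                     description=json.dumps(meta))


def read_volume(path) -> tuple[np.ndarray, dict]:
    """Read a volume TIFF; returns (array, spacing metadata dict)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return data, meta


def write_mask(path, mask: np.ndarray, dx_um: float = 12.0,
               dy_um: float = 12.0, dz_um: float = 2.0) -> None:
    """Write a {0,1} mask volume as uint8 {0,255} multi-page TIFF."""
    write_volume(path, (np.asarray(mask) > 0).astype(np.uint8) * 255,
                 dx_um, dy_um, dz_um)


def read_mask(path) -> tuple[np.ndarray, dict]:
    """Read a mask TIFF back to {0,1} uint8."""
    data, meta = read_volume(path)
    return (data > 127).astype(np.uint8), meta


def write_well_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_well_image(path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def write_boxes_jsonl(path, records) -> None:
    """Write (image name, BoundingBox) pairs as JSON lines."""
    with open(path, "w") as fh:
        for image, box in records:
            fh.write(json.dumps({
                "image": image, "x0": box.x0, "y0": box.y0,
                "x1": box.x1, "y1": box.y1, "confidence": box.confidence,
            }) + "\n")


def read_boxes_jsonl(path) -> list:
    from .plate_detection import BoundingBox

    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            records.append((d["image"], BoundingBox(
                d["x0"], d["y0"], d["x1"], d["y1"],
                d.get("confidence", 1.0))))
    return records


def write_screen_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_screen_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"screen CSV missing columns: {missing}")
    return table


def write_ground_truth(path, gt: GroundTruth) -> None:
    """JSON sidecar of the scalar ground-truth fields (arrays omitted)."""
    payload = {
        "has_tissue": gt.has_tissue,
        "bbox_px": list(gt.bbox_px) if gt.bbox_px is not None else None,
        "centroid_mm": list(gt.centroid_mm) if gt.centroid_mm else None,
        "area_mm2": gt.area_mm2,
        "volume_mm3": gt.volume_mm3,
        "central_thickness_um": gt.central_thickness_um,
        "optimal_z_index": gt.optimal_z_index,
        "analytic": gt.analytic,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Screen orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    readouts: pd.DataFrame
    qc: dict
    log: list
    stage: SimulatedStage


def _well_spec(cfg: ScreenConfig, well_id: str, group: Optional[str],
               rng: np.random.Generator) -> PhantomSpec:
    params: dict = dict(cfg.phantom_defaults)
    if group is not None and group in cfg.group_overrides:
        params.update(cfg.group_overrides[group])
    params.update(cfg.well_overrides.get(well_id, {}))
    params["occupancy"] = 1.0 if group is not None else 0.0
    spec = PhantomSpec(**params)
    if group is not None and cfg.center_jitter_mm > 0:
        cx, cy = spec.tissue_center_mm
        jitter = rng.uniform(-cfg.center_jitter_mm, cfg.center_jitter_mm, 2)
        spec.tissue_center_mm = (cx + float(jitter[0]), cy + float(jitter[1]))
    spec.validate()
    return spec


def _qc_report(table: pd.DataFrame) -> dict:
    """Assay-quality report per readout from a single-timepoint screen table."""
    per_sample = table.groupby(["sample_id", "group"], as_index=False)[
        READOUT_COLUMNS].mean()
    groups = set(per_sample["group"])
    if not {"negative", "positive"} <= groups:
        return {}
    report: dict = {}
    for readout in READOUT_COLUMNS:
        pos = per_sample.loc[per_sample["group"] == "positive", readout]
        neg = per_sample.loc[per_sample["group"] == "negative", readout]
        if len(pos) < 2 or len(neg) < 2:
            continue
        entry: dict = {}
        try:
            q = assay_stats.assess(pos.to_numpy(), neg.to_numpy(),
                                   readout=readout)
            entry.update({"zprime": q.zprime, "ssmd": q.ssmd,
                          "flags": q.flags})
        except Exception as exc:  # degenerate groups: record, don't abort
            entry["error"] = str(exc)
        entry["p_value"] = assay_stats.group_compare(pos.to_numpy(),
                                                     neg.to_numpy())
        n_reps = table["repetition"].nunique()
        if n_reps >= 2:
            entry["repeatability"] = assay_stats.repeatability(table, readout)
        entry["reproducibility"] = {
            grp: assay_stats.reproducibility(
                table, grp, readout, condition_cols=("group",))
            for grp in ("negative", "positive")
        }
        report[readout] = entry
    return report


def run_screen(cfg: ScreenConfig, out_dir=None) -> ScreenResult:
    """Run the full simulated screening pipeline over one plate.

    Fully reproducible from ``cfg.seed``; returns the readout table, the QC
    report (empty dict when a control group is missing), the per-well event
    log and the simulated stage with its motion log. With ``out_dir`` set,
    writes readouts.csv, qc.json, screen_log.jsonl and per-well artifacts
    (well image PNG + ground-truth JSON; volumes only when
    ``cfg.save_volumes``).
    """
    cfg.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise ParameterError(f"cannot create output dir {out}: {exc}")

    master = np.random.default_rng(cfg.seed)
    # One block of pre-drawn seeds per well keeps well pipelines independent
    # of each other's draw counts.
    well_ids = cfg.well_ids()
    well_seeds = master.integers(0, 2**31 - 1, size=(len(well_ids),
                                                     cfg.n_repeats + 3))
    sweep_optimal = int(master.integers(0, cfg.sweep_n_positions))

    stage = SimulatedStage()
    log: list[dict] = []
    rows: list[dict] = []
    cached_z: Optional[float] = None

    for i, well_id in enumerate(well_ids):
        group = cfg.groups.get(well_id)
        jitter_rng = np.random.default_rng(well_seeds[i, 0])
        spec = _well_spec(cfg, well_id, group, jitter_rng)

        image, gt_well = make_well_image(spec, seed=int(well_seeds[i, 1]))
        if out is not None:
            write_well_image(out / f"{well_id}.png", image)
            write_ground_truth(out / f"{well_id}.gt.json", gt_well)
        mm_per_px = spec.well_fov_mm / spec.image_size_px[1]
        det = detect_tissue_baseline(image, mm_per_px)

        if det.status == "void":
            log.append({"well": well_id, "group": group, "stage": "detect",
                        "status": "void"})
            logger.info("well %s: void", well_id)
            continue
        log.append({"well": well_id, "group": group, "stage": "detect",
                    "status": "found",
                    "centroid_mm": list(det.centroid_mm)})

        vx, vy = centroid_to_stage(det.centroid_mm, cfg.calibration)
        stage.move_to(x=vx, y=vy, note=f"{well_id}:move-xy")
        log.append({"well": well_id, "stage": "move",
                    "voltages": [vx, vy]})

        if cached_z is None or not cfg.sweep_skip_after_first:
            stack, _ = make_depth_stack(spec, cfg.sweep_n_positions,
                                        sweep_optimal,
                                        seed=int(well_seeds[i, 2]))
            z_pos, z_idx = find_optimal_depth(stack)
            cached_z = z_pos
            log.append({"well": well_id, "stage": "sweep",
                        "z_position": z_pos, "z_index": z_idx})
        else:
            log.append({"well": well_id, "stage": "sweep",
                        "z_position": cached_z, "skipped": True})
        stage.move_to(z=cached_z, note=f"{well_id}:move-z")

        dx_um = spec.oct_fov_mm * 1000.0 / spec.n_alines
        dy_um = spec.oct_fov_mm * 1000.0 / spec.n_bscans
        for rep in range(1, cfg.n_repeats + 1):
            vol, _gt = make_oct_volume(spec, seed=int(well_seeds[i, 2 + rep]))
            masks = segmentation.segment_volume(vol, dz_um=spec.dz_um,
                                                dx_um=dx_um)
            seg = morphometry.SegVolume(masks=masks, dx_um=dx_um,
                                        dy_um=dy_um, dz_um=spec.dz_um)
            r = morphometry.readout_from_volume(
                seg, sample_id=well_id, timepoint=cfg.timepoint,
                repetition=rep)
            rows.append({
                "sample_id": well_id, "group": group,
                "timepoint": cfg.timepoint, "repetition": rep,
                "thickness_um": r.central_thickness_um,
                "area_mm2": r.area_mm2, "volume_mm3": r.volume_mm3,
            })
            if out is not None and cfg.save_volumes:
                write_volume(out / f"{well_id}_rep{rep}.tiff", vol,
                             dx_um, dy_um, spec.dz_um)
        log.append({"well": well_id, "stage": "measure",
                    "n_repetitions": cfg.n_repeats})

    table = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    qc = _qc_report(table) if len(table) else {}

    if out is not None:
        write_screen_csv(table, out / "readouts.csv")
        with open(out / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        with open(out / "screen_log.jsonl", "w") as fh:
            header = {"seed": cfg.seed, "n_wells": len(well_ids)}
            fh.write(json.dumps(header) + "\n")
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return ScreenResult(readouts=table, qc=qc, log=log, stage=stage)
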