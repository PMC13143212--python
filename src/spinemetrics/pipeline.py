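"""End-to-end workflows: spine morphometry over an image folder and trace
quantification over a folder of trace CSVs, with resolved-parameter
provenance logs so a rerun with the same config is byte-identical."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .images import GrayscaleImage
from .morphometry import summarize_dendrite
from .segmentation import (auto_peel_depth, compare_methods, extract_centerline,
                           extract_spines_by_centerline,
                           extract_spines_by_peeling, resolve_threshold)
from .benchmark import clean_mask
from .traces import (CalciumTrace, CalibrationConstants, calibrate,
                     normalize_to_reference, ratio_trace, trace_features)


class ConfigError(ValueError):
    """Bad or inconsistent run configuration (exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (exit code 3)."""


@dataclass(frozen=True)
class RunConfig:
    input_dir: str = "."
    output_dir: str = "out"
    pixel_size_um: float = 0.1
    threshold: object = "mean+2*sd"        # number or "mean+k*sd"
    min_island_area_px: int = 50
    peel_depth_px: object = 2              # int or "auto"
    min_head_area_px: int = 10
    occupancy_radius_px: int = 4
    n_layers: int = 5
    n_angles: int = 36
    n_avg: int = 5
    auc_baseline: object = "pre-event"
    calibration: dict | None = None        # {r_min, r_max, k_d, beta}
    reference_group: object = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig, extra: dict) -> dict:
    return {"config": asdict(config), "config_sha256_16": config.digest(),
            "spinemetrics_version": __version__, "seed": config.seed, **extra}


def run_spine_analysis(config: RunConfig) -> pd.DataFrame:
    """Full morphometry workflow over every TIFF in ``input_dir``.

    Per image: threshold → label → small-island removal → spine extraction
    by both the peel and centerline routes → cross-method comparison →
    per-spine morphometry from the peel-route result. Writes a per-spine
    long-format CSV, a per-image report CSV and a provenance JSON.
    """
    in_dir = Path(config.input_dir)
    images = sorted(in_dir.glob("*.tif")) + sorted(in_dir.glob("*.tiff"))
    if not images:
        raise DataError(f"no images found in {in_dir}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_image, per_spine = [], []
    for path in images:
        image = GrayscaleImage.from_tiff(path, config.pixel_size_um)
        threshold = resolve_threshold(image, config.threshold)
        mask = clean_mask(image, threshold, config.min_island_area_px)
        depth = auto_peel_depth(mask) if config.peel_depth_px == "auto" \
            else int(config.peel_depth_px)
        try:
            peel_seg = extract_spines_by_peeling(mask, depth,
                                                 config.min_head_area_px)
            centerline = extract_centerline(mask, config.occupancy_radius_px)
            cl_seg = extract_spines_by_centerline(mask, centerline,
                                                  config.n_layers,
                                                  config.min_head_area_px)
        except ValueError as exc:
            raise DataError(f"segmentation failed on {path.name}: {exc}") from exc
        comparison = compare_methods(peel_seg, cl_seg)
        report = summarize_dendrite(peel_seg, centerline,
                                    max_neck_width_px=2 * depth - 1,
                                    n_angles=config.n_angles)
        per_image.append({
            "image_id": path.stem,
            "n_spines": report.n_spines,
            "spine_density_per_um": report.spine_density_per_um,
            "mean_local_dendrite_diameter_um":
                report.mean_local_dendrite_diameter_um,
            "centerline_length_um": report.centerline_length_um,
            "method_mean_jaccard": comparison.mean_jaccard,
            "resolved_threshold": threshold,
            "resolved_peel_depth": depth,
        })
        for rec in report.spine_records:
            per_spine.append({
                "image_id": path.stem,
                "spine_id": rec.spine_id,
                "area_um2": rec.area_um2,
                "head_area_um2": rec.head_area_um2,
                "neck_base_row": rec.neck_reference_point[0],
                "neck_base_col": rec.neck_reference_point[1],
                "thickness_um": rec.local_dendrite_thickness_um,
            })
    img_df = pd.DataFrame(per_image)
    img_df.to_csv(out / "dendrite_reports.csv", index=False, float_format="%.6g")
    pd.DataFrame(per_spine).to_csv(out / "spine_records.csv", index=False,
                                   float_format="%.6g")
    with open(out / "provenance.json", "w") as fh:
        json.dump(_provenance(config, {"n_images": len(images)}), fh, indent=1,
                  sort_keys=True)
    return img_df


def run_trace_analysis(config: RunConfig) -> pd.DataFrame:
    """Trace workflow: ratio → features (→ optional Grynkiewicz calibration
    → optional fold change against a reference group) over every trace CSV
    (with ``.events.json`` sidecars) in ``input_dir``."""
    in_dir = Path(config.input_dir)
    files = sorted(p for p in in_dir.glob("*.csv"))
    if not files:
        raise DataError(f"no trace CSVs found in {in_dir}")
    constants = None
    if config.calibration is not None:
        try:
            constants = CalibrationConstants(**config.calibration)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad calibration constants: {exc}") from exc
    rows = []
    for path in files:
        try:
            trace = CalciumTrace.from_csv(path)
            ratio = ratio_trace(trace)
            if constants is not None:
                ratio = calibrate(ratio, constants, clip=True)
            feats = trace_features(ratio, trace.events, trace.time,
                                   n_avg=config.n_avg)
        except (OSError, KeyError, ValueError) as exc:
            raise DataError(f"trace {path.name}: {exc}") from exc
        row = {"cell_id": path.stem, **feats.as_dict()}
        rows.append(row)
    df = pd.DataFrame(rows)
    if config.reference_group is not None:
        df["group"] = [cid.rsplit("_", 1)[0] for cid in df["cell_id"]]
        df = normalize_to_reference(df, "group", config.reference_group)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "trace_features.csv", index=False, float_format="%.6g")
    with open(out / "provenance.json", "w") as fh:
        json.dump(_provenance(config, {"n_traces": len(files)}), fh, indent=1,
                  sort_keys=True)
    return df
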