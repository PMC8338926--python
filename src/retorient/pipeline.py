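"""End-to-end analysis: image → vesselness → mask → sectors → metrics.

One run produces exactly eight metric rows (one per anatomical sector) and
the supporting artifacts: the binary vessel mask, the orientation color
map, the per-sector orientation distributions, and a JSON log of every
parameter, threshold and sector pixel count so that empirically chosen
settings remain recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hessian import FilterParams, VesselnessResult, multiscale_vesselness
from .image import ScalarImage2D
from .io import load_image, save_mask_png, save_orientation_colormap
from .mask import MASK_MODES, BinaryMask, make_vessel_mask
from .pattern import orientation_histogram, pattern_metrics, vessel_density
from .sectors import SECTOR_LABELS, SectorROI, disk_mask, sector_masks

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_image"]

SCHEMA_VERSION = "1.0"

METRIC_COLUMNS = [
    "schema_version",
    "subject_id",
    "eye",
    "sector",
    "preferred_orientation_deg",
    "anisotropy",
    "vessel_area_px2",
    "vessel_density",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs.

    ``center`` is the macula center in (row, col) pixels — a required user
    input, since plain image exports carry no fixation metadata.
    """

    image_path: str | Path
    center: tuple[float, float]
    px_per_mm: float
    eye: str
    subject_id: str = "subject"
    diameter_mm: float = 5.0
    filter_params: FilterParams = field(default_factory=FilterParams)
    mask_mode: str = "and"
    bin_width_deg: float = 1.0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.mask_mode not in MASK_MODES:
            raise ValueError(f"mask_mode must be one of {MASK_MODES}")


@dataclass(frozen=True)
class PipelineResult:
    metrics: pd.DataFrame
    vesselness: VesselnessResult
    mask: BinaryMask
    roi: SectorROI
    distributions: pd.DataFrame
    log: dict


def analyze_image(image: ScalarImage2D, center: tuple[float, float], eye: str,
                  subject_id: str = "subject", diameter_mm: float = 5.0,
                  filter_params: FilterParams | None = None, mask_mode: str = "and",
                  bin_width_deg: float = 1.0) -> PipelineResult:
    """Run the full analysis on an in-memory image (no file I/O)."""
    if image.px_per_mm is None:
        raise ValueError("image needs px_per_mm metadata for the disk ROI")
    params = filter_params or FilterParams()

    vness = multiscale_vesselness(image, params)
    vmask = make_vessel_mask(image, vness, mode=mask_mode)
    disk, radius = disk_mask(center, diameter_mm, image.px_per_mm, image.shape)
    roi = sector_masks(disk, center, eye, radius_px=radius)

    rows = []
    dist_rows = []
    sector_counts = {}
    for label in SECTOR_LABELS:
        sec = roi.sectors[label]
        sector_counts[label] = int(sec.sum())
        dist = orientation_histogram(vness.theta0, vmask, sec, bin_width_deg)
        density = vessel_density(vmask, sec)
        if dist.empty:
            met_row = {"preferred_orientation_deg": np.nan, "anisotropy": np.nan,
                       "vessel_area_px2": 0.0, "vessel_density": density}
        else:
            met = pattern_metrics(dist).with_density(density)
            met_row = {
                "preferred_orientation_deg": met.preferred_orientation_deg,
                "anisotropy": met.anisotropy,
                "vessel_area_px2": met.vessel_area_px2,
                "vessel_density": met.vessel_density,
            }
        rows.append({"schema_version": SCHEMA_VERSION, "subject_id": subject_id,
                     "eye": eye, "sector": label, **met_row})
        for k in range(dist.n_bins):
            dist_rows.append({"sector": label, "bin_deg": k * dist.bin_width,
                              "count": int(dist.counts[k])})

    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    distributions = pd.DataFrame(dist_rows, columns=["sector", "bin_deg", "count"])
    log = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": subject_id,
        "eye": eye,
        "center_row_col": [float(center[0]), float(center[1])],
        "px_per_mm": image.px_per_mm,
        "diameter_mm": diameter_mm,
        "filter_params": {
            "sigma_min": params.sigma_min, "sigma_max": params.sigma_max,
            "sigma_step": params.sigma_step, "beta": params.beta,
            "gamma": params.gamma, "gamma_used": vness.gamma_used,
            "polarity": params.polarity, "ridge_norm_gamma": params.ridge_norm_gamma,
        },
        "mask_mode": mask_mode,
        "mask_threshold": vmask.threshold_used,
        "bin_width_deg": bin_width_deg,
        "sector_pixel_counts": sector_counts,
        "border_px_unreliable": vness.border_px,
    }
    return PipelineResult(metrics=metrics, vesselness=vness, mask=vmask, roi=roi,
                          distributions=distributions, log=log)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load the image, run the analysis and (optionally) write all artifacts.

    With ``out_dir`` set, writes metrics.csv, distributions.csv,
    vessel_mask.png, orientation_colormap.png and run_log.json. Identical
    configs produce byte-identical CSV output.
    """
    image = load_image(config.image_path, px_per_mm=config.px_per_mm)
    result = analyze_image(
        image, config.center, config.eye, subject_id=config.subject_id,
        diameter_mm=config.diameter_mm, filter_params=config.filter_params,
        mask_mode=config.mask_mode, bin_width_deg=config.bin_width_deg,
    )
    result.log["image_path"] = str(config.image_path)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
        result.distributions.to_csv(out / "distributions.csv", index=False)
        save_mask_png(result.mask, out / "vessel_mask.png")
        save_orientation_colormap(result.vesselness, result.mask,
                                  out / "orientation_colormap.png")
        (out / "run_log.json").write_text(json.dumps(result.log, indent=2, default=str))
    return result
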