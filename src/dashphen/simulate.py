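"""Synthetic dashcam seasons with known phenology ground truth.

Real roadside capture yields one frame per day across a ~90-day spring
window, with days lost to recorder failures, day-to-day illumination drift
from the changing morning light, occasional vehicles occluding the tree, and
an imperfect detector that emits duplicate boxes, boxes clipped at the top
of the frame, and low-confidence boxes. This module emulates exactly those
properties with a known leaf-on trajectory, so every downstream stage can be
validated against ground truth that real data cannot provide.

The scene is deliberately schematic: a sky/road background and a single
elliptical canopy whose colour blends from a branch (leaf-off) colour to a
leaf (leaf-on) colour in proportion to a logistic green fraction

    g(day) = baseline + amplitude / (1 + exp(-k (day - t0)))

A fixed multiplicative per-pixel texture field gives the canopy spatial
structure without disturbing chromatic ratios, and a per-day global
illumination multiplier reproduces brightness drift. The generator is fully
deterministic given its configuration (including the seed).

Stochastic draw order (one ``numpy`` Generator per season): first the
vector of missing-day indicators; then, for each present day in order, the
illumination multiplier, the two box-jitter offsets, the occlusion
indicator, and the two occluder-geometry fractions; finally the detection
noise draws day by day (duplicate indicator/offsets/confidence, then
low-confidence indicator/offsets/confidence, then edge indicator/confidence).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from pydantic import BaseModel, Field, model_validator

from .detections import BoundingBox, DetectionSet, write_detections_csv

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "DetectionNoise",
    "SeasonConfig",
    "SeasonTruth",
    "Season",
    "leaf_on_curve",
    "render_frame",
    "inject_detection_noise",
    "simulate_season",
    "canopy_gcc_curve",
    "write_season",
]

# scene palette (8-bit RGB); chosen as plausible leaf-off branchwork, spring
# foliage, overcast sky and tarmac — kept well under 255 so moderate
# illumination multipliers do not clip channels
BRANCH_RGB = np.array([85.0, 70.0, 55.0])
LEAF_RGB = np.array([70.0, 160.0, 60.0])
SKY_RGB = np.array([135.0, 175.0, 220.0])
ROAD_RGB = np.array([95.0, 90.0, 85.0])
OCCLUDER_RGB = np.array([120.0, 120.0, 120.0])

TEXTURE_AMPLITUDE = 0.08  # multiplicative canopy texture, chromatically neutral

TRUE_BOX_CONFIDENCE = 0.99
GREEN_UP_FRACTION = 0.10  # fraction of amplitude defining the true green-up
PLATEAU_FRACTION = 0.90


class ParameterError(ValueError):
    """A curve or noise parameter is outside its domain; names the field."""


class ConfigurationError(ValueError):
    """The season configuration is internally inconsistent (e.g. canopy > image)."""


class DetectionNoise(BaseModel):
    """Detector pathology rates.

    Each probability is per present day: a duplicate box for the same tree at
    lower confidence, a spurious box touching the top image edge, and a
    spurious box with confidence below 0.30. ``duplicate_offset_px`` is the
    standard deviation of the duplicate's centre offset (the offset
    distribution of real detectors is unknown, so it is exposed rather than
    fixed); offsets are clipped to 15% of the box dimensions so a duplicate
    always overlaps its source box with IoU > 0.5. ``box_noise_px`` is the
    per-edge localisation noise of the detector's own box around the true
    one; the default of 0 makes every day's primary detection coincide with
    the ground-truth box.
    """

    duplicate_prob: float = Field(default=0.2, ge=0.0, le=1.0)
    lowconf_prob: float = Field(default=0.15, ge=0.0, le=1.0)
    edge_prob: float = Field(default=0.15, ge=0.0, le=1.0)
    duplicate_offset_px: float = Field(default=4.0, ge=0.0)
    box_noise_px: float = Field(default=0.0, ge=0.0)


class SeasonConfig(BaseModel):
    """Parameters of one synthetic season.

    The defaults emulate a 90-day spring capture starting 3 March: logistic
    leaf-on midpoint at day 40 with rate 0.3/day, pre-season green fraction
    0.05 rising to 0.9, ±10% illumination drift, and 10% each of missing
    days and occluded frames.
    """

    n_days: int = Field(default=90, ge=7)
    start_date: dt.date = dt.date(2020, 3, 3)
    onset_day: float = 40.0
    rate: float = Field(default=0.3, gt=0.0)
    baseline_green: float = Field(default=0.05, ge=0.0, le=1.0)
    max_green: float = Field(default=0.9, ge=0.0, le=1.0)
    illum_amplitude: float = Field(default=0.1, ge=0.0)
    occlusion_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    missing_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    jitter_px: float = Field(default=3.0, ge=0.0)
    image_size: tuple[int, int] = (320, 240)  # (width, height)
    canopy_radii_px: tuple[float, float] | None = None  # default: scales with image
    seed: int = 0
    detection_noise: DetectionNoise = Field(default_factory=DetectionNoise)
    tree_id: str = "tree_1"

    @model_validator(mode="after")
    def _check(self) -> "SeasonConfig":
        if not self.baseline_green < self.max_green:
            raise ValueError(
                f"baseline_green ({self.baseline_green}) must be < max_green ({self.max_green})"
            )
        w, h = self.image_size
        if w < 32 or h < 32:
            raise ValueError("image_size must be at least 32x32")
        return self

    def date_of(self, day_index: int) -> dt.date:
        return self.start_date + dt.timedelta(days=int(day_index))


@dataclass(frozen=True)
class SeasonTruth:
    """Ground truth for one season: the noiseless green-fraction curve, the
    analytic transition dates derived from it, and the true boxes."""

    true_green_up_date: dt.date | None
    true_plateau_date: dt.date | None
    green_fraction: pd.Series
    ground_truth_boxes: list[BoundingBox]


@dataclass
class Season:
    """A fully realised synthetic season."""

    config: SeasonConfig
    dates: list[dt.date]
    frames: dict[dt.date, np.ndarray]
    boxes: dict[dt.date, BoundingBox]
    occluded: dict[dt.date, bool]
    detections: DetectionSet
    truth: SeasonTruth
    noise_counts: dict[str, int] = field(default_factory=dict)


def leaf_on_curve(day, t0: float, k: float, baseline: float, amplitude: float):
    """Logistic leaf-on trajectory: ``baseline + amplitude / (1 + exp(-k (day - t0)))``.

    Monotone non-decreasing in ``day``; the midpoint value
    ``baseline + amplitude/2`` occurs at ``day = t0``. Accepts scalar or
    array ``day``.
    """
    if k <= 0:
        raise ParameterError(f"rate k must be > 0, got {k}")
    if not 0.0 <= baseline <= 1.0:
        raise ParameterError(f"baseline must be in [0, 1], got {baseline}")
    if amplitude < 0:
        raise ParameterError(f"amplitude must be >= 0, got {amplitude}")
    if baseline + amplitude > 1.0 + 1e-12:
        raise ParameterError(
            f"baseline + amplitude must be <= 1, got {baseline + amplitude}"
        )
    day = np.asarray(day, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> inf gives the correct limit
        val = baseline + amplitude / (1.0 + np.exp(-k * (day - t0)))
    return float(val) if val.ndim == 0 else val


def _canopy_geometry(config: SeasonConfig) -> tuple[float, float, float, float]:
    """Nominal (un-jittered) canopy centre and radii in pixels."""
    w, h = config.image_size
    if config.canopy_radii_px is not None:
        rx, ry = config.canopy_radii_px
    else:
        rx, ry = 0.21 * w, 0.26 * h
    return 0.5 * w, 0.40 * h, rx, ry


def _texture_field(config: SeasonConfig) -> np.ndarray:
    """Season-constant multiplicative texture; same field on every frame so
    day-to-day greenness changes come only from the leaf-on curve."""
    w, h = config.image_size
    tex_rng = np.random.default_rng([config.seed % (2**31), 7919])
    return 1.0 + TEXTURE_AMPLITUDE * (2.0 * tex_rng.random((h, w, 1)) - 1.0)


def _green_fraction(config: SeasonConfig, day_index) -> float | np.ndarray:
    return leaf_on_curve(
        day_index,
        config.onset_day,
        config.rate,
        config.baseline_green,
        config.max_green - config.baseline_green,
    )


def render_frame(
    day_index: int,
    config: SeasonConfig,
    rng: np.random.Generator,
    as_float: bool = False,
) -> tuple[np.ndarray, BoundingBox, bool]:
    """Render one day's frame.

    Returns the image (8-bit RGB, or float64 in [0, 255] with
    ``as_float=True``), the ground-truth box tightly enclosing the jittered
    canopy, and whether an occluder was drawn. Consumes a fixed number of
    random draws regardless of outcomes (see module docstring).
    """
    if not 0 <= day_index < config.n_days:
        raise ValueError(f"day_index {day_index} outside [0, {config.n_days})")
    w, h = config.image_size
    cx0, cy0, rx, ry = _canopy_geometry(config)
    if 2 * rx > w or 2 * ry > h:
        raise ConfigurationError("canopy does not fit inside the image")

    mult = 1.0 + config.illum_amplitude * (2.0 * rng.random() - 1.0)
    dx, dy = rng.normal(0.0, config.jitter_px, size=2)
    occ_u = rng.random()
    occ_geom = rng.random(2)
    occluded = occ_u < config.occlusion_prob

    cx = float(np.clip(cx0 + dx, rx + 1.0, w - rx - 1.0))
    cy = float(np.clip(cy0 + dy, ry + 1.0, h - ry - 1.0))

    img = np.empty((h, w, 3), dtype=np.float64)
    horizon = int(0.66 * h)
    img[:horizon] = SKY_RGB
    img[horizon:] = ROAD_RGB

    yy, xx = np.mgrid[0:h, 0:w]
    canopy = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    g = _green_fraction(config, day_index)
    img[canopy] = (1.0 - g) * BRANCH_RGB + g * LEAF_RGB

    img *= _texture_field(config)

    if occluded:
        # grey vehicle-like rectangle over the lower part of the canopy
        occ_w = 0.6 * rx
        occ_x0 = cx - rx + occ_geom[0] * (2 * rx - occ_w)
        occ_y0 = cy + (occ_geom[1] - 0.2) * 0.4 * ry
        x0, x1 = int(occ_x0), int(min(occ_x0 + occ_w, w))
        y0, y1 = int(max(occ_y0, 0)), int(min(cy + ry + 2, h))
        img[y0:y1, x0:x1] = OCCLUDER_RGB

    img = np.clip(img * mult, 0.0, 255.0)

    gt_box = BoundingBox(
        x_min=max(int(np.floor(cx - rx)), 0),
        y_min=max(int(np.floor(cy - ry)), 1),
        x_max=min(int(np.ceil(cx + rx)) + 1, w),
        y_max=min(int(np.ceil(cy + ry)) + 1, h),
        confidence=None,
        class_label="Tree",
        date=config.date_of(day_index),
        tree_id=config.tree_id,
    )
    if not as_float:
        img = np.round(img).astype(np.uint8)
    return img, gt_box, bool(occluded)


def _clipped_shift(
    box: BoundingBox, dx: float, dy: float, image_size: tuple[int, int]
) -> BoundingBox:
    """Shift a box, clipping the offset to 15% of its size (keeps IoU > 0.5
    with the source) and keeping it inside the image with y_min >= 1."""
    w, h = image_size
    max_dx, max_dy = 0.15 * box.width, 0.15 * box.height
    sdx = int(np.clip(dx, -max_dx, max_dx))
    sdy = int(np.clip(dy, -max_dy, max_dy))
    sdx = int(np.clip(sdx, -box.x_min, w - box.x_max))
    sdy = int(np.clip(sdy, 1 - box.y_min, h - box.y_max))
    return box.shifted(sdx, sdy)


def inject_detection_noise(
    gt_boxes: dict[dt.date, BoundingBox],
    noise: DetectionNoise,
    rng: np.random.Generator,
    image_size: tuple[int, int],
) -> tuple[dict[dt.date, list[BoundingBox]], dict[str, int]]:
    """Turn ground-truth boxes into noisy per-day detection lists.

    Every day keeps its true box at confidence 0.99. With the configured
    probabilities a day additionally receives: a shifted duplicate at
    confidence U(0.5, 0.95); a spurious box at confidence U(0.05, 0.30)
    (strictly below the 0.30 cut); and a box touching the top image edge
    (``y_min = 0``) at confidence U(0.35, 0.9). Injected-pathology counts
    are returned for round-trip assertions against the filter cascade.
    """
    w, h = image_size
    out: dict[dt.date, list[BoundingBox]] = {}
    counts = {"duplicate": 0, "lowconf": 0, "edge": 0}
    for date in sorted(gt_boxes):
        box = gt_boxes[date]
        if noise.box_noise_px > 0:
            e = rng.normal(0.0, noise.box_noise_px, size=4)
            x0 = int(np.clip(box.x_min + e[0], 0, w - 2))
            y0 = int(np.clip(box.y_min + e[1], 1, h - 2))
            box = BoundingBox(
                x_min=x0,
                y_min=y0,
                x_max=int(np.clip(box.x_max + e[2], x0 + 2, w)),
                y_max=int(np.clip(box.y_max + e[3], y0 + 2, h)),
                confidence=None,
                class_label=box.class_label,
                date=box.date,
                tree_id=box.tree_id,
            )
        day = [replace(box, confidence=TRUE_BOX_CONFIDENCE)]
        if rng.random() < noise.duplicate_prob:
            dx, dy = rng.normal(0.0, max(noise.duplicate_offset_px, 1e-9), size=2)
            dup = _clipped_shift(box, dx, dy, image_size)
            day.append(replace(dup, confidence=float(rng.uniform(0.5, 0.95))))
            counts["duplicate"] += 1
        if rng.random() < noise.lowconf_prob:
            dx, dy = rng.normal(0.0, 0.1 * box.width, size=2)
            low = _clipped_shift(box, dx, dy, image_size)
            day.append(replace(low, confidence=float(rng.uniform(0.05, 0.30))))
            counts["lowconf"] += 1
        if rng.random() < noise.edge_prob:
            edge = BoundingBox(
                x_min=max(box.x_min - 10, 0),
                y_min=0,
                y_max=max(int(0.35 * h), 1),
                x_max=min(box.x_max + 10, w),
                confidence=float(rng.uniform(0.35, 0.9)),
                class_label=box.class_label,
                date=date,
                tree_id=box.tree_id,
            )
            day.append(edge)
            counts["edge"] += 1
        out[date] = day
    return out, counts


def _truth_from_curve(config: SeasonConfig, boxes: list[BoundingBox]) -> SeasonTruth:
    days = np.arange(config.n_days)
    g = _green_fraction(config, days)
    dates = pd.DatetimeIndex([config.date_of(int(d)) for d in days])
    series = pd.Series(g, index=dates)
    amp = config.max_green - config.baseline_green

    def first_crossing(frac: float) -> dt.date | None:
        level = config.baseline_green + frac * amp
        idx = np.nonzero(g > level)[0]
        return config.date_of(int(idx[0])) if idx.size else None

    return SeasonTruth(
        true_green_up_date=first_crossing(GREEN_UP_FRACTION),
        true_plateau_date=first_crossing(PLATEAU_FRACTION),
        green_fraction=series,
        ground_truth_boxes=boxes,
    )


def simulate_season(config: SeasonConfig, render: bool = True) -> Season:
    """Generate a complete season: frames, true boxes, noisy detections, truth.

    With ``render=False`` the images are skipped (boxes, detections and truth
    only), which is much faster when only the detection pipeline is studied.
    """
    rng = np.random.default_rng(config.seed)
    missing = rng.random(config.n_days) < config.missing_prob

    dates: list[dt.date] = []
    frames: dict[dt.date, np.ndarray] = {}
    boxes: dict[dt.date, BoundingBox] = {}
    occluded: dict[dt.date, bool] = {}
    for day in range(config.n_days):
        if missing[day]:
            continue
        img, gt_box, occ = render_frame(day, config, rng)
        date = config.date_of(day)
        dates.append(date)
        if render:
            frames[date] = img
        boxes[date] = gt_box
        occluded[date] = occ

    noisy, counts = inject_detection_noise(
        boxes, config.detection_noise, rng, config.image_size
    )
    det_records = [b for date in sorted(noisy) for b in noisy[date]]
    detections = DetectionSet(det_records, config.image_size)
    truth = _truth_from_curve(config, [boxes[d] for d in dates])
    return Season(
        config=config,
        dates=dates,
        frames=frames,
        boxes=boxes,
        occluded=occluded,
        detections=detections,
        truth=truth,
        noise_counts=counts,
    )


def canopy_gcc_curve(config: SeasonConfig) -> pd.Series:
    """Noiseless per-day canopy GCC implied by the colour blend.

    Because canopy texture and illumination are multiplicative, the
    per-pixel rgb-mode GCC of the rendered (unquantized) canopy equals the
    GCC of the blended colour exactly; this closed form is the analytic
    truth the measured series is validated against.
    """
    days = np.arange(config.n_days)
    g = _green_fraction(config, days)[:, None]
    colour = (1.0 - g) * BRANCH_RGB + g * LEAF_RGB
    vals = colour[:, 1] / colour.sum(axis=1)
    dates = pd.DatetimeIndex([config.date_of(int(d)) for d in days])
    return pd.Series(vals, index=dates)


def write_season(season: Season, outdir: str | Path) -> dict[str, str]:
    """Write a season to disk: PNG frames, detection/truth CSVs, config JSON.

    Returns a mapping of artefact names to paths.
    """
    outdir = Path(outdir)
    frames_dir = outdir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for date, img in season.frames.items():
        Image.fromarray(img).save(frames_dir / f"{date.isoformat()}.png")

    det_path = outdir / "detections.csv"
    write_detections_csv(season.detections, det_path)
    gt_path = outdir / "ground_truth.csv"
    write_detections_csv(
        DetectionSet(season.truth.ground_truth_boxes, season.config.image_size), gt_path
    )
    curve_path = outdir / "truth_curve.csv"
    curve = season.truth.green_fraction
    pd.DataFrame(
        {"date": curve.index.strftime("%Y-%m-%d"), "green_fraction": curve.to_numpy()}
    ).to_csv(curve_path, index=False)
    config_path = outdir / "config.json"
    with open(config_path, "w") as fh:
        fh.write(season.config.model_dump_json(indent=1))
    truth_dates_path = outdir / "truth_dates.json"
    with open(truth_dates_path, "w") as fh:
        json.dump(
            {
                "tree_id": season.config.tree_id,
                "true_green_up_date": (
                    season.truth.true_green_up_date.isoformat()
                    if season.truth.true_green_up_date
                    else None
                ),
                "true_plateau_date": (
                    season.truth.true_plateau_date.isoformat()
                    if season.truth.true_plateau_date
                    else None
                ),
            },
            fh,
            indent=1,
        )
    return {
        "frames_dir": str(frames_dir),
        "detections": str(det_path),
        "ground_truth": str(gt_path),
        "truth_curve": str(curve_path),
        "config": str(config_path),
        "truth_dates": str(truth_dates_path),
    }
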