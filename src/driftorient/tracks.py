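"""Trajectory and compass file IO, bearing extraction and swimming speed.

The system boundary is the post-tracking interface: per-second head
positions in camera pixels plus a per-second magnetic heading of the
camera's up-axis. Bearings are the angular position of the head relative
to the chamber centre (0 = image-up, clockwise), rotated into the
magnetic frame by adding the compass heading at the matching second.

File dialects (delimiter-separated text, comma default):

* track file    — header ``t_s,x_px,y_px``; y is mathematical y-up unless
  the deployment metadata says ``y_axis: down``
* compass file  — header ``t_s,heading_deg``
* metadata file — flat YAML mapping with deployment and calibration keys
  (``id, utc_start, lat, lon, tide_phase, site, center_x, center_y,
  radius_px, radius_cm, ...``)
* manifest      — one metadata path (or ``meta,track,compass`` triple) per
  line, for batch runs
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from driftorient.angles import Frame, from_components, wrap_deg
from driftorient.circstats import AngleSeries

DEFAULT_ACCLIMATION_S = 300
DEFAULT_ANALYSIS_S = 600
COMPASS_MATCH_TOLERANCE_S = 1.0
MAX_COMPASS_MISS_FRACTION = 0.10
MIN_COVERAGE_FRACTION = 0.80
ARENA_SLACK = 1.05


@dataclass(frozen=True)
class Track:
    """Per-second head positions (camera pixels) for one deployment."""

    t: np.ndarray  # seconds from deployment start, strictly increasing
    x: np.ndarray
    y: np.ndarray
    id: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.size == x.size == y.size):
            raise ValueError("t, x, y must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 2  # 1-based data row
            raise ValueError(f"non-monotone t at data row {bad}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.t.size)

    def gaps(self, spacing: float = 1.0) -> np.ndarray:
        """Seconds missing from the nominal 1 Hz grid (flagged, not filled)."""
        if self.n == 0:
            return np.array([])
        full = np.arange(self.t[0], self.t[-1] + spacing / 2, spacing)
        return np.setdiff1d(np.round(full, 6), np.round(self.t, 6))


@dataclass(frozen=True)
class CompassSeries:
    """Magnetic heading (deg, [0, 360)) of the camera up-axis over time."""

    t: np.ndarray
    heading: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        h = np.asarray(self.heading, dtype=float)
        if t.size != h.size:
            raise ValueError("t and heading must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 2
            raise ValueError(f"non-monotone t at data row {bad}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "heading", wrap_deg(h))


@dataclass(frozen=True)
class ChamberCalibration:
    """Pixel-to-chamber mapping of the circular arena."""

    center_x: float
    center_y: float
    radius_px: float
    radius_cm: float = 20.0  # 40 cm diameter arena

    def __post_init__(self):
        if self.radius_px <= 0 or self.radius_cm <= 0:
            raise ValueError("degenerate calibration")

    @property
    def cm_per_px(self) -> float:
        return self.radius_cm / self.radius_px


@dataclass(frozen=True)
class DeploymentMeta:
    """Deployment-level metadata; tide phase is always supplied, never inferred."""

    id: str
    utc_start: datetime
    latitude: float
    longitude: float
    tide_phase: str  # "ebb" | "flood"
    site_name: str = ""
    acclimation_s: int = DEFAULT_ACCLIMATION_S
    analysis_s: int = DEFAULT_ANALYSIS_S
    y_axis: str = "up"  # "up" | "down" pixel-y convention of the track file

    def __post_init__(self):
        if self.tide_phase not in ("ebb", "flood"):
            raise ValueError("tide_phase must be 'ebb' or 'flood'")
        if self.y_axis not in ("up", "down"):
            raise ValueError("y_axis must be 'up' or 'down'")
        utc = self.utc_start
        if isinstance(utc, str):
            utc = datetime.fromisoformat(utc)
        if utc.tzinfo is None:
            utc = utc.replace(tzinfo=timezone.utc)
        object.__setattr__(self, "utc_start", utc.astimezone(timezone.utc))

    @property
    def midpoint_utc(self) -> datetime:
        from datetime import timedelta

        half = (self.acclimation_s + self.analysis_s) / 2.0
        return self.utc_start + timedelta(seconds=half)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def _read_table(path, columns, sep=","):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header = row 1
        raise ValueError(f"{path}: malformed rows at lines {rows}")
    dup = df[columns[0]].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicated timestamp at line {line}")
    return df.sort_values(columns[0], kind="mergesort").reset_index(drop=True)


def read_track(path, sep=",", id: str = "") -> Track:
    """Read a ``t_s,x_px,y_px`` track file."""
    df = _read_table(path, ["t_s", "x_px", "y_px"], sep=sep)
    return Track(df["t_s"].to_numpy(), df["x_px"].to_numpy(),
                 df["y_px"].to_numpy(), id=id or Path(path).stem)


def write_track(track: Track, path, sep=",") -> None:
    df = pd.DataFrame({"t_s": track.t, "x_px": track.x, "y_px": track.y})
    df.to_csv(path, sep=sep, index=False)


def read_compass(path, sep=",") -> CompassSeries:
    """Read a ``t_s,heading_deg`` compass file."""
    df = _read_table(path, ["t_s", "heading_deg"], sep=sep)
    return CompassSeries(df["t_s"].to_numpy(), df["heading_deg"].to_numpy())


def write_compass(compass: CompassSeries, path, sep=",") -> None:
    pd.DataFrame({"t_s": compass.t, "heading_deg": compass.heading}).to_csv(
        path, sep=sep, index=False)


def read_meta(path) -> tuple[DeploymentMeta, ChamberCalibration]:
    """Read a flat key-value deployment metadata file (YAML mapping)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: metadata must be a flat mapping")
    meta = DeploymentMeta(
        id=str(raw["id"]),
        utc_start=raw["utc_start"],
        latitude=float(raw["lat"]),
        longitude=float(raw["lon"]),
        tide_phase=str(raw["tide_phase"]),
        site_name=str(raw.get("site", "")),
        acclimation_s=int(raw.get("acclimation_s", DEFAULT_ACCLIMATION_S)),
        analysis_s=int(raw.get("analysis_s", DEFAULT_ANALYSIS_S)),
        y_axis=str(raw.get("y_axis", "up")),
    )
    cal = ChamberCalibration(
        center_x=float(raw["center_x"]),
        center_y=float(raw["center_y"]),
        radius_px=float(raw["radius_px"]),
        radius_cm=float(raw.get("radius_cm", 20.0)),
    )
    return meta, cal


def write_meta(meta: DeploymentMeta, cal: ChamberCalibration, path) -> None:
    payload = {
        "id": meta.id,
        "utc_start": meta.utc_start.isoformat(),
        "lat": meta.latitude,
        "lon": meta.longitude,
        "tide_phase": meta.tide_phase,
        "site": meta.site_name,
        "acclimation_s": meta.acclimation_s,
        "analysis_s": meta.analysis_s,
        "y_axis": meta.y_axis,
        "center_x": cal.center_x,
        "center_y": cal.center_y,
        "radius_px": cal.radius_px,
        "radius_cm": cal.radius_cm,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# analysis-window selection
# ---------------------------------------------------------------------------

def _analysis_mask(track: Track, meta: DeploymentMeta) -> np.ndarray:
    lo = meta.acclimation_s
    hi = meta.acclimation_s + meta.analysis_s
    if track.n and track.t[-1] + 1 < hi:
        warnings.warn(
            f"track '{track.id}' shorter than acclimation+analysis window; "
            "truncating", stacklevel=3)
    return (track.t >= lo) & (track.t < hi)


def coverage_fraction(track: Track, meta: DeploymentMeta) -> float:
    """Fraction of the analysis window's nominal seconds present in the track."""
    return float(np.count_nonzero(_analysis_mask(track, meta))) / meta.analysis_s


# ---------------------------------------------------------------------------
# bearings and speed
# ---------------------------------------------------------------------------

def bearings_from_track(
    track: Track,
    compass: CompassSeries,
    cal: ChamberCalibration,
    meta: DeploymentMeta,
) -> AngleSeries:
    """Magnetic bearings of the head position over the analysis window.

    Camera-frame angle is measured from image-up, clockwise; the compass
    heading at the nearest timestamp (within 1 s) rotates it into the
    magnetic frame. Raises when more than 10% of retained seconds lack a
    compass match.
    """
    mask = _analysis_mask(track, meta)
    if not mask.any():
        raise ValueError("no samples in the analysis window")
    t = track.t[mask]
    dx = track.x[mask] - cal.center_x
    dy = track.y[mask] - cal.center_y
    if meta.y_axis == "down":
        dy = -dy  # normalize image y-down to mathematical y-up

    r = np.hypot(dx, dy)
    if np.any(r > cal.radius_px * ARENA_SLACK):
        worst = float(r.max() / cal.radius_px)
        warnings.warn(
            f"track '{track.id}': positions outside the arena circle "
            f"(max {worst:.2f} R)", stacklevel=2)

    theta_cam = from_components(dx, dy)  # 0 = image-up, clockwise

    idx = np.searchsorted(compass.t, t)
    idx = np.clip(idx, 1, compass.t.size - 1) if compass.t.size > 1 else np.zeros(
        t.size, dtype=int)
    if compass.t.size > 1:
        left = compass.t[idx - 1]
        right = compass.t[idx]
        use_left = (t - left) <= (right - t)
        nearest = np.where(use_left, idx - 1, idx)
    else:
        nearest = np.zeros(t.size, dtype=int)
    dt = np.abs(compass.t[nearest] - t)
    matched = dt <= COMPASS_MATCH_TOLERANCE_S
    if np.mean(~matched) > MAX_COMPASS_MISS_FRACTION:
        raise ValueError("compass coverage: >10% of seconds lack a heading")

    bearings = wrap_deg(theta_cam[matched] + compass.heading[nearest[matched]])
    return AngleSeries(bearings, Frame.MAGNETIC_NORTH)


def swimming_speed(
    track: Track, cal: ChamberCalibration, meta: DeploymentMeta
) -> tuple[np.ndarray, float, float]:
    """Per-second speeds (cm/s) over the analysis window, with mean and median.

    Steps spanning gaps (dt != nominal 1 s) are excluded.
    """
    mask = _analysis_mask(track, meta)
    t = track.t[mask]
    if t.size < 2:
        raise ValueError("need at least 2 retained samples")
    x = track.x[mask] * cal.cm_per_px
    y = track.y[mask] * cal.cm_per_px
    dt = np.diff(t)
    step = np.hypot(np.diff(x), np.diff(y))
    keep = np.isclose(dt, 1.0)
    speeds = step[keep] / dt[keep]
    if speeds.size == 0:
        raise ValueError("no consecutive-second steps in the analysis window")
    return speeds, float(np.mean(speeds)), float(np.median(speeds))
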