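"""Ground-truthed synthetic deployments and campaigns.

Generates complete deployments (track + compass + metadata) whose
statistical structure matches what the analysis assumes: a fraction
``p_orient`` of individuals draw a preferred direction from a von Mises
distribution around the population direction (optionally defined per
deployment as moon azimuth + offset) and emit per-second bearings von
Mises-concentrated around it; the remaining individuals emit uniform
bearings. The chamber heading is a wrapped-normal random walk recorded by
the simulated compass, so extraction is an exact inverse of generation.

Head positions sit on a circle of constant per-deployment radius chosen
so that the deployment's mean extracted swimming speed equals a lognormal
draw around ``speed_median`` (the radius is clipped into the arena when
angular movement is too small or too large for the target; a warning is
issued). Radial placement carries no directional information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from driftorient.angles import Frame, wrap_deg, wrap_signed_deg
from driftorient.circstats import AngleSeries
from driftorient import ephemeris as eph
from driftorient.tracks import (
    ChamberCalibration,
    CompassSeries,
    DeploymentMeta,
    Track,
    write_compass,
    write_meta,
    write_track,
)

DEFAULT_CALIBRATION = ChamberCalibration(
    center_x=512.0, center_y=512.0, radius_px=400.0, radius_cm=20.0)

_RADIUS_BOUNDS = (0.05, 0.95)  # fraction of arena radius


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters; recorded alongside every generated dataset."""

    mu_pop: float = 180.0  # population preferred direction (deg)
    kappa_pop: float = 2.0  # between-individual concentration
    kappa_within: float = 0.63  # within-track concentration (Rbar ~ 0.30)
    p_orient: float = 1.0  # fraction of orienting individuals
    sigma_rot: float = 2.0  # chamber-rotation increment s.d. (deg/s)
    speed_median: float = 3.0  # cm/s
    speed_logsd: float = 0.22  # lognormal sigma of deployment mean speed
    seed: int = 0
    moon_offset: Optional[float] = None  # if set, mu_pop = moon azimuth + offset

    def __post_init__(self):
        if self.kappa_pop < 0 or self.kappa_within < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.p_orient <= 1.0:
            raise ValueError("p_orient must be in [0, 1]")
        if self.sigma_rot < 0:
            raise ValueError("sigma_rot must be non-negative")


def deployment_rng(seed: int, counter: int) -> np.random.Generator:
    """Deterministic per-deployment substream from one global seed."""
    return np.random.default_rng([seed, counter])


def simulate_deployment(
    truth: SyntheticTruth,
    meta: DeploymentMeta,
    cal: ChamberCalibration = DEFAULT_CALIBRATION,
    moon_azimuth: Optional[float] = None,
    counter: int = 0,
) -> tuple[Track, CompassSeries, dict]:
    """Simulate one deployment; returns (track, compass, hidden truth record).

    ``moon_azimuth`` (magnetic frame) is only consulted when
    ``truth.moon_offset`` is set, in which case the population direction
    for this deployment is moon azimuth + offset. Fully reproducible from
    ``truth.seed`` and ``counter``.
    """
    rng = deployment_rng(truth.seed, counter)
    n = meta.acclimation_s + meta.analysis_s

    mu_pop = truth.mu_pop
    if truth.moon_offset is not None:
        if moon_azimuth is None:
            raise ValueError("moon_offset set but no moon azimuth supplied")
        mu_pop = wrap_deg(moon_azimuth + truth.moon_offset)

    orienting = bool(rng.random() < truth.p_orient)
    if orienting:
        if truth.kappa_pop > 0:
            mu_i = wrap_deg(np.rad2deg(
                rng.vonmises(np.deg2rad(mu_pop), truth.kappa_pop)))
        else:
            mu_i = wrap_deg(rng.uniform(0.0, 360.0))
        if np.isinf(truth.kappa_within):  # noiseless limit
            theta = np.full(n, mu_i)
        elif truth.kappa_within > 0:
            theta = wrap_deg(np.rad2deg(
                rng.vonmises(np.deg2rad(mu_i), truth.kappa_within, size=n)))
        else:
            theta = rng.uniform(0.0, 360.0, size=n)
    else:
        mu_i = float("nan")
        theta = rng.uniform(0.0, 360.0, size=n)

    # chamber heading: wrapped random walk recorded by the compass
    phi0 = rng.uniform(0.0, 360.0)
    increments = rng.normal(0.0, truth.sigma_rot, size=n - 1)
    phi = wrap_deg(phi0 + np.concatenate([[0.0], np.cumsum(increments)]))

    theta_cam = wrap_deg(theta - phi)

    # constant head radius calibrated so the mean analysis-window speed
    # matches a lognormal draw around speed_median
    target_speed = float(truth.speed_median
                         * np.exp(rng.normal(0.0, truth.speed_logsd)))
    lo = meta.acclimation_s
    win = slice(lo, n)
    dcam = np.deg2rad(wrap_signed_deg(np.diff(theta_cam[win])))
    mean_chord = float(np.mean(2.0 * np.abs(np.sin(dcam / 2.0))))
    if mean_chord > 0:
        rho_cm = target_speed / mean_chord
    else:
        rho_cm = cal.radius_cm * _RADIUS_BOUNDS[1]
    rho_min = _RADIUS_BOUNDS[0] * cal.radius_cm
    rho_max = _RADIUS_BOUNDS[1] * cal.radius_cm
    if not rho_min <= rho_cm <= rho_max:
        warnings.warn(
            f"deployment '{meta.id}': target speed {target_speed:.2f} cm/s "
            "not reachable at this angular movement; head radius clipped",
            stacklevel=2)
        rho_cm = float(np.clip(rho_cm, rho_min, rho_max))
    rho_px = rho_cm / cal.cm_per_px

    rad = np.deg2rad(theta_cam)
    x = cal.center_x + rho_px * np.sin(rad)
    y = cal.center_y + rho_px * np.cos(rad)  # y-up convention

    t = np.arange(n, dtype=float)
    track = Track(t, x, y, id=meta.id)
    compass = CompassSeries(t, phi)
    hidden = {
        "id": meta.id,
        "orienting": orienting,
        "mu_pop": mu_pop,
        "mu_i": mu_i,
        "kappa_within": truth.kappa_within if orienting else 0.0,
        "target_mean_speed": target_speed,
        "achieved_mean_speed": float(
            np.mean(2.0 * rho_cm * np.abs(np.sin(dcam / 2.0)))),
        "rho_cm": rho_cm,
        "sigma_rot": truth.sigma_rot,
        "seed": truth.seed,
        "counter": counter,
        "magnetic_bearings": wrap_deg(theta),
    }
    return track, compass, hidden


@dataclass(frozen=True)
class DeploymentSpec:
    """One planned deployment in a campaign calendar."""

    utc_start: datetime
    latitude: float
    longitude: float
    tide_phase: str
    site_name: str = ""
    condition: str = ""  # free-form label carried into the truth ledger


def simulate_campaign(
    truth: SyntheticTruth,
    calendar: Sequence[DeploymentSpec],
    out_dir: Optional[Path] = None,
    cal: ChamberCalibration = DEFAULT_CALIBRATION,
    declination: float = 0.0,
) -> tuple[list[tuple[Track, CompassSeries, DeploymentMeta]], pd.DataFrame]:
    """Simulate a batch of deployments over a calendar.

    Returns the in-memory deployments and the hidden-truth table. When
    ``out_dir`` is given, writes the track/compass/metadata dialects of
    the tracks module plus ``manifest.csv`` and ``truth.tsv``.
    """
    if len(calendar) == 0:
        warnings.warn("campaign calendar is empty")
    deployments = []
    records = []
    manifest_rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, spec in enumerate(calendar):
        meta = DeploymentMeta(
            id=f"dep{i:04d}",
            utc_start=spec.utc_start,
            latitude=spec.latitude,
            longitude=spec.longitude,
            tide_phase=spec.tide_phase,
            site_name=spec.site_name,
        )
        moon_az = None
        if truth.moon_offset is not None:
            state = eph.moon_position(
                meta.midpoint_utc,
                eph.Site(spec.latitude, spec.longitude, declination))
            moon_az = wrap_deg(state.azimuth - declination)
        track, compass, hidden = simulate_deployment(
            truth, meta, cal=cal, moon_azimuth=moon_az, counter=i)
        deployments.append((track, compass, meta))
        hidden = {k: v for k, v in hidden.items() if k != "magnetic_bearings"}
        hidden["condition"] = spec.condition
        records.append(hidden)
        if out_dir is not None:
            track_path = out_dir / f"{meta.id}_track.csv"
            compass_path = out_dir / f"{meta.id}_compass.csv"
            meta_path = out_dir / f"{meta.id}_meta.yaml"
            write_track(track, track_path)
            write_compass(compass, compass_path)
            write_meta(meta, cal, meta_path)
            manifest_rows.append({
                "meta": meta_path.name,
                "track": track_path.name,
                "compass": compass_path.name,
            })
    truth_table = pd.DataFrame.from_records(records)
    if out_dir is not None:
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv",
                                           index=False)
        truth_table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return deployments, truth_table
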