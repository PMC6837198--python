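"""Full analysis orchestration.

Per-individual inference (bearings -> Rayleigh test -> significance ->
cue-relative bearing -> speed), condition classification from metadata
plus the internal ephemeris, second-order group tests in both the
magnetic and cue-relative frames, the above/below-horizon speed contrast,
and deterministic tabular reports.

The ephemeris instant for azimuth and horizon classification is the
deployment midpoint (start + half of acclimation + analysis); the azimuth
moves by well under the analysis resolution over one deployment.
Altitude exactly 0 classifies as below the horizon (strict inequality).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from driftorient import __version__
from driftorient.angles import Frame, wrap_deg
from driftorient.circstats import (
    AngleSeries,
    CircularSummary,
    RankTestResult,
    angular_difference,
    rank_sum_test,
    rayleigh_second_order,
    rayleigh_test,
)
from driftorient import ephemeris as eph
from driftorient.tracks import (
    ChamberCalibration,
    CompassSeries,
    DeploymentMeta,
    MIN_COVERAGE_FRACTION,
    Track,
    bearings_from_track,
    coverage_fraction,
    read_compass,
    read_meta,
    read_track,
    swimming_speed,
)

ALPHA = 0.05

GROUP_KEYS = ("moon_phase", "tide_phase", "moon_above_horizon")


@dataclass(frozen=True)
class Conditions:
    moon_phase: str
    tide_phase: str
    moon_above_horizon: bool
    moon_azimuth: float  # magnetic frame (true azimuth minus declination)
    sun_azimuth: float
    sun_above_horizon: bool


@dataclass(frozen=True)
class IndividualResult:
    """One individual's magnetic and cue-relative orientation plus speed."""

    id: str
    magnetic: CircularSummary
    moon_relative_bearing: Optional[float]
    sun_relative_bearing: Optional[float]
    significant: bool
    mean_speed: float
    median_speed: float
    conditions: Conditions


@dataclass(frozen=True)
class GroupResult:
    """One stratified row: condition keys, N and both-frame summaries."""

    moon_phase: str
    tide_phase: Optional[str]
    moon_above_horizon: Optional[bool]
    n: int  # significant individuals entering the circular summaries
    n_tested: int
    magnetic: Optional[CircularSummary]
    moon_relative: Optional[CircularSummary]
    prop_significant: float
    mean_r: float
    sd_r: float
    sun_relative: Optional[CircularSummary] = None
    insufficient: bool = False


# ---------------------------------------------------------------------------
# per-individual analysis
# ---------------------------------------------------------------------------

def classify_conditions(meta: DeploymentMeta, site: eph.Site) -> Conditions:
    """Condition labels at the deployment midpoint.

    Tide phase is copied from metadata, never computed. Azimuths are
    converted to the magnetic frame by subtracting the site declination.
    """
    instant = meta.midpoint_utc
    moon = eph.moon_position(instant, site)
    sun = eph.sun_position(instant, site)
    return Conditions(
        moon_phase=moon.phase_label.value,
        tide_phase=meta.tide_phase,
        moon_above_horizon=moon.above_horizon,
        moon_azimuth=wrap_deg(moon.azimuth - site.magnetic_declination),
        sun_azimuth=wrap_deg(sun.azimuth - site.magnetic_declination),
        sun_above_horizon=sun.above_horizon,
    )


def analyze_individual(
    track: Track,
    compass: CompassSeries,
    cal: ChamberCalibration,
    meta: DeploymentMeta,
    site: eph.Site,
    alpha: float = ALPHA,
) -> IndividualResult:
    """Analyse one deployment end to end.

    Raises ``LowCoverageError`` when less than 80% of the analysis window
    is retained; batch drivers exclude such deployments with a logged
    reason.
    """
    cov = coverage_fraction(track, meta)
    if cov < MIN_COVERAGE_FRACTION:
        raise LowCoverageError(
            f"deployment '{meta.id}': coverage {cov:.0%} < "
            f"{MIN_COVERAGE_FRACTION:.0%}")
    conditions = classify_conditions(meta, site)
    bearings = bearings_from_track(track, compass, cal, meta)
    summary = rayleigh_test(bearings)
    _, mean_speed, median_speed = swimming_speed(track, cal, meta)
    moon_rel = sun_rel = None
    if summary.mean_bearing is not None:
        moon_rel = angular_difference(summary.mean_bearing,
                                      conditions.moon_azimuth)
        sun_rel = angular_difference(summary.mean_bearing,
                                     conditions.sun_azimuth)
    return IndividualResult(
        id=meta.id,
        magnetic=summary,
        moon_relative_bearing=moon_rel,
        sun_relative_bearing=sun_rel,
        significant=summary.p_value < alpha,
        mean_speed=mean_speed,
        median_speed=median_speed,
        conditions=conditions,
    )


class LowCoverageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# group-level analysis
# ---------------------------------------------------------------------------

def _group_summary(values: list[float], frame: Frame) -> Optional[CircularSummary]:
    if len(values) < 2:
        return None
    return rayleigh_second_order(AngleSeries(np.asarray(values), frame))


def _make_group(
    members: Sequence[IndividualResult],
    moon_phase: str,
    tide_phase: Optional[str],
    above: Optional[bool],
    sun_frame: bool,
) -> GroupResult:
    sig = [m for m in members
           if m.significant and m.magnetic.mean_bearing is not None]
    rbars = [m.magnetic.resultant_length for m in members]
    magnetic = _group_summary([m.magnetic.mean_bearing for m in sig],
                              Frame.MAGNETIC_NORTH)
    moon_rel = _group_summary([m.moon_relative_bearing for m in sig],
                              Frame.MOON_RELATIVE)
    sun_rel = None
    if sun_frame:
        sun_rel = _group_summary([m.sun_relative_bearing for m in sig],
                                 Frame.SUN_RELATIVE)
    return GroupResult(
        moon_phase=moon_phase,
        tide_phase=tide_phase,
        moon_above_horizon=above,
        n=len(sig),
        n_tested=len(members),
        magnetic=magnetic,
        moon_relative=moon_rel,
        prop_significant=(sum(m.significant for m in members) / len(members)
                          if members else float("nan")),
        mean_r=float(np.mean(rbars)) if rbars else float("nan"),
        sd_r=float(np.std(rbars, ddof=1)) if len(rbars) > 1 else float("nan"),
        sun_relative=sun_rel,
        insufficient=len(sig) < 2,
    )


def analyze_group(
    results: Sequence[IndividualResult],
    keys: Sequence[str] = GROUP_KEYS,
    pooled_phases: Sequence[str] = (),
    sun_frame: bool = False,
) -> list[GroupResult]:
    """Second-order analysis per condition cell, plus optional pooled rows.

    Circular summaries are restricted to individuals with a significant
    magnetic orientation; ``prop_significant`` and the Rbar distribution
    cover all tested individuals. Groups with fewer than 2 significant
    members are reported with ``insufficient=True``. ``pooled_phases``
    adds one pooled row per listed moon phase (all tide/horizon strata
    combined).
    """
    if not results:
        warnings.warn("no individual results; empty group list")
        return []

    def cell_of(res: IndividualResult):
        cond = res.conditions
        return tuple(getattr(cond, k) for k in keys)

    groups: list[GroupResult] = []
    cells: dict[tuple, list[IndividualResult]] = {}
    for res in results:
        cells.setdefault(cell_of(res), []).append(res)
    for cell in sorted(cells, key=lambda c: tuple(str(v) for v in c)):
        members = cells[cell]
        labels = dict(zip(keys, cell))
        groups.append(_make_group(
            members,
            moon_phase=str(labels.get("moon_phase", "all")),
            tide_phase=labels.get("tide_phase"),
            above=labels.get("moon_above_horizon"),
            sun_frame=sun_frame,
        ))
    for phase in pooled_phases:
        members = [r for r in results if r.conditions.moon_phase == phase]
        if not members:
            warnings.warn(f"pooled phase '{phase}' has no deployments")
            continue
        groups.append(_make_group(members, moon_phase=phase, tide_phase=None,
                                  above=None, sun_frame=sun_frame))
    return groups


def speed_contrast(
    results: Sequence[IndividualResult],
    split_key: str = "moon_above_horizon",
) -> RankTestResult:
    """Rank-sum comparison of per-individual mean speeds across a split."""
    above = [r.mean_speed for r in results
             if getattr(r.conditions, split_key)]
    below = [r.mean_speed for r in results
             if not getattr(r.conditions, split_key)]
    if not above or not below:
        raise ValueError(f"only one stratum present for '{split_key}'")
    return rank_sum_test(above, below)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt(value, digits=4):
    if value is None:
        return ""
    if isinstance(value, float) and not np.isfinite(value):
        return ""
    if isinstance(value, float):
        return f"{value:.{digits}g}"
    return str(value)


def _summary_columns(prefix: str, s: Optional[CircularSummary]) -> dict:
    if s is None:
        return {f"{prefix}_mean_bearing": "", f"{prefix}_r": "",
                f"{prefix}_p": ""}
    return {
        f"{prefix}_mean_bearing": _fmt(s.mean_bearing),
        f"{prefix}_r": _fmt(s.resultant_length),
        f"{prefix}_p": _fmt(s.p_value),
    }


def write_report(
    groups: Sequence[GroupResult],
    individuals: Sequence[IndividualResult],
    out_dir,
    config: Optional[dict] = None,
    speed: Optional[RankTestResult] = None,
) -> dict[str, Path]:
    """Write the group table, per-individual table and run log.

    Output is deterministic: same inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    group_rows = []
    for g in groups:
        row = {
            "moon_phase": g.moon_phase,
            "tide_phase": "" if g.tide_phase is None else g.tide_phase,
            "moon_above_horizon": ("" if g.moon_above_horizon is None
                                   else str(g.moon_above_horizon).lower()),
            "n": g.n,
            "n_tested": g.n_tested,
        }
        row.update(_summary_columns("magnetic", g.magnetic))
        row.update(_summary_columns("moon", g.moon_relative))
        if g.sun_relative is not None:
            row.update(_summary_columns("sun", g.sun_relative))
        row["prop_significant"] = _fmt(g.prop_significant)
        row["mean_r"] = _fmt(g.mean_r)
        row["sd_r"] = _fmt(g.sd_r)
        row["insufficient"] = str(g.insufficient).lower()
        group_rows.append(row)
    group_path = out_dir / "group_summary.tsv"
    if group_rows:
        pd.DataFrame(group_rows).to_csv(group_path, sep="\t", index=False)
    else:
        header = ["moon_phase", "tide_phase", "moon_above_horizon", "n",
                  "n_tested", "magnetic_mean_bearing", "magnetic_r",
                  "magnetic_p", "moon_mean_bearing", "moon_r", "moon_p",
                  "prop_significant", "mean_r", "sd_r", "insufficient"]
        group_path.write_text("\t".join(header) + "\n")

    ind_rows = []
    for r in sorted(individuals, key=lambda r: r.id):
        ind_rows.append({
            "id": r.id,
            "mean_bearing": _fmt(r.magnetic.mean_bearing),
            "r": _fmt(r.magnetic.resultant_length),
            "p": _fmt(r.magnetic.p_value),
            "n_bearings": r.magnetic.n,
            "significant": str(r.significant).lower(),
            "alpha_moon": _fmt(r.moon_relative_bearing),
            "alpha_sun": _fmt(r.sun_relative_bearing),
            "mean_speed_cms": _fmt(r.mean_speed),
            "median_speed_cms": _fmt(r.median_speed),
            "moon_phase": r.conditions.moon_phase,
            "tide_phase": r.conditions.tide_phase,
            "moon_above_horizon": str(r.conditions.moon_above_horizon).lower(),
            "moon_azimuth": _fmt(r.conditions.moon_azimuth),
        })
    ind_path = out_dir / "individuals.tsv"
    pd.DataFrame(ind_rows).to_csv(ind_path, sep="\t", index=False)

    log = {"version": __version__, "config": config or {},
           "n_individuals": len(individuals), "n_groups": len(groups)}
    if speed is not None:
        log["speed_contrast"] = {
            "statistic": speed.statistic, "p_value": speed.p_value,
            "method": speed.method, "n_above": speed.n1, "n_below": speed.n2,
            "median_above_cms": speed.median1, "median_below_cms": speed.median2,
        }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {"groups": group_path, "individuals": ind_path, "log": log_path}


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def run_analysis(
    manifest_path,
    out_dir=None,
    declination: float = 0.0,
    alpha: float = ALPHA,
    pooled_phases: Sequence[str] = (),
    sun_frame: bool = False,
):
    """Analyse every deployment listed in a manifest file.

    The manifest is a CSV with columns ``meta,track,compass`` (paths
    relative to the manifest's directory). Returns (individuals, groups,
    speed contrast or None, list of exclusions).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    for col in ("meta", "track", "compass"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column '{col}'")

    individuals: list[IndividualResult] = []
    exclusions: list[str] = []
    for _, row in manifest.iterrows():
        meta, cal = read_meta(base / row["meta"])
        site = eph.Site(meta.latitude, meta.longitude, declination)
        track = read_track(base / row["track"], id=meta.id)
        compass = read_compass(base / row["compass"])
        try:
            individuals.append(
                analyze_individual(track, compass, cal, meta, site,
                                   alpha=alpha))
        except LowCoverageError as exc:
            exclusions.append(str(exc))

    groups = analyze_group(individuals, pooled_phases=pooled_phases,
                           sun_frame=sun_frame)
    speed = None
    strata = {r.conditions.moon_above_horizon for r in individuals}
    if len(strata) == 2:
        speed = speed_contrast(individuals)
    if out_dir is not None:
        config = {"manifest": str(manifest_path), "declination": declination,
                  "alpha": alpha, "pooled_phases": list(pooled_phases),
                  "sun_frame": sun_frame, "exclusions": exclusions}
        write_report(groups, individuals, out_dir, config=config, speed=speed)
    return individuals, groups, speed, exclusions
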