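from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from driftorient import ephemeris as eph
from driftorient import synthetic as syn
from driftorient.tracks import ChamberCalibration, DeploymentMeta

AUSTEVOLL = eph.Site(60.09, 5.28)


@pytest.fixture
def site():
    return AUSTEVOLL


@pytest.fixture
def cal():
    return ChamberCalibration(center_x=512.0, center_y=512.0,
                              radius_px=400.0, radius_cm=20.0)


@pytest.fixture
def meta():
    return DeploymentMeta(
        id="dep0000",
        utc_start=datetime(2015, 4, 19, 10, 0, tzinfo=timezone.utc),
        latitude=60.09,
        longitude=5.28,
        tide_phase="ebb",
        site_name="Langenuen",
    )


def make_calendar(start, n, spacing_min=20.0, lat=60.09, lon=5.28,
                  tide_phase="ebb"):
    return [
        syn.DeploymentSpec(
            utc_start=start + timedelta(minutes=spacing_min * i),
            latitude=lat, longitude=lon, tide_phase=tide_phase)
        for i in range(n)
    ]


@pytest.fixture
def make_deployment(meta, cal):
    """Factory producing (track, compass, hidden, meta, cal) tuples."""

    def _make(truth=None, counter=0, moon_azimuth=None, **truth_kwargs):
        if truth is None:
            truth = syn.SyntheticTruth(**truth_kwargs)
        track, compass, hidden = syn.simulate_deployment(
            truth, meta, cal=cal, moon_azimuth=moon_azimuth, counter=counter)
        return track, compass, hidden, meta, cal

    return _make
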