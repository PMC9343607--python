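import numpy as np
import pytest

from spherosort.geometry import SpheroidGeometry
from spherosort.tracks import Spot, Track


@pytest.fixture
def circle_geom() -> SpheroidGeometry:
    return SpheroidGeometry(center=(0.0, 0.0), a=100.0, b=100.0)


@pytest.fixture
def ellipse_geom() -> SpheroidGeometry:
    return SpheroidGeometry(center=(0.0, 0.0), a=120.0, b=80.0)


@pytest.fixture
def rotated_ellipse_geom() -> SpheroidGeometry:
    return SpheroidGeometry(center=(50.0, -30.0), a=150.0, b=90.0, phi0_axis=0.7)


def make_track(positions, dt=10.0, track_id="t0", population="", start_frame=0):
    """Track from a list of (x, y) with uniform frame spacing."""
    spots = [
        Spot(frame=start_frame + i, t=(start_frame + i) * dt, x=float(x), y=float(y))
        for i, (x, y) in enumerate(positions)
    ]
    return Track(track_id=track_id, spots=spots, population=population)


@pytest.fixture
def straight_track():
    return make_track([(0, 0), (10, 0), (20, 0), (30, 0)])
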