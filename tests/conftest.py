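import numpy as np
import pytest

from mtlumen import FilamentTrace, build_domain


def straight_trace(length=1000.0, spacing=20.0, mt_id=0, origin=(0.0, 0.0, 0.0),
                   direction=(1.0, 0.0, 0.0)):
    """Axis-aligned straight resampled trace."""
    n = int(round(length / spacing)) + 1
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    pts = np.asarray(origin, dtype=float) + np.arange(n)[:, None] * spacing * d
    return FilamentTrace(mt_id=mt_id, points=pts, resampled=True, spacing=spacing)


def segment_trace(length=1000.0, mt_id=0):
    """Straight trace stored as a single segment (cheapest exact geometry)."""
    return FilamentTrace(mt_id=mt_id, points=[[0.0, 0.0, 0.0], [length, 0.0, 0.0]],
                         resampled=True, spacing=length)


@pytest.fixture
def straight_domain():
    return build_domain(straight_trace(), 8.5)


@pytest.fixture
def segment_domain():
    return build_domain(segment_trace(), 8.5)
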