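import numpy as np
import pandas as pd
import pytest

from clingaze.io import default_roi_hierarchy
from clingaze.synthetic import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def hierarchy():
    return default_roi_hierarchy()


@pytest.fixture(scope="session")
def small_experiment():
    """A fully realized scaled experiment: 4 physicians, 25 s trials."""
    cfg = GeneratorConfig(
        n_participants=4, trial_duration_s=25.0, trial_duration_sd_s=4.0, seed=42,
    )
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def planned_experiment():
    """Event-level plan at the full study design (19 physicians, 324 s)."""
    cfg = GeneratorConfig(seed=7)
    return generate_experiment(cfg, realize=False)


def make_gaze(t, x, y, confidence=None):
    t = np.asarray(t, float)
    if confidence is None:
        confidence = np.ones(len(t))
    return pd.DataFrame({
        "t_ms": t,
        "x": np.broadcast_to(np.asarray(x, float), t.shape).copy(),
        "y": np.broadcast_to(np.asarray(y, float), t.shape).copy(),
        "confidence": np.broadcast_to(np.asarray(confidence, float), t.shape).copy(),
    })


def make_static_tracks(boxes, t_end=60_000.0, dt=1000.0):
    """Track table with constant boxes observed every ``dt`` ms."""
    times = np.arange(0.0, t_end + dt, dt)
    rows = []
    for rid, (x0, y0, x1, y1) in boxes.items():
        for t in times:
            rows.append((t, rid, x0, y0, x1, y1, True))
    return pd.DataFrame(
        rows, columns=["t_ms", "roi_id", "x_min", "y_min", "x_max", "y_max", "visible"])
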