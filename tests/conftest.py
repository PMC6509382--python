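import numpy as np
import pandas as pd
import pytest


def make_fixes(rows):
    """Telemetry frame from (animal_id, herd, iso_time, x, y) tuples."""
    df = pd.DataFrame(rows, columns=["animal_id", "herd", "timestamp", "x", "y"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def walk_fixes(animal="a", herd="h", start="2020-01-20", n=10, speed=200.0, dt_hr=2):
    """A clean straight-line track moving ``speed`` m/hr."""
    times = pd.date_range(start, periods=n, freq=f"{dt_hr}h", tz="UTC")
    x = np.arange(n) * speed * dt_hr
    return make_fixes(
        [(animal, herd, t, xi, 0.0) for t, xi in zip(times, x)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
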