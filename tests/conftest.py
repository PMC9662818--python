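import numpy as np
import pytest

from socialchamber import pipeline, synthdata
from socialchamber.core import SessionLayout, TrackingSeries


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-unit mixed experiment with strongly modulated social neurons."""
    config = synthdata.SimulationConfig(
        n_units=12, social_neuron_fraction=0.5, decreasing_fraction=0.3)
    return synthdata.simulate_experiment(config, seed=2)


@pytest.fixture(scope="session")
def small_events(small_bundle):
    return pipeline.extract_events(small_bundle)


@pytest.fixture(scope="session")
def default_layout():
    return SessionLayout()


def make_track(nose_xy, tail_xy=None, n_frames=120, fps=30.0, t0=0.0,
               session="EE", likelihood=1.0, extra_parts=None):
    """Tracking series with constant (or per-frame) part positions."""
    def expand(xy):
        xy = np.asarray(xy, dtype=float)
        if xy.ndim == 1:
            xy = np.tile(xy, (n_frames, 1))
        lk = np.full((len(xy), 1), likelihood)
        return np.hstack([xy, lk])

    nose = expand(nose_xy)
    tail = expand(tail_xy if tail_xy is not None else nose_xy)
    parts = {"nose": nose, "tail_base": tail}
    if extra_parts:
        parts.update({k: expand(v) for k, v in extra_parts.items()})
    ts = t0 + np.arange(len(nose)) / fps
    return TrackingSeries(session=session, timestamps=ts, parts=parts)
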