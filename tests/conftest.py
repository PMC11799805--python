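import numpy as np
import pytest

from scanpathml.gaze_model import Fixation, GazeDataset, Trial


def make_trial(
    points,
    *,
    trial_id="t1",
    participant_id="p1",
    label="faculty",
    display=(300.0, 300.0),
    onsets=None,
    durations=None,
    valid=None,
):
    """Build a trial from a list of (x, y) points with simple timing."""
    n = len(points)
    onsets = list(onsets) if onsets is not None else [0.5 * i for i in range(n)]
    durations = list(durations) if durations is not None else [0.3] * n
    valid = list(valid) if valid is not None else [True] * n
    fixes = tuple(
        Fixation(x=float(x), y=float(y), onset=float(o), duration=float(d), valid=v)
        for (x, y), o, d, v in zip(points, onsets, durations, valid)
    )
    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        label=label,
        display_w=float(display[0]),
        display_h=float(display[1]),
        fixations=fixes,
    )


def make_dataset(trials, device="other"):
    return GazeDataset(device=device, trials=tuple(trials))


def random_trial(rng, *, display=(300.0, 300.0), n_max=60, oob=False, **kw):
    """A random trial; with oob=True some points may fall off-display."""
    n = int(rng.integers(1, n_max + 1))
    lo, hi = (-100.0, display[0] + 100.0) if oob else (0.0, display[0])
    xs = rng.uniform(lo, hi, n)
    ys = rng.uniform(
        -100.0 if oob else 0.0, display[1] + (100.0 if oob else 0.0), n
    )
    durs = rng.uniform(0.05, 0.5, n)
    gaps = rng.uniform(0.0, 0.1, n)
    onsets = np.concatenate([[0.0], np.cumsum(durs + gaps)[:-1]])
    return make_trial(
        list(zip(xs, ys)), display=display, onsets=onsets, durations=durs, **kw
    )


@pytest.fixture(scope="session")
def eyelink_ds():
    """Session-shared synthetic dataset at the default study conditions."""
    from scanpathml.synthetic import preset_config, simulate_dataset

    return simulate_dataset(preset_config("eyelink_like", seed=1, separation=0.8))
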