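"""Synthetic two-class scanpath generator.

Stands in for non-deposited clinical eye-tracking data.  Two behavioural
archetypes over a fixed display emulate the qualitative expertise contrast
reported for radiograph reading:

- **faculty** (expert): a broad, systematically distributed search — a
  large share of fixations follow a left-to-right, top-to-bottom sweep,
  the remainder visit many dispersed, loose clusters, with few returns;
- **trainee**: a focal search concentrated on a few tight suspected-
  abnormality clusters with frequent revisits and little sweeping.

A scalar ``separation`` in [0, 1] interpolates every archetype parameter
between a common midpoint (separation 0: the classes are statistically
identical, so any classifier is at chance) and the full contrast above.
Fixation-count and duration models are shared by the two classes at every
separation, so the class signal is carried by the spatial/sequential
structure rather than by trivial scalar summaries.

Two presets mirror typical acquisition set-ups: ``eyelink_like``
(pre-filtered fixations; 1 participant per class x 55 trials = 110 trials)
and ``tobii_like`` (raw ~33 Hz gaze samples treated as fixations; 4 per
class x 27 trials = 216 trials, more samples and more position noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .gaze_model import FACULTY, TRAINEE, Fixation, GazeDataset, Trial

__all__ = [
    "ArchetypeParams",
    "SimulationConfig",
    "PRESETS",
    "archetypes",
    "simulate_trial",
    "simulate_dataset",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters of one expertise archetype.

    Spatial quantities are display fractions; durations are seconds;
    ``jitter_sd`` is measurement noise in pixels.
    """

    n_fix_mean: float
    n_fix_dispersion: float  # negative-binomial size parameter r
    cluster_means: np.ndarray  # (K, 2) display fractions
    cluster_sd: float  # isotropic sd, fraction of min(display)
    cluster_weights: np.ndarray  # (K,), sums to 1
    sweep_weight: float  # P(fixation follows the raster sweep)
    revisit_prob: float  # P(cluster move returns to a visited cluster)
    dur_mean: float
    dur_sd: float
    gap_mean: float  # inter-fixation (saccade) gap, seconds
    jitter_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cluster_means", np.asarray(self.cluster_means, dtype=float)
        )
        w = np.asarray(self.cluster_weights, dtype=float)
        object.__setattr__(self, "cluster_weights", w)
        if not np.isclose(w.sum(), 1.0):
            raise ConfigError(f"cluster weights must sum to 1, got {w.sum()}")
        if self.cluster_sd <= 0 or self.dur_mean <= 0:
            raise ConfigError("cluster_sd and dur_mean must be > 0")
        for name in ("sweep_weight", "revisit_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """One synthetic acquisition."""

    preset: Literal["eyelink_like", "tobii_like", "custom"] = "eyelink_like"
    n_participants_per_class: int = 1
    trials_per_participant: int = 55
    display_w: float = 1280.0
    display_h: float = 1024.0
    separation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.separation <= 1:
            raise ConfigError(
                f"separation must be in [0, 1], got {self.separation}"
            )
        if self.n_participants_per_class < 0 or self.trials_per_participant < 0:
            raise ConfigError("counts must be >= 0")


#: preset -> (participants per class, trials per participant, gaze_like)
PRESETS: dict[str, tuple[int, int, bool]] = {
    "eyelink_like": (1, 55, False),
    "tobii_like": (4, 27, True),
}


def preset_config(
    preset: str, seed: int = 0, separation: float = 0.8
) -> SimulationConfig:
    """A :class:`SimulationConfig` matching a named preset."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    npc, tpp, _ = PRESETS[preset]
    return SimulationConfig(
        preset=preset,  # type: ignore[arg-type]
        n_participants_per_class=npc,
        trials_per_participant=tpp,
        separation=separation,
        seed=seed,
    )


# Cluster anchor positions (display fractions): a rough pair of lung fields
# with mediastinal and basal anchors, the layout a chest-film reader scans.
_BASE_MEANS = np.array(
    [
        [0.30, 0.30],
        [0.70, 0.30],
        [0.30, 0.55],
        [0.70, 0.55],
        [0.38, 0.78],
        [0.62, 0.78],
    ]
)
_K = len(_BASE_MEANS)

# trainee endpoint: mass on two suspected-abnormality clusters
_TRAINEE_WEIGHTS = np.array([0.42, 0.42, 0.04, 0.04, 0.04, 0.04])


def _lerp(a, b, s):
    return a + (np.asarray(b) - np.asarray(a)) * s


def archetypes(
    separation: float, *, gaze_like: bool = False
) -> tuple[ArchetypeParams, ArchetypeParams]:
    """(faculty, trainee) archetypes at the given class separation.

    At separation 0 the two are identical field-for-field; every parameter
    interpolates linearly toward the full contrast at separation 1.
    ``gaze_like`` switches count/duration/noise models to raw ~33 Hz gaze
    samples instead of detected fixations.
    """
    if not 0 <= separation <= 1:
        raise ConfigError(f"separation must be in [0, 1], got {separation}")
    s = float(separation)

    if gaze_like:
        count = dict(n_fix_mean=320.0, n_fix_dispersion=24.0)
        timing = dict(dur_mean=1 / 33, dur_sd=0.0, gap_mean=0.0)
        jitter = 16.0
    else:
        count = dict(n_fix_mean=42.0, n_fix_dispersion=14.0)
        timing = dict(dur_mean=0.26, dur_sd=0.08, gap_mean=0.03)
        jitter = 3.0

    base = dict(
        cluster_means=_BASE_MEANS,
        cluster_sd=0.075,
        cluster_weights=np.full(_K, 1.0 / _K),
        sweep_weight=0.30,
        revisit_prob=0.30,
        jitter_sd=jitter,
        **count,
        **timing,
    )

    faculty = ArchetypeParams(
        cluster_means=_lerp(_BASE_MEANS, _BASE_MEANS + (_BASE_MEANS - 0.5) * 0.45, s),
        cluster_sd=float(_lerp(base["cluster_sd"], 0.13, s)),
        cluster_weights=np.full(_K, 1.0 / _K),
        sweep_weight=float(_lerp(base["sweep_weight"], 0.62, s)),
        revisit_prob=float(_lerp(base["revisit_prob"], 0.08, s)),
        jitter_sd=jitter,
        **count,
        **timing,
    )
    trainee = ArchetypeParams(
        cluster_means=_BASE_MEANS,
        cluster_sd=float(_lerp(base["cluster_sd"], 0.032, s)),
        cluster_weights=_lerp(base["cluster_weights"], _TRAINEE_WEIGHTS, s),
        sweep_weight=float(_lerp(base["sweep_weight"], 0.04, s)),
        revisit_prob=float(_lerp(base["revisit_prob"], 0.55, s)),
        jitter_sd=jitter,
        **count,
        **timing,
    )
    return faculty, trainee


_SWEEP_ROWS = 3  # raster rows of the systematic sweep component


def simulate_trial(
    params: ArchetypeParams,
    display_w: float,
    display_h: float,
    rng: np.random.Generator,
    *,
    trial_id: str = "t0",
    participant_id: str = "p0",
    label: str = FACULTY,
) -> Trial:
    """Draw one trial from an archetype (fully determined by ``rng``)."""
    r = params.n_fix_dispersion
    p = r / (r + params.n_fix_mean)
    n = max(1, int(rng.negative_binomial(r, p)))

    # Trial-level behavioural variability: a reader's sweep share, revisit
    # tendency and cluster spread fluctuate from image to image, so scalar
    # summaries (path length, coverage, regressions) overlap across trials
    # while the spatial layout of the archetype stays distinctive.
    sweep_w = _beta_around(rng, params.sweep_weight, concentration=5.0)
    revisit_p = _beta_around(rng, params.revisit_prob, concentration=5.0)
    cluster_sd = params.cluster_sd * rng.lognormal(0.0, 0.3)

    scale = min(display_w, display_h)
    visited: list[int] = []
    xs = np.empty(n)
    ys = np.empty(n)
    for k in range(n):
        if rng.random() < sweep_w:
            # systematic raster: left-to-right within top-to-bottom rows
            prog = k / max(n - 1, 1)
            row = min(int(prog * _SWEEP_ROWS), _SWEEP_ROWS - 1)
            within = prog * _SWEEP_ROWS - row
            mu_x = within * display_w
            mu_y = (row + 0.5) / _SWEEP_ROWS * display_h
            sd = 0.05 * scale
        else:
            if visited and rng.random() < revisit_p:
                c = visited[int(rng.integers(len(visited)))]
            else:
                c = int(rng.choice(_K_of(params), p=params.cluster_weights))
            visited.append(c)
            mu_x = params.cluster_means[c, 0] * display_w
            mu_y = params.cluster_means[c, 1] * display_h
            sd = cluster_sd * scale
        xs[k] = rng.normal(mu_x, sd) + rng.normal(0.0, params.jitter_sd)
        ys[k] = rng.normal(mu_y, sd) + rng.normal(0.0, params.jitter_sd)

    np.clip(xs, 0.0, display_w, out=xs)
    np.clip(ys, 0.0, display_h, out=ys)

    if params.dur_sd > 0:
        durs = np.maximum(rng.normal(params.dur_mean, params.dur_sd, n), 0.03)
    else:
        durs = np.full(n, params.dur_mean)
    gaps = (
        rng.uniform(0.5 * params.gap_mean, 1.5 * params.gap_mean, n)
        if params.gap_mean > 0
        else np.zeros(n)
    )
    onsets = np.concatenate([[0.0], np.cumsum(durs + gaps)[:-1]])

    fixes = tuple(
        Fixation(x=float(xs[k]), y=float(ys[k]), onset=float(onsets[k]),
                 duration=float(durs[k]))
        for k in range(n)
    )
    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        label=label,
        display_w=display_w,
        display_h=display_h,
        fixations=fixes,
    )


def _K_of(params: ArchetypeParams) -> int:
    return len(params.cluster_weights)


def _beta_around(rng: np.random.Generator, mean: float, concentration: float) -> float:
    """Beta draw with the given mean; degenerate means (0 or 1) pass through."""
    if mean <= 0.0 or mean >= 1.0:
        return float(mean)
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


def simulate_dataset(config: SimulationConfig) -> GazeDataset:
    """Generate a full labelled dataset, reproducible from ``config.seed``.

    One seed stream is split per trial (counter-based spawning), so trials
    are independent and the dataset is bit-identical across runs.
    """
    gaze_like = PRESETS.get(config.preset, (0, 0, False))[2]
    faculty, trainee = archetypes(config.separation, gaze_like=gaze_like)
    root = np.random.SeedSequence(config.seed)

    n_trials_total = 2 * config.n_participants_per_class * config.trials_per_participant
    children = root.spawn(n_trials_total) if n_trials_total else []

    trials: list[Trial] = []
    counter = 0
    for label, params in ((FACULTY, faculty), (TRAINEE, trainee)):
        for pi in range(config.n_participants_per_class):
            pid = f"{label}_{pi + 1}"
            for j in range(config.trials_per_participant):
                rng = np.random.default_rng(children[counter])
                trials.append(
                    simulate_trial(
                        params,
                        config.display_w,
                        config.display_h,
                        rng,
                        trial_id=f"{pid}_img{j + 1:03d}",
                        participant_id=pid,
                        label=label,
                    )
                )
                counter += 1
    device = config.preset if config.preset in PRESETS else "other"
    return GazeDataset(device=device, trials=tuple(trials))
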