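"""Data model for fixation/gaze recordings.

A *fixation* is a period during which gaze rests near one display location;
an ordered sequence of fixations over one stimulus is a *scanpath*, recorded
here as a :class:`Trial`.  A :class:`GazeDataset` bundles the trials of one
acquisition (one eye tracker, one display geometry).

Coordinate convention (used consistently throughout the package): the origin
is the **top-left** corner of the display, ``x`` increases rightward and
``y`` increases downward, both in pixels.  Time is in seconds from trial
start.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FACULTY = "faculty"
TRAINEE = "trainee"
LABELS = (FACULTY, TRAINEE)

#: default column names of the fixation CSV schema
DEFAULT_COLUMNS = {
    "trial": "trial_id",
    "participant": "participant_id",
    "label": "label",
    "x": "x",
    "y": "y",
    "onset": "onset_s",
    "duration": "duration_s",
    "valid": "valid",
    "display_w": "display_w",
    "display_h": "display_h",
}

REQUIRED_FIELDS = ("trial", "participant", "label", "x", "y", "onset", "duration")


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ParseError(ValueError):
    """A cell could not be parsed (reported with its row number)."""


class LabelError(ValueError):
    """An expertise label is not one of the two known classes."""


class GeometryError(ValueError):
    """Display extent missing or non-positive."""


@dataclass(frozen=True)
class Fixation:
    """One fixation: display position, onset and duration, artifact flag."""

    x: float
    y: float
    onset: float
    duration: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ValueError(f"fixation duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class Trial:
    """An ordered fixation sequence with participant identity and geometry."""

    trial_id: str
    participant_id: str
    label: str
    display_w: float
    display_h: float
    fixations: tuple[Fixation, ...]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise LabelError(
                f"trial {self.trial_id!r}: label {self.label!r} not in {LABELS}"
            )
        if self.display_w <= 0 or self.display_h <= 0:
            raise GeometryError(
                f"trial {self.trial_id!r}: display extent must be positive, "
                f"got {self.display_w}x{self.display_h}"
            )
        onsets = [f.onset for f in self.fixations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(
                f"trial {self.trial_id!r}: fixations must be sorted by onset"
            )
        object.__setattr__(self, "fixations", tuple(self.fixations))

    def __len__(self) -> int:
        return len(self.fixations)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of fixation coordinates."""
        if not self.fixations:
            return np.empty((0, 2), dtype=float)
        return np.array([(f.x, f.y) for f in self.fixations], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([f.onset for f in self.fixations], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)


@dataclass(frozen=True)
class GazeDataset:
    """Trials from one acquisition device."""

    device: str
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    @property
    def participants(self) -> np.ndarray:
        return np.array([t.participant_id for t in self.trials])

    @property
    def trial_ids(self) -> np.ndarray:
        return np.array([t.trial_id for t in self.trials])

    @property
    def display(self) -> tuple[float, float]:
        """Shared display extent (w, h); raises on a mixed-geometry dataset."""
        geoms = {(t.display_w, t.display_h) for t in self.trials}
        if len(geoms) > 1:
            raise GeometryError(f"mixed display geometries in dataset: {geoms}")
        if not geoms:
            raise GeometryError("empty dataset has no display geometry")
        return next(iter(geoms))


@dataclass(frozen=True)
class Dialect:
    """Column mapping and unit declaration for delimited fixation tables.

    ``columns`` maps logical field names (keys of :data:`DEFAULT_COLUMNS`)
    to the actual column names in the file; unmapped fields fall back to the
    defaults.  ``time_unit`` is ``"s"`` or ``"ms"`` (milliseconds are
    converted to seconds on read).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    time_unit: str = "s"

    def __post_init__(self) -> None:
        if self.time_unit not in ("s", "ms"):
            raise ValueError(f"time_unit must be 's' or 'ms', got {self.time_unit!r}")
        unknown = set(self.columns) - set(DEFAULT_COLUMNS)
        if unknown:
            raise SchemaError(f"unknown dialect fields: {sorted(unknown)}")

    def column(self, logical: str) -> str:
        return self.columns.get(logical, DEFAULT_COLUMNS[logical])


def _parse_numeric(df: pd.DataFrame, col: str, what: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any() or vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise ParseError(
            f"non-numeric {what} in column {col!r} at data row {row + 1} "
            f"(value {df[col].iloc[row]!r})"
        )
    return vals.to_numpy(dtype=float)


def read_fixation_table(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    device: str = "other",
    display: tuple[float, float] | None = None,
) -> GazeDataset:
    """Read a delimited fixation table into a :class:`GazeDataset`.

    Fixations are grouped by trial and stably sorted by onset (ties keep
    file order).  Display extent is taken from the optional
    ``display_w``/``display_h`` columns, else from the ``display`` argument.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    df = pd.read_csv(path)

    for logical in REQUIRED_FIELDS:
        col = dialect.column(logical)
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} (field {logical!r})")

    scale = 1e-3 if dialect.time_unit == "ms" else 1.0
    x = _parse_numeric(df, dialect.column("x"), "coordinate")
    y = _parse_numeric(df, dialect.column("y"), "coordinate")
    onset = _parse_numeric(df, dialect.column("onset"), "onset") * scale
    dur = _parse_numeric(df, dialect.column("duration"), "duration") * scale

    labels = df[dialect.column("label")].astype(str).to_numpy()
    bad_labels = sorted(set(labels) - set(LABELS))
    if bad_labels:
        raise LabelError(f"unknown label value(s) {bad_labels}; expected {LABELS}")

    vcol = dialect.column("valid")
    if vcol in df.columns:
        valid = (
            df[vcol]
            .map({1: True, 0: False, "1": True, "0": False, True: True, False: False})
            .fillna(True)
            .to_numpy(dtype=bool)
        )
    else:
        valid = np.ones(len(df), dtype=bool)

    wcol, hcol = dialect.column("display_w"), dialect.column("display_h")
    if wcol in df.columns and hcol in df.columns:
        disp_w = _parse_numeric(df, wcol, "display width")
        disp_h = _parse_numeric(df, hcol, "display height")
    elif display is not None:
        disp_w = np.full(len(df), float(display[0]))
        disp_h = np.full(len(df), float(display[1]))
    else:
        raise GeometryError(
            "no display_w/display_h columns and no display= argument given"
        )

    trial_col = df[dialect.column("trial")].astype(str)
    part_col = df[dialect.column("participant")].astype(str)

    trials: list[Trial] = []
    for tid in trial_col.drop_duplicates():  # first-appearance order
        idx = np.flatnonzero((trial_col == tid).to_numpy())
        idx = idx[np.argsort(onset[idx], kind="stable")]
        parts = set(part_col.iloc[idx])
        labs = set(labels[idx])
        if len(parts) > 1 or len(labs) > 1:
            raise ParseError(
                f"trial {tid!r} has inconsistent participant/label rows"
            )
        fixes = tuple(
            Fixation(x[i], y[i], onset[i], dur[i], bool(valid[i])) for i in idx
        )
        trials.append(
            Trial(
                trial_id=tid,
                participant_id=part_col.iloc[idx[0]],
                label=labels[idx[0]],
                display_w=float(disp_w[idx[0]]),
                display_h=float(disp_h[idx[0]]),
                fixations=fixes,
            )
        )
    return GazeDataset(device=device, trials=tuple(trials))


def write_fixation_table(ds: GazeDataset, path: str | Path) -> None:
    """Write a dataset in the default fixation CSV schema (round-trips)."""
    rows = []
    for t in ds.trials:
        for f in t.fixations:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "participant_id": t.participant_id,
                    "label": t.label,
                    "x": f.x,
                    "y": f.y,
                    "onset_s": f.onset,
                    "duration_s": f.duration,
                    "valid": int(f.valid),
                    "display_w": t.display_w,
                    "display_h": t.display_h,
                }
            )
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values())).to_csv(
        path, index=False
    )


def filter_artifacts(trial: Trial, margin: float = 0.0) -> Trial:
    """Remove flagged-invalid and off-display fixations.

    A fixation survives iff ``valid`` is true and (x, y) lies inside
    ``[-margin, display_w + margin] x [-margin, display_h + margin]``.
    Ordering is preserved; the input trial is not modified.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    lo_x, hi_x = -margin, trial.display_w + margin
    lo_y, hi_y = -margin, trial.display_h + margin
    kept = tuple(
        f
        for f in trial.fixations
        if f.valid and lo_x <= f.x <= hi_x and lo_y <= f.y <= hi_y
    )
    if not kept and trial.fixations:
        logger.warning(
            "trial %s: all %d fixations removed by artifact filtering",
            trial.trial_id,
            len(trial.fixations),
        )
    return dataclasses.replace(trial, fixations=kept)


@dataclass
class ValidationReport:
    """Counts and consistency findings for one dataset (never raises)."""

    n_trials: int
    trials_per_participant: dict[str, int]
    trials_per_class: dict[str, int]
    participant_classes: dict[str, set[str]]
    empty_trials: list[str]
    geometries: set[tuple[float, float]]
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(ds: GazeDataset) -> ValidationReport:
    """Check counts, geometry and participant/class consistency."""
    per_part: dict[str, int] = {}
    per_class: dict[str, int] = {}
    part_classes: dict[str, set[str]] = {}
    empty: list[str] = []
    geoms: set[tuple[float, float]] = set()
    for t in ds.trials:
        per_part[t.participant_id] = per_part.get(t.participant_id, 0) + 1
        per_class[t.label] = per_class.get(t.label, 0) + 1
        part_classes.setdefault(t.participant_id, set()).add(t.label)
        if not t.fixations:
            empty.append(t.trial_id)
        geoms.add((t.display_w, t.display_h))

    issues: list[str] = []
    if len(geoms) > 1:
        issues.append(f"mixed display geometries: {sorted(geoms)}")
    for pid, classes in part_classes.items():
        if len(classes) > 1:
            issues.append(
                f"participant {pid!r} appears under multiple classes: "
                f"{sorted(classes)}"
            )
    if empty:
        issues.append(f"{len(empty)} empty trial(s): {empty[:5]}")

    return ValidationReport(
        n_trials=len(ds.trials),
        trials_per_participant=per_part,
        trials_per_class=per_class,
        participant_classes=part_classes,
        empty_trials=empty,
        geometries=geoms,
        issues=issues,
    )
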