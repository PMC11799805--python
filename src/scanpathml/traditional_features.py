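"""The curated "traditional" gaze feature baseline.

Five per-trial attributes repeatedly associated with reader expertise in the
visual-expertise literature: total scan time, fixation count, regressive
fixation count, total saccade length, and coverage of the salient image
area.  Attributes that require ground-truth abnormality locations
(area-of-interest dwell/fixation/time-to-first-fixation features) are
deliberately excluded: they need manual expert annotation and do not scale.

Definitions used here where the literature leaves room:

- *regressive fixation*: a fixation landing in a location-grid cell visited
  earlier in the trial after at least one intervening fixation in a
  different cell (consecutive same-cell fixations are dwell, not
  regression).  The location grid defaults to 5x5 over the display.
- *saccade length*: Euclidean distance between consecutive fixation
  positions (spatial path length).
- *coverage*: fraction of the salient pixel area lying within radius ``r``
  of at least one fixation; ``r`` defaults to 2% of the display diagonal,
  roughly the 1-degree accuracy of a desktop eye tracker.  Salient pixels
  are the image content excluding the peripheral black background; with no
  image available the whole display counts as salient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .encoder import CellGrid, EncodingConfig, assign_cells, cell_centroids
from .gaze_model import GazeDataset, Trial

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "total_time_s",
    "fixation_count",
    "regressive_count",
    "saccade_length_px",
    "coverage",
]


class DegenerateMaskError(ValueError):
    """The salient mask would be empty (e.g. an all-black image)."""


@dataclass(frozen=True)
class TraditionalFeatures:
    total_time: float
    fixation_count: int
    regressive_fixation_count: int
    total_saccade_length: float
    coverage: float

    def as_row(self) -> list[float]:
        return [
            self.total_time,
            self.fixation_count,
            self.regressive_fixation_count,
            self.total_saccade_length,
            self.coverage,
        ]


@dataclass(frozen=True)
class SalientMask:
    """Boolean mask (rows = y, cols = x) of salient display pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if not m.any():
            raise DegenerateMaskError("salient mask is empty")

    @property
    def salient_area(self) -> int:
        return int(self.mask.sum())


def total_scan_time(trial: Trial) -> float:
    """Span from first onset to last offset, in seconds (0 if empty)."""
    if not trial.fixations:
        return 0.0
    first = trial.fixations[0]
    last = trial.fixations[-1]
    return (last.onset + last.duration) - first.onset


def fixation_count(trial: Trial) -> int:
    return len(trial.fixations)


def regressive_fixation_count(trial: Trial, loc_grid: CellGrid) -> int:
    """Fixations returning to a previously visited location-grid cell.

    A return requires at least one intervening fixation in a different
    cell; a run of consecutive fixations in one cell counts as dwell.
    """
    if len(loc_grid) == 0:
        raise ValueError("location grid is empty")
    cells = assign_cells(trial.xy, loc_grid)
    count = 0
    seen: set[int] = set()
    prev: int | None = None
    for c in map(int, cells):
        if prev is not None and c != prev and c in seen:
            count += 1
        seen.add(c)
        prev = c
    return count


def total_saccade_length(trial: Trial) -> float:
    """Sum of Euclidean distances between consecutive fixations (pixels)."""
    xy = trial.xy
    if len(xy) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())


def full_display_mask(display_w: float, display_h: float) -> SalientMask:
    """Whole-display salient mask used when no image is available."""
    return SalientMask(np.ones((int(round(display_h)), int(round(display_w))), bool))


def salient_mask_from_image(image: np.ndarray, threshold: float = 0.05) -> SalientMask:
    """Salient region of a grayscale image: content minus black border.

    Pixels brighter than ``threshold`` (after normalising to [0, 1]) are
    foreground; the foreground is morphologically closed and the bounding
    box of its largest connected component becomes the salient mask.  The
    box, not the thresholded set, is kept so dark structures inside the
    radiograph (lung fields) remain salient while the peripheral black
    frame is removed.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if img.max() > 1.0:
        img = img / 255.0
    fg = img > threshold
    if not fg.any():
        raise DegenerateMaskError("image is entirely background at this threshold")
    closed = ndimage.binary_closing(fg, structure=np.ones((3, 3), bool))
    closed |= fg  # closing with a border can only shrink at edges; keep fg
    labels, n = ndimage.label(closed)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    sl = ndimage.find_objects(labels)[largest - 1]
    mask = np.zeros_like(fg)
    mask[sl] = True
    return SalientMask(mask)


def coverage(trial: Trial, mask: SalientMask, radius: float) -> float:
    """Fraction of salient pixels within ``radius`` of any fixation."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    xy = trial.xy
    if len(xy) == 0:
        return 0.0
    h, w = mask.mask.shape
    covered = np.zeros((h, w), dtype=bool)
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = (dx * dx + dy * dy) <= radius * radius
    for px, py in xy:
        cx, cy = int(round(px)), int(round(py))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        covered[y0:y1, x0:x1] |= disc[
            y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)
        ]
    return float((covered & mask.mask).sum() / mask.salient_area)


def default_radius(display_w: float, display_h: float) -> float:
    """Coverage disc radius: 2% of the display diagonal."""
    return 0.02 * math.hypot(display_w, display_h)


def compute_features(
    trial: Trial,
    loc_grid_size: int = 5,
    mask: SalientMask | None = None,
    radius: float | None = None,
) -> TraditionalFeatures:
    """All five traditional attributes for one trial."""
    grid = cell_centroids(
        EncodingConfig(grid_x=loc_grid_size, t=1), trial.display_w, trial.display_h
    )
    if mask is None:
        mask = full_display_mask(trial.display_w, trial.display_h)
    if radius is None:
        radius = default_radius(trial.display_w, trial.display_h)
    return TraditionalFeatures(
        total_time=total_scan_time(trial),
        fixation_count=fixation_count(trial),
        regressive_fixation_count=regressive_fixation_count(trial, grid),
        total_saccade_length=total_saccade_length(trial),
        coverage=coverage(trial, mask, radius),
    )


def extract_traditional(
    ds: GazeDataset,
    loc_grid_size: int = 5,
    masks: dict[str, SalientMask] | None = None,
    radius: float | None = None,
) -> pd.DataFrame:
    """Per-trial feature table: ids, label, then the five attributes.

    ``masks`` optionally maps trial_id to a per-trial salient mask; trials
    without one fall back to the full-display mask.
    """
    rows = []
    for trial in ds.trials:
        mask = (masks or {}).get(trial.trial_id)
        try:
            feats = compute_features(
                trial, loc_grid_size=loc_grid_size, mask=mask, radius=radius
            )
        except Exception as exc:
            raise type(exc)(f"trial {trial.trial_id!r}: {exc}") from exc
        rows.append(
            [trial.trial_id, trial.participant_id, trial.label] + feats.as_row()
        )
    return pd.DataFrame(
        rows, columns=["trial_id", "participant_id", "label"] + FEATURE_COLUMNS
    )
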