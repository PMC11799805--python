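"""Discretized spatiotemporal vector encoding of scanpaths.

A trial's fixations are split into ``t`` ordered temporal groups, the
fixations of each group are counted over an ``grid_x`` x ``grid_y`` spatial
grid tiling the display, and the ``t`` count grids are flattened into a
single vector of length ``grid_x * grid_y * t``.  The vector length is fixed
by the configuration, independent of trial duration or fixation count, so
trials of any length map to one fixed-width feature space: longer trials
yield larger counts, shorter trials sparser vectors.

Flattening is temporal-major with row-major cells within each grid:
``counts[b * grid_x * grid_y + i * grid_x + j]`` is the number of fixations
of temporal group ``b`` falling in grid row ``i`` (from the top), column
``j`` (from the left).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .gaze_model import Fixation, GazeDataset, GeometryError, Trial

__all__ = [
    "EncodingConfig",
    "CellGrid",
    "EncodedVector",
    "cell_centroids",
    "assign_cell",
    "assign_cells",
    "split_temporal",
    "encode_trial",
    "encode_dataset",
    "feature_names",
]

BinningMode = Literal["time", "count"]
OobPolicy = Literal["clamp", "drop"]


class ConfigError(ValueError):
    """Invalid encoding configuration."""


@dataclass(frozen=True)
class EncodingConfig:
    """Grid/temporal-bin configuration of the encoder.

    ``grid_y`` defaults to ``grid_x`` (square grids).  ``binning_mode``
    selects how fixations are split into temporal groups:

    - ``"time"`` (default): the span from first onset to last offset is cut
      into ``t`` equal half-open intervals and fixations are assigned by
      onset (the final interval is closed on the right);
    - ``"count"``: the ordered fixations are split into ``t`` near-equal
      contiguous runs, remainder to the front (n = q*t + r gives r groups
      of q+1 followed by groups of q).

    ``oob_policy`` controls off-display fixations: ``"clamp"`` (default)
    lets the nearest-centroid assignment pull them into the closest edge
    cell; ``"drop"`` discards them before temporal grouping.
    """

    grid_x: int
    grid_y: int | None = None
    t: int = 3
    binning_mode: BinningMode = "time"
    oob_policy: OobPolicy = "clamp"

    def __post_init__(self) -> None:
        gy = self.grid_x if self.grid_y is None else self.grid_y
        object.__setattr__(self, "grid_y", int(gy))
        if self.grid_x < 1 or self.grid_y < 1 or self.t < 1:
            raise ConfigError(
                f"grid_x, grid_y, t must all be >= 1, got "
                f"({self.grid_x}, {self.grid_y}, {self.t})"
            )
        if self.binning_mode not in ("time", "count"):
            raise ConfigError(f"unknown binning_mode {self.binning_mode!r}")
        if self.oob_policy not in ("clamp", "drop"):
            raise ConfigError(f"unknown oob_policy {self.oob_policy!r}")

    @property
    def length(self) -> int:
        """Encoded vector length, ``grid_x * grid_y * t``."""
        return self.grid_x * self.grid_y * self.t


@dataclass(frozen=True)
class CellGrid:
    """Row-major grid of cell centroids tiling the display."""

    centroids: np.ndarray  # (grid_x*grid_y, 2), row-major
    cell_w: float
    cell_h: float
    grid_x: int
    grid_y: int

    def __len__(self) -> int:
        return self.grid_x * self.grid_y


@dataclass(frozen=True)
class EncodedVector:
    """The flattened count vector of one trial plus its configuration."""

    counts: np.ndarray  # int, length config.length
    config: EncodingConfig


def cell_centroids(
    config: EncodingConfig, display_w: float, display_h: float
) -> CellGrid:
    """Centroids of the grid cells tiling the display exactly.

    Cell (row i, col j) has centroid ((j + 0.5) * cell_w, (i + 0.5) * cell_h)
    with cell_w = display_w / grid_x and cell_h = display_h / grid_y.
    """
    if display_w <= 0 or display_h <= 0:
        raise GeometryError(
            f"display extent must be positive, got {display_w}x{display_h}"
        )
    cw = display_w / config.grid_x
    ch = display_h / config.grid_y
    jj, ii = np.meshgrid(np.arange(config.grid_x), np.arange(config.grid_y))
    cents = np.column_stack(
        [(jj.ravel() + 0.5) * cw, (ii.ravel() + 0.5) * ch]
    ).astype(float)
    return CellGrid(
        centroids=cents, cell_w=cw, cell_h=ch,
        grid_x=config.grid_x, grid_y=config.grid_y,
    )


def assign_cells(xy: np.ndarray, grid: CellGrid) -> np.ndarray:
    """Nearest-centroid (Euclidean) cell index for each (x, y) row.

    Ties are broken toward the lowest row-major index.  Because the
    centroids form an axis-aligned lattice, the squared distance separates
    into per-axis terms and the argmin can be taken per axis; numpy's
    argmin returns the first minimum, which realises the tie-break.  Points
    outside the display are naturally assigned to the nearest edge cell
    (the clamp behaviour).
    """
    xy = np.asarray(xy, dtype=float)
    if xy.size == 0:
        return np.empty(0, dtype=np.intp)
    cx = (np.arange(grid.grid_x) + 0.5) * grid.cell_w
    cy = (np.arange(grid.grid_y) + 0.5) * grid.cell_h
    col = np.abs(xy[:, 0:1] - cx[None, :]).argmin(axis=1)
    row = np.abs(xy[:, 1:2] - cy[None, :]).argmin(axis=1)
    return row * grid.grid_x + col


def assign_cell(fx: Fixation | tuple[float, float], grid: CellGrid) -> int:
    """Cell index of a single fixation (see :func:`assign_cells`)."""
    if isinstance(fx, Fixation):
        pt = (fx.x, fx.y)
    else:
        pt = fx
    return int(assign_cells(np.array([pt]), grid)[0])


def _split_indices(
    onsets: np.ndarray, durations: np.ndarray, t: int, mode: BinningMode
) -> list[np.ndarray]:
    """Index arrays of the t temporal groups, in fixation order."""
    n = len(onsets)
    if t < 1:
        raise ConfigError(f"t must be >= 1, got {t}")
    if n == 0:
        return [np.empty(0, dtype=np.intp) for _ in range(t)]
    if mode == "count":
        # n = q*t + r -> first r groups take q+1
        q, r = divmod(n, t)
        sizes = [q + 1] * r + [q] * (t - r)
        edges = np.cumsum([0] + sizes)
        return [np.arange(edges[i], edges[i + 1]) for i in range(t)]
    if mode == "time":
        a = onsets[0]
        b = onsets[-1] + durations[-1]
        if b <= a:  # zero-span trial: everything in the first bin
            groups = [np.empty(0, dtype=np.intp) for _ in range(t)]
            groups[0] = np.arange(n)
            return groups
        edges = np.linspace(a, b, t + 1)
        bins = np.clip(np.searchsorted(edges, onsets, side="right") - 1, 0, t - 1)
        return [np.flatnonzero(bins == i) for i in range(t)]
    raise ConfigError(f"unknown binning_mode {mode!r}")


def split_temporal(
    trial: Trial, t: int, mode: BinningMode = "time"
) -> list[tuple[Fixation, ...]]:
    """Split a trial's fixations into ``t`` ordered temporal groups.

    Groups are disjoint and their concatenation preserves fixation order.
    """
    idx = _split_indices(trial.onsets, trial.durations, t, mode)
    fixes = trial.fixations
    return [tuple(fixes[i] for i in g) for g in idx]


def encode_trial(trial: Trial, config: EncodingConfig) -> EncodedVector:
    """Encode one trial into its spatiotemporal count vector."""
    grid = cell_centroids(config, trial.display_w, trial.display_h)
    xy = trial.xy
    onsets = trial.onsets
    durations = trial.durations
    if config.oob_policy == "drop" and len(xy):
        inside = (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= trial.display_w)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= trial.display_h)
        )
        xy, onsets, durations = xy[inside], onsets[inside], durations[inside]
    groups = _split_indices(onsets, durations, config.t, config.binning_mode)
    ncell = config.grid_x * config.grid_y
    counts = np.zeros(config.length, dtype=np.int64)
    for b, g in enumerate(groups):
        if len(g) == 0:
            continue
        cells = assign_cells(xy[g], grid)
        counts[b * ncell : (b + 1) * ncell] = np.bincount(cells, minlength=ncell)
    return EncodedVector(counts=counts, config=config)


def encode_dataset(
    ds: GazeDataset, config: EncodingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode every trial; rows follow dataset order.

    Returns ``(X, labels, participants, trial_ids)`` with ``X`` of shape
    ``(n_trials, config.length)``.
    """
    X = np.zeros((len(ds.trials), config.length), dtype=np.int64)
    for i, trial in enumerate(ds.trials):
        try:
            X[i] = encode_trial(trial, config).counts
        except Exception as exc:  # re-raise with trial context
            raise type(exc)(f"trial {trial.trial_id!r}: {exc}") from exc
    return X, ds.labels, ds.participants, ds.trial_ids


def feature_names(config: EncodingConfig) -> list[str]:
    """Column names ``b{bin}_r{row}_c{col}`` in flattening order."""
    return [
        f"b{b}_r{i}_c{j}"
        for b in range(config.t)
        for i in range(config.grid_y)
        for j in range(config.grid_x)
    ]
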