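"""Dynamic functional connectivity: band-pass filtering, sliding windows,
windowed node-node correlation graphs, and edge-weight time series.

The regional BOLD-like signals are band-pass filtered to the task-related
0.06-0.125 Hz range, segmented into consecutive non-overlapping 60 s windows
aligned to run starts, and a Pearson node-node adjacency matrix is computed
per window.  Joining each node pair's weight across windows yields an E x W
edge time series matrix (E = N(N-1)/2 in canonical upper-triangle order),
the input to the hypergraph stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalTimeSeries",
    "WindowedConnectivity",
    "EdgeIndexMap",
    "EdgeTimeSeries",
    "Window",
    "bandpass_filter",
    "segment_windows",
    "window_adjacency",
    "windowed_connectivity",
    "build_edge_timeseries",
]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """Concatenated multi-run regional signal matrix.

    Parameters
    ----------
    values : (T, N) float array
        One column per region, one row per acquired volume.
    sampling_period : float or sequence of float
        TR in seconds; a scalar applies to all runs, a sequence gives one TR
        per run.
    run_boundaries : sequence of int
        Cumulative end indices of the runs; strictly increasing, last equals
        T.  A single-run series has ``run_boundaries=[T]``.
    task_labels : sequence of str
        One task label per run.
    """

    values: np.ndarray
    sampling_period: float | Sequence[float]
    run_boundaries: tuple[int, ...]
    task_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D time x region matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        object.__setattr__(self, "values", values)
        bounds = tuple(int(b) for b in self.run_boundaries)
        if len(bounds) == 0:
            raise ValueError("at least one run is required")
        if any(b2 <= b1 for b1, b2 in zip((0,) + bounds, bounds)):
            raise ValueError("run boundaries must be strictly increasing from 0")
        if bounds[-1] != values.shape[0]:
            raise ValueError(
                f"last run boundary {bounds[-1]} does not match "
                f"time-series length {values.shape[0]}"
            )
        object.__setattr__(self, "run_boundaries", bounds)
        labels = tuple(str(t) for t in self.task_labels)
        if len(labels) != len(bounds):
            raise ValueError("need exactly one task label per run")
        object.__setattr__(self, "task_labels", labels)
        trs = np.atleast_1d(np.asarray(self.sampling_period, dtype=float))
        if trs.size == 1:
            trs = np.full(len(bounds), trs[0])
        if trs.size != len(bounds):
            raise ValueError("sampling_period must be scalar or one value per run")
        if np.any(trs <= 0):
            raise ValueError("sampling_period must be positive")
        object.__setattr__(self, "sampling_period", tuple(float(t) for t in trs))

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_slices(self) -> list[slice]:
        starts = (0,) + self.run_boundaries[:-1]
        return [slice(a, b) for a, b in zip(starts, self.run_boundaries)]

    def replace_values(self, values: np.ndarray) -> "RegionalTimeSeries":
        return RegionalTimeSeries(
            values, self.sampling_period, self.run_boundaries, self.task_labels
        )


@dataclass(frozen=True)
class Window:
    """Half-open sample range [start, stop) carrying its run's task label."""

    start: int
    stop: int
    task: str
    run: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty window")


@dataclass(frozen=True)
class WindowedConnectivity:
    """Sequence of symmetric node-node Pearson adjacency matrices, one per
    consecutive window, each labeled with its window's task."""

    matrices: np.ndarray  # (W, N, N)
    window_task: tuple[str, ...]
    window_seconds: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be a (W, N, N) stack")
        if m.shape[0] < 1:
            raise ValueError("need at least one window")
        if not np.allclose(m, np.transpose(m, (0, 2, 1)), atol=1e-10):
            raise ValueError("window adjacency matrices must be symmetric")
        object.__setattr__(self, "matrices", m)
        object.__setattr__(self, "window_task", tuple(self.window_task))
        if len(self.window_task) != m.shape[0]:
            raise ValueError("need one task label per window")

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between edge ids and node pairs (i, j), i < j, in canonical
    upper-triangle (lexicographic) order; edge ids are 0-based ranks."""

    n_nodes: int
    _rows: np.ndarray = field(repr=False, default=None)
    _cols: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least two nodes to define edges")
        rows, cols = np.triu_indices(self.n_nodes, k=1)
        object.__setattr__(self, "_rows", rows)
        object.__setattr__(self, "_cols", cols)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def pair_of(self, edge_id: int) -> tuple[int, int]:
        if not 0 <= edge_id < self.n_edges:
            raise IndexError(f"edge id {edge_id} out of range [0, {self.n_edges})")
        return int(self._rows[edge_id]), int(self._cols[edge_id])

    def index_of(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("self-pairs are not edges")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n_nodes):
            raise IndexError(f"node pair ({i}, {j}) out of range")
        n = self.n_nodes
        # rank of (i, j) in row-major upper-triangle order
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def pairs(self) -> np.ndarray:
        """(E, 2) array of node pairs in edge-id order."""
        return np.column_stack([self._rows, self._cols])


@dataclass(frozen=True)
class EdgeTimeSeries:
    """E x W matrix of edge weights across windows, plus the edge index map
    and per-window task labels."""

    weights: np.ndarray  # (E, W)
    index: EdgeIndexMap
    window_task: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D edge x window matrix")
        if w.shape[0] != self.index.n_edges:
            raise ValueError("weights row count must equal the edge count")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "window_task", tuple(self.window_task))
        if len(self.window_task) != w.shape[1]:
            raise ValueError("need one task label per window")

    @property
    def n_edges(self) -> int:
        return self.weights.shape[0]

    @property
    def n_windows(self) -> int:
        return self.weights.shape[1]

    def task_window_indices(self, task: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.window_task) == task)


def _design_sos(low: float, high: float, fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(
            f"upper band edge {high} Hz is not below the Nyquist frequency "
            f"{nyq:.4g} Hz for sampling period {1.0 / fs:.4g} s"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    series: RegionalTimeSeries,
    low: float = 0.06,
    high: float = 0.125,
    *,
    order: int = 4,
    per_run: bool = False,
) -> RegionalTimeSeries:
    """Zero-phase Butterworth band-pass of every regional signal.

    A forward-backward (``sosfiltfilt``) 4th-order Butterworth band-pass
    restricts each region's signal to [low, high] Hz without phase
    distortion, so window boundaries are not shifted by filtering.  With
    ``per_run=True`` each run is filtered independently before concatenation
    (the edge-effect control variant); runs with differing sampling periods
    are always filtered per run, since a single digital filter design is only
    valid at one sampling rate.
    """
    trs = set(series.sampling_period)
    if len(trs) > 1 and not per_run:
        logger.info("runs have differing sampling periods; filtering per run")
        per_run = True
    out = np.empty_like(series.values)
    if per_run:
        for sl, tr in zip(series.run_slices(), series.sampling_period):
            sos = _design_sos(low, high, 1.0 / tr, order)
            out[sl] = signal.sosfiltfilt(sos, series.values[sl], axis=0)
    else:
        sos = _design_sos(low, high, 1.0 / series.sampling_period[0], order)
        out[:] = signal.sosfiltfilt(sos, series.values, axis=0)
    return series.replace_values(out)


def segment_windows(
    series: RegionalTimeSeries,
    window_seconds: float = 60.0,
    drop_boundary_windows: int = 0,
) -> list[Window]:
    """Non-overlapping windows aligned to run starts.

    Each run is cut into ``floor(run_samples / samples_per_window)`` full
    windows of ``floor(window_seconds / TR)`` samples; the trailing remainder
    is discarded.  With ``drop_boundary_windows=d`` the first d and last d
    windows of each run are removed (edge-effect control).  Every window
    carries its run's task label.
    """
    if drop_boundary_windows < 0:
        raise ValueError("drop_boundary_windows must be >= 0")
    windows: list[Window] = []
    for run, (sl, tr, task) in enumerate(
        zip(series.run_slices(), series.sampling_period, series.task_labels)
    ):
        spw = int(window_seconds / tr + 1e-9)
        if spw < 2:
            raise ValueError(f"window of {window_seconds} s too short for TR {tr} s")
        n_run = sl.stop - sl.start
        n_win = n_run // spw
        needed = 1 + 2 * drop_boundary_windows
        if n_win < needed:
            raise ValueError(
                f"run {run} ({task!r}, {n_run} samples at TR {tr} s) holds "
                f"{n_win} windows of {window_seconds} s; {needed} required"
            )
        for w in range(drop_boundary_windows, n_win - drop_boundary_windows):
            start = sl.start + w * spw
            windows.append(Window(start, start + spw, task, run))
    return windows


def window_adjacency(window_values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of one window's samples x regions block.

    Regions constant within the window have undefined correlations; their
    rows and columns are set to 0 (diagonal kept at 1) and a warning is
    emitted, so a degenerate window does not abort a cohort run.
    """
    x = np.asarray(window_values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("window must be a samples x regions block with >= 3 samples")
    sd = x.std(axis=0)
    constant = sd < 1e-12  # tolerance: exact zero fails on rounded constants
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} region(s) constant within window; "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        x = x.copy()
        # give constant columns unit variance noise-free placeholder, zero later
        x[:, constant] = np.arange(x.shape[0])[:, None]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def windowed_connectivity(
    series: RegionalTimeSeries,
    window_seconds: float = 60.0,
    drop_boundary_windows: int = 0,
) -> WindowedConnectivity:
    """Segment a (filtered) series and compute one adjacency per window."""
    windows = segment_windows(series, window_seconds, drop_boundary_windows)
    mats = np.stack(
        [window_adjacency(series.values[w.start : w.stop]) for w in windows]
    )
    return WindowedConnectivity(mats, tuple(w.task for w in windows), window_seconds)


def build_edge_timeseries(conn: WindowedConnectivity) -> EdgeTimeSeries:
    """Join each node pair's weight across windows into an E x W matrix.

    Rows follow canonical edge order: upper-triangle pairs (i, j), i < j,
    lexicographic; the accompanying :class:`EdgeIndexMap` recovers the pair
    for any row.
    """
    index = EdgeIndexMap(conn.n_nodes)
    rows, cols = np.triu_indices(conn.n_nodes, k=1)
    weights = conn.matrices[:, rows, cols].T  # (E, W)
    return EdgeTimeSeries(weights, index, conn.window_task)
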