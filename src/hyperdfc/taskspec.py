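"""Task-specific hyperedge classification.

A hyperedge is task-specific when the coherence of its member edges —
mean absolute pairwise Pearson correlation of the member edge time series —
is significantly higher within one task's windows than in equally sized
window sets drawn at random from all tasks.  One-sided permutation p-values
are Bonferroni-corrected over (hyperedges x tasks) within the subject, and
a hyperedge is labeled only if exactly one task survives; hyperedges
associated with several tasks stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfc import EdgeTimeSeries
from .hypergraph import Hyperedge, Hypergraph

__all__ = ["TaskSpecificLabel", "hyperedge_coherence", "classify_task_specific"]


def _pairwise_stat(rows: np.ndarray, absolute: bool) -> float:
    """Mean (absolute) pairwise Pearson correlation over row pairs; pairs
    involving a constant row contribute 0."""
    n = rows.shape[0]
    sd = rows.std(axis=1)
    ok = sd > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    iu = np.triu_indices(n, k=1)
    vals = corr[iu]
    if absolute:
        vals = np.abs(vals)
    return float(vals.mean())


def hyperedge_coherence(
    ets: EdgeTimeSeries,
    h: Hyperedge,
    windows: np.ndarray,
    *,
    absolute: bool = True,
) -> float:
    """Coherence of a hyperedge on a window subset.

    Mean absolute pairwise Pearson correlation over all member-edge pairs,
    computed on ``windows`` only.  ``absolute=False`` gives the mean signed
    correlation instead.
    """
    windows = np.asarray(windows, dtype=int)
    if windows.size < 3:
        raise ValueError("need at least 3 windows to correlate")
    if h.size < 2:
        raise ValueError("hyperedge needs >= 2 member edges")
    rows = ets.weights[sorted(h.edge_ids)][:, windows]
    return _pairwise_stat(rows, absolute)


@dataclass(frozen=True)
class TaskSpecificLabel:
    """Classification of one hyperedge: the single task it is specific to
    (or None), with its per-task permutation p-values."""

    hyperedge_id: int
    label: str | None
    p_per_task: dict[str, float]


def classify_task_specific(
    ets: EdgeTimeSeries,
    hypergraph: Hypergraph,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    *,
    absolute: bool = True,
) -> list[TaskSpecificLabel]:
    """Permutation test of per-task coherence against all-task window draws.

    For each hyperedge and task t with m_t windows, the observed coherence
    on t's windows is compared to the coherence on ``n_perm`` uniform random
    m_t-subsets (without replacement) of all windows; the one-sided add-one
    p-value is ``(1 + #{null >= observed}) / (1 + n_perm)``.  Significance
    uses the Bonferroni threshold ``alpha / (cardinality * n_tasks)``; a
    hyperedge is labeled iff exactly one task survives.
    """
    tasks = sorted(set(ets.window_task))
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks to classify specificity")
    task_windows = {t: ets.task_window_indices(t) for t in tasks}
    for t, idx in task_windows.items():
        if idx.size < 3:
            raise ValueError(f"task {t!r} has {idx.size} windows; >= 3 required")
    rng = np.random.default_rng(seed)
    W = ets.n_windows
    n_tests = max(1, hypergraph.cardinality * len(tasks))
    threshold = alpha / n_tests
    labels: list[TaskSpecificLabel] = []
    for hid, h in enumerate(hypergraph.hyperedges):
        member_rows = ets.weights[sorted(h.edge_ids)]
        p_per_task: dict[str, float] = {}
        for t in tasks:
            idx = task_windows[t]
            observed = _pairwise_stat(member_rows[:, idx], absolute)
            exceed = 0
            for _ in range(n_perm):
                draw = rng.choice(W, size=idx.size, replace=False)
                if _pairwise_stat(member_rows[:, draw], absolute) >= observed:
                    exceed += 1
            p_per_task[t] = (1 + exceed) / (1 + n_perm)
        surviving = [t for t in tasks if p_per_task[t] < threshold]
        label = surviving[0] if len(surviving) == 1 else None
        labels.append(TaskSpecificLabel(hid, label, p_per_task))
    return labels
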