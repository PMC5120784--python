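"""Synthetic cohorts with planted hypergraph structure.

The generator emulates the statistical skeleton the analysis assumes:
band-limited (0.06-0.125 Hz) regional signals sampled at fMRI-like TRs,
concatenated task runs cut into 60 s windows, and K planted modules —
disjoint groups of >= 3 regions whose pairwise connectivity co-fluctuates
from window to window, so each module surfaces downstream as exactly one
hyperedge.  Background regions are pure band-limited noise.  Cohorts add an
age covariate that linearly modulates the planted module count K, and a
categorized individual-differences table (low-rank factors plus noise) with
a head-motion proxy column.

Planting mechanism.  In every 60 s window a module sits in one of two
states: a *coherent* state, where all member regions load on one shared
band-limited carrier (pairwise correlation near +1), or an *anti-phase*
state, where members load on zero-sum contrasts of private carriers
(pairwise correlation at the negative-definiteness limit, -1/(m-1) for an
m-region module).  States are drawn as a balanced random sequence with
coherent fraction 1/m, which makes the *time-averaged* pairwise correlation
(almost) exactly zero.  Within-module edge weights therefore swing
coherently between strongly positive and negative values — a high-variance,
zero-mean edge co-fluctuation — while any edge to a region outside the
module sees correlation contributions of opposite sign in the two states
that cancel on average.  This balance is what lets the downstream FDR
thresholding isolate exactly the planted edge groups: a naive design with a
single amplitude-modulated shared component makes module regions near
copies of each other in high-gain windows, so their edges to *every* third
region co-fluctuate too, flooding the hypergraph with spurious hyperedges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .dfc import RegionalTimeSeries, _design_sos

__all__ = [
    "SyntheticSpec",
    "CohortSpec",
    "DEFAULT_MEASURE_CATEGORIES",
    "generate_subject",
    "generate_null_subject",
    "generate_cohort",
    "default_module_node_sets",
]

RunSpec = tuple[str, int, float]  # (task label, n_volumes, sampling period s)

#: Category split of the 42 individual-difference measures shared by the two
#: studies (five categories; the four demographic measures are age, years of
#: education, sex, and handedness).
DEFAULT_MEASURE_CATEGORIES: dict[str, int] = {
    "performance": 6,
    "demographics": 4,
    "state_of_mind": 10,
    "cognitive_factors": 10,
    "personality": 12,
}

DEFAULT_RUNS: tuple[RunSpec, ...] = (("memory", 1740, 2.0),)  # 58 windows of 60 s

BAND = (0.06, 0.125)


def default_module_node_sets(n_modules: int, nodes_per_module: int = 3) -> tuple:
    """K disjoint modules of consecutive region indices, 3 nodes each by
    default (the smallest module that contributes a multi-edge hyperedge)."""
    return tuple(
        frozenset(range(k * nodes_per_module, (k + 1) * nodes_per_module))
        for k in range(n_modules)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic subject.

    ``modulation_strength`` is the amplitude of the state-modulated module
    component relative to each region's private noise (``noise_sd``); the
    coherent-state pairwise correlation is ``M^2 / (M^2 + sd^2)``.  Defaults
    define the well-separated regime: strong state contrast (coherent-state
    correlation about 0.9) so within-module edge weights sweep most of
    [-0.45, 0.9] coherently across windows.
    """

    n_regions: int = 40
    runs: tuple[RunSpec, ...] = DEFAULT_RUNS
    module_node_sets: tuple[frozenset[int], ...] = ()
    modulation_strength: float = 1.0
    noise_sd: float = 0.35
    age: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        runs = tuple((str(t), int(n), float(tr)) for t, n, tr in self.runs)
        if not runs:
            raise ValueError("need at least one run")
        object.__setattr__(self, "runs", runs)
        modules = tuple(frozenset(int(i) for i in m) for m in self.module_node_sets)
        seen: set[int] = set()
        for m in modules:
            if len(m) < 3:
                raise ValueError("each module needs >= 3 nodes (>= 3 edges)")
            if m & seen:
                raise ValueError("module node sets must be pairwise disjoint")
            if any(i < 0 or i >= self.n_regions for i in m):
                raise ValueError("module node index out of range")
            seen |= m
        object.__setattr__(self, "module_node_sets", modules)
        if self.modulation_strength < 0:
            raise ValueError("modulation_strength must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for task, n, tr in runs:
            if n * tr < 60.0:
                raise ValueError(
                    f"run {task!r}: {n} volumes at TR {tr} s is shorter than "
                    "one 60 s window"
                )

    @property
    def n_modules(self) -> int:
        return len(self.module_node_sets)


def _bandlimited_noise(
    rng: np.random.Generator, n_samples: int, fs: float, shape: tuple[int, ...]
) -> np.ndarray:
    """White noise filtered into the analysis band, unit variance per column."""
    sos = _design_sos(*BAND, fs, order=4)
    raw = rng.standard_normal((n_samples, *shape))
    out = signal.sosfiltfilt(sos, raw, axis=0)
    sd = out.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _run_layout(runs: Sequence[RunSpec]) -> tuple[tuple[int, ...], tuple[str, ...], tuple[float, ...]]:
    boundaries, labels, trs = [], [], []
    total = 0
    for task, n, tr in runs:
        total += n
        boundaries.append(total)
        labels.append(task)
        trs.append(tr)
    return tuple(boundaries), tuple(labels), tuple(trs)


def _balanced_states(
    rng: np.random.Generator, n_windows: int, coherent_fraction: float
) -> np.ndarray:
    """Random boolean state sequence with an (almost) exact coherent count.

    Drawing states i.i.d. would let the realized coherent fraction drift,
    leaving a nonzero time-averaged within-module correlation that couples
    module edges to third-party edges; fixing the composition keeps the
    cancellation tight for every seed.
    """
    n_coh = int(np.floor(coherent_fraction * n_windows + 0.5))
    states = np.zeros(n_windows, dtype=bool)
    states[:n_coh] = True
    return rng.permutation(states)


def generate_subject(spec: SyntheticSpec) -> RegionalTimeSeries:
    """Simulate one subject's regional time series with planted modules.

    Region i of an m-region module follows ``M * (A(w) c(t) + B(w) y_i(t))
    + noise_sd * u_i(t)`` where c is the module's shared band-limited
    carrier, y_i are zero-sum contrasts of private carriers (pairwise
    correlation -1/(m-1)), u_i is private noise, and the per-window mixing
    (A, B) is (1, 0) in coherent windows and (0, 1) in anti-phase windows;
    the coherent fraction 1/m cancels the time-averaged correlation.
    Background regions are pure band-limited noise.  Deterministic given
    the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    M, sd = spec.modulation_strength, spec.noise_sd
    scale = float(np.sqrt(M**2 + sd**2))
    pieces: list[np.ndarray] = []
    for task, n, tr in spec.runs:
        fs = 1.0 / tr
        spw = int(60.0 / tr + 1e-9)
        n_win = max(n // spw, 1)
        x = _bandlimited_noise(rng, n, fs, (spec.n_regions,))
        for module in spec.module_node_sets:
            nodes = sorted(module)
            m = len(nodes)
            common = _bandlimited_noise(rng, n, fs, ())
            private = _bandlimited_noise(rng, n, fs, (m,))
            contrasts = private - private.mean(axis=1, keepdims=True)
            contrasts /= np.sqrt(1.0 - 1.0 / m)  # unit variance, corr -1/(m-1)
            coherent = _balanced_states(rng, n_win, 1.0 / m)
            A = np.where(coherent, 1.0, 0.0)
            B = np.where(coherent, 0.0, 1.0)
            per_sample_A = np.repeat(A, spw)
            per_sample_B = np.repeat(B, spw)
            tail = n - n_win * spw  # remainder keeps the last state (discarded later)
            if tail > 0:
                per_sample_A = np.concatenate([per_sample_A, np.full(tail, A[-1])])
                per_sample_B = np.concatenate([per_sample_B, np.full(tail, B[-1])])
            noise = _bandlimited_noise(rng, n, fs, (m,))
            for idx, node in enumerate(nodes):
                x[:, node] = (
                    M * (per_sample_A * common + per_sample_B * contrasts[:, idx])
                    + sd * noise[:, idx]
                ) / scale
        pieces.append(x)
    values = np.vstack(pieces)
    boundaries, labels, trs = _run_layout(spec.runs)
    return RegionalTimeSeries(values, trs, boundaries, labels)


def generate_null_subject(
    n_regions: int, runs: Sequence[RunSpec] = DEFAULT_RUNS, seed: int = 0
) -> RegionalTimeSeries:
    """Structureless subject: independent stationary band-limited noise per
    region, no planted cross-edge temporal structure."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions (a single region has no edges)")
    rng = np.random.default_rng(seed)
    pieces = [
        _bandlimited_noise(rng, int(n), 1.0 / tr, (n_regions,)) for _, n, tr in runs
    ]
    boundaries, labels, trs = _run_layout(tuple((str(t), int(n), float(tr)) for t, n, tr in runs))
    return RegionalTimeSeries(np.vstack(pieces), trs, boundaries, labels)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort with an age-linked fragmentation effect.

    Each subject's planted module count is ``K(age) = base_modules +
    round(cardinality_slope * (age - min age))`` — older subjects carry more
    independently fluctuating connection groups, the hypergraph analogue of
    age-related loss of large-scale coherence.
    """

    n_subjects: int = 30
    age_range: tuple[float, float] = (18.0, 75.0)
    cardinality_slope: float = 1.0 / 15.0  # planted modules per year
    base_modules: int = 2
    n_regions: int = 40
    runs: tuple[RunSpec, ...] = DEFAULT_RUNS
    modulation_strength: float = 1.0
    noise_sd: float = 0.6
    measure_categories: tuple[tuple[str, int], ...] = tuple(
        DEFAULT_MEASURE_CATEGORIES.items()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        lo, hi = self.age_range
        if not lo <= hi:
            raise ValueError("age_range must be (min, max)")
        if self.base_modules < 0 or self.cardinality_slope < 0:
            raise ValueError("base_modules and cardinality_slope must be >= 0")
        cats = tuple((str(c), int(n)) for c, n in dict(self.measure_categories).items())
        if any(n < 1 for _, n in cats):
            raise ValueError("every category needs >= 1 measure")
        object.__setattr__(self, "measure_categories", cats)
        k_max = self.max_modules
        if 3 * k_max > self.n_regions:
            raise ValueError(
                f"maximum planted module count {k_max} needs {3 * k_max} regions, "
                f"only {self.n_regions} available"
            )

    @property
    def max_modules(self) -> int:
        lo, hi = self.age_range
        return self.base_modules + int(np.floor(self.cardinality_slope * (hi - lo) + 0.5))

    @property
    def n_measures(self) -> int:
        return sum(n for _, n in self.measure_categories)


def _planted_k(spec: CohortSpec, age: float) -> int:
    # round-half-up keeps the age -> K map deterministic across platforms
    return spec.base_modules + int(
        np.floor(spec.cardinality_slope * (age - spec.age_range[0]) + 0.5)
    )


def _measure_block(
    rng: np.random.Generator, n_subjects: int, n_measures: int
) -> np.ndarray:
    """Two-factor low-rank structure plus standard-normal residuals.

    Loadings are scaled so the two factors dominate the category variance,
    guaranteeing the 75% rule selects a small factor count.
    """
    n_fac = min(2, n_measures)
    scores = rng.standard_normal((n_subjects, n_fac))
    loadings = rng.standard_normal((n_measures, n_fac)) * np.array(
        [3.0, 2.0][:n_fac]
    )
    return scores @ loadings.T + rng.standard_normal((n_subjects, n_measures))


def generate_cohort(spec: CohortSpec) -> tuple[list[RegionalTimeSeries], pd.DataFrame]:
    """Simulate a cohort and its individual-differences table.

    Returns one :class:`~hyperdfc.dfc.RegionalTimeSeries` per subject
    (planted module count driven by the subject's age) and a DataFrame whose
    columns carry a ``category`` attribute map via ``df.attrs["category_of"]``;
    covariate columns (``age``, ``head_motion``) are flagged there as
    ``"covariate"``.  The ``age`` measure inside the demographics category
    equals the true simulated age.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = np.sort(rng.uniform(lo, hi, spec.n_subjects))
    subjects: list[RegionalTimeSeries] = []
    child_seeds = rng.integers(0, 2**31 - 1, spec.n_subjects)
    for age, sseed in zip(ages, child_seeds):
        k = _planted_k(spec, age)
        sub_spec = SyntheticSpec(
            n_regions=spec.n_regions,
            runs=spec.runs,
            module_node_sets=default_module_node_sets(k),
            modulation_strength=spec.modulation_strength,
            noise_sd=spec.noise_sd,
            age=float(age),
            seed=int(sseed),
        )
        subjects.append(generate_subject(sub_spec))

    columns: dict[str, np.ndarray] = {}
    category_of: dict[str, str] = {}
    for cat, n_meas in spec.measure_categories:
        if cat == "demographics":
            # the four named demographic measures; age in years dominates the
            # demeaned (unstandardized) category variance by construction
            edu = 12.0 + 0.08 * (ages - lo) + rng.standard_normal(spec.n_subjects)
            sex = rng.integers(0, 2, spec.n_subjects).astype(float)
            hand = (rng.uniform(size=spec.n_subjects) < 0.9).astype(float)
            named = {"age": ages.copy(), "education": edu, "sex": sex, "handedness": hand}
            extra = _measure_block(rng, spec.n_subjects, max(0, n_meas - 4))
            for j, (name, col) in enumerate(named.items()):
                if j >= n_meas:
                    break
                columns[name] = col
                category_of[name] = cat
            for j in range(max(0, n_meas - 4)):
                name = f"{cat}_{j + 5}"
                columns[name] = extra[:, j]
                category_of[name] = cat
        else:
            block = _measure_block(rng, spec.n_subjects, n_meas)
            for j in range(n_meas):
                name = f"{cat}_{j + 1}"
                columns[name] = block[:, j]
                category_of[name] = cat
    # head-motion proxy: mildly age-correlated scalar, flagged as covariate
    motion = 0.1 + 0.002 * (ages - lo) + 0.05 * np.abs(
        rng.standard_normal(spec.n_subjects)
    )
    columns["head_motion"] = motion
    category_of["head_motion"] = "covariate"
    if "age" not in columns:
        columns["age"] = ages.copy()
    category_of.setdefault("age", "covariate")
    table = pd.DataFrame(columns, index=[f"sub-{i:03d}" for i in range(spec.n_subjects)])
    table.attrs["category_of"] = category_of
    return subjects, table
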