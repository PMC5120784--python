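"""Individual-differences stage.

Behavioral measures are grouped into five categories, demeaned, and reduced
per category by SVD to the minimal factor count retaining at least 75% of
the category variance.  Hypergraph metrics (typically cardinality) are then
regressed on all factors at once; each category's contribution is the drop
in model R^2 when that category's factors are held out of the full model —
a hierarchical regression with every category entered last, the
conservative variance-partitioning reading.  Coefficient t-tests are
Bonferroni-corrected over all regressions of a session.  Age analyses add a
Spearman rank correlation between age and cardinality and a per-region
comparison of hyperedge node degree between age groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .hypergraph import NodeDegreeProfile

__all__ = [
    "MeasureTable",
    "FactorSet",
    "RegressionResult",
    "choose_factors",
    "r2_change_regression",
    "bonferroni_flags",
    "spearman_age",
    "age_group_degree_comparison",
]


@dataclass(frozen=True)
class MeasureTable:
    """Subjects x measures table with a category per measure.

    Covariate columns (age, head motion, rest cardinality, ...) are flagged
    with category ``"covariate"`` and excluded from factor reduction.
    """

    data: pd.DataFrame
    category_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in measures: {bad}")
        missing = [c for c in self.data.columns if c not in self.category_of]
        if missing:
            raise ValueError(f"measures without category assignment: {missing}")
        object.__setattr__(self, "category_of", dict(self.category_of))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeasureTable":
        """Build from a DataFrame carrying ``df.attrs['category_of']``."""
        return cls(df, dict(df.attrs["category_of"]))

    @property
    def categories(self) -> list[str]:
        seen: list[str] = []
        for col in self.data.columns:
            cat = self.category_of[col]
            if cat != "covariate" and cat not in seen:
                seen.append(cat)
        return seen

    def measures_in(self, category: str) -> list[str]:
        return [c for c in self.data.columns if self.category_of[c] == category]

    def covariate(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class FactorSet:
    """Per-category factor scores, unit-norm loadings, and variance kept."""

    scores: dict[str, np.ndarray]  # category -> (subjects, k)
    loadings: dict[str, pd.DataFrame]  # category -> measures x k
    variance_retained: dict[str, float]
    threshold: float

    @property
    def n_factors(self) -> dict[str, int]:
        return {c: s.shape[1] for c, s in self.scores.items()}

    def design(self) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
        """Stacked score matrix, column names, and per-category column ids."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        groups: dict[str, list[int]] = {}
        for cat, s in self.scores.items():
            groups[cat] = list(range(len(names), len(names) + s.shape[1]))
            for k in range(s.shape[1]):
                names.append(f"{cat}_f{k + 1}")
            cols.append(s)
        return np.hstack(cols), names, groups


def _svd_factors(
    x: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Demeaned SVD; k = minimal factor count with cumulative squared
    singular-value fraction >= threshold."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("category has zero variance")
    frac = np.cumsum(s**2) / total
    k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    k = min(k, len(s))
    directions = vt[:k].T  # (measures, k), unit-norm columns
    # SVD signs are arbitrary: orient each direction so its largest-magnitude
    # loading is positive
    for j in range(k):
        lead = np.argmax(np.abs(directions[:, j]))
        if directions[lead, j] < 0:
            directions[:, j] = -directions[:, j]
    scores = xc @ directions  # = U_k S_k up to sign
    return scores, directions, float(frac[k - 1]), k


def choose_factors(
    table: MeasureTable,
    threshold: float = 0.75,
    joint_tables: Sequence[MeasureTable] | None = None,
) -> FactorSet:
    """Category-wise SVD factor reduction at the 75% variance rule.

    Measures are demeaned (not variance-standardized) per category; the
    returned scores are the projections of ``table``'s rows onto the top-k
    right singular directions.  With ``joint_tables``, directions are fitted
    on the row-stacked data of all tables (the cross-study variant), then
    ``table``'s rows are projected onto them.  Constant columns are dropped
    with a warning.
    """
    import warnings

    scores: dict[str, np.ndarray] = {}
    loadings: dict[str, pd.DataFrame] = {}
    retained: dict[str, float] = {}
    for cat in table.categories:
        cols = table.measures_in(cat)
        if not cols:
            raise ValueError(f"category {cat!r} has no measures")
        x = table.data[cols].to_numpy(dtype=float)
        keep = x.std(axis=0) > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(
                f"dropping constant measures in {cat!r}: {dropped}",
                RuntimeWarning,
                stacklevel=2,
            )
            cols = [c for c, k in zip(cols, keep) if k]
            x = x[:, keep]
        if joint_tables:
            stacked = np.vstack(
                [x] + [t.data[cols].to_numpy(dtype=float) for t in joint_tables]
            )
            _, directions, var_kept, k = _svd_factors(stacked, threshold)
            scores[cat] = (x - stacked.mean(axis=0)) @ directions
        else:
            scores[cat], directions, var_kept, k = _svd_factors(x, threshold)
        loadings[cat] = pd.DataFrame(
            directions, index=cols, columns=[f"f{j + 1}" for j in range(k)]
        )
        retained[cat] = var_kept
    return FactorSet(scores, loadings, retained, threshold)


@dataclass(frozen=True)
class RegressionResult:
    """Full-model OLS fit with per-category R^2 changes."""

    coefficients: pd.Series
    p_values: pd.Series
    r_squared: float
    r2_change: dict[str, float]
    normalized_r2_change: dict[str, float]
    significant: pd.Series  # Bonferroni-corrected flags for coefficients
    bonferroni_m: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("R^2 out of [0, 1]")
        for cat, ch in self.r2_change.items():
            if ch < -1e-9:
                raise ValueError(f"negative R^2 change for {cat!r}: {ch}")
        total = sum(self.normalized_r2_change.values())
        if self.normalized_r2_change and total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("normalized R^2 changes must sum to 1")


def _ols_r2(y: np.ndarray, x: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return float(model.rsquared)


def r2_change_regression(
    dependent: np.ndarray,
    factors: FactorSet,
    extra_predictors: Mapping[str, np.ndarray] | None = None,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> RegressionResult:
    """Hierarchical regression with each category's contribution computed
    last.

    Fits OLS of ``dependent`` on all category factors plus any extra
    predictors (head motion, rest cardinality, ...).  For each category c,
    the R^2 change is ``R^2(full) - R^2(full minus c's factors)``; extra
    predictors stay in both models.  Coefficient two-sided t-tests come from
    the full model; flags use Bonferroni at ``alpha / m`` where ``m``
    defaults to the number of coefficient tests in this regression (override
    to correct over a whole session of regressions).
    """
    y = np.asarray(dependent, dtype=float)
    design, names, groups = factors.design()
    if extra_predictors:
        for name, col in extra_predictors.items():
            design = np.column_stack([design, np.asarray(col, dtype=float)])
            names.append(name)
    n, p = design.shape
    if y.shape[0] != n:
        raise ValueError("dependent length does not match the design")
    if n <= p + 1:
        raise ValueError(f"{n} subjects cannot support {p} predictors + intercept")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), design]))
    if rank < p + 1:
        raise ValueError(f"rank-deficient design; collinear columns among {names}")
    full = sm.OLS(y, sm.add_constant(design, has_constant="add")).fit()
    r2_full = float(full.rsquared)
    changes: dict[str, float] = {}
    for cat, cols in groups.items():
        keep = [j for j in range(p) if j not in cols]
        r2_red = _ols_r2(y, design[:, keep]) if keep else _ols_r2(y, np.empty((n, 0)))
        changes[cat] = max(0.0, r2_full - r2_red)
    total = sum(changes.values())
    normalized = {
        c: (ch / total if total > 0 else 0.0) for c, ch in changes.items()
    }
    coef = pd.Series(full.params[1:], index=names)
    pvals = pd.Series(full.pvalues[1:], index=names)
    m = bonferroni_m if bonferroni_m is not None else len(pvals)
    flags = bonferroni_flags(pvals, m, alpha)
    return RegressionResult(coef, pvals, r2_full, changes, normalized, flags, m)


def bonferroni_flags(p_values, family_size: int, alpha: float = 0.05):
    """Flag p < alpha / m.  ``family_size`` is the total number of tests in
    the correction family (all regressions of the session)."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    p = pd.Series(p_values)
    if family_size < len(p):
        raise ValueError("family size smaller than the p-values contributed")
    return p < alpha / family_size


def spearman_age(cardinalities, ages) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) between hypergraph
    cardinality and age, with the two-sided t-approximation p-value."""
    x = np.asarray(cardinalities, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = ((18, 18), (25, 33), (60, 75))


def age_group_degree_comparison(
    profiles: Sequence[NodeDegreeProfile],
    ages: Sequence[float],
    bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
    *,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-region mean hyperedge node degree by age group, with a youngest-
    vs-oldest test per region.

    Default is a Welch two-sample t-test per region (the groups contain
    different subjects); ``paired=True`` instead pairs regions across the
    two group-mean maps with a single paired t-test, reported on every row.
    Returns a DataFrame with one row per region: group means, t, and p.
    """
    ages = np.asarray(ages, dtype=float)
    degrees = np.vstack([p.degree for p in profiles]).astype(float)
    if degrees.shape[0] != ages.size:
        raise ValueError("need one degree profile per age")
    members = [
        np.flatnonzero((ages >= lo) & (ages <= hi)) for lo, hi in bins
    ]
    youngest, oldest = members[0], members[-1]
    for name, idx in (("youngest", youngest), ("oldest", oldest)):
        if idx.size < 2:
            raise ValueError(f"{name} age bin has {idx.size} subject(s); >= 2 required")
    out = pd.DataFrame(
        {
            f"mean_{lo:g}-{hi:g}": degrees[idx].mean(axis=0)
            for (lo, hi), idx in zip(bins, members)
            if idx.size
        }
    )
    if paired:
        t, p = stats.ttest_rel(degrees[oldest].mean(axis=0), degrees[youngest].mean(axis=0))
        out["t"] = float(t)
        out["p"] = float(p)
    else:
        t, p = stats.ttest_ind(
            degrees[oldest], degrees[youngest], axis=0, equal_var=False
        )
        out["t"] = t
        out["p"] = p
    out.index.name = "region"
    return out
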