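# Methods

## Pipeline model

The analysis treats a subject's recording as T samples of N regional
signals, acquired in one or more task runs with known sampling period (TR).
Stages, each behind its own module:

**Band-pass filtering** (`dfc.bandpass_filter`).  Zero-phase 4th-order
Butterworth band-pass to 0.06–0.125 Hz (`scipy.signal.sosfiltfilt`).  The
forward–backward realization has no phase delay, so window boundaries are
not shifted by filtering; order and band are configurable.  The default
filters the concatenated series; `per_run=True` filters each run
independently before concatenation (an edge-effect control), and runs with
different TRs are always filtered per run because one digital design is
valid at one rate only.

**Windowing** (`dfc.segment_windows`).  Non-overlapping windows aligned to
run starts, `floor(window_seconds / TR)` samples each, trailing remainder
discarded; `drop_boundary_windows=d` removes the first and last d windows
of every run (a second edge-effect control).  Each window inherits its
run's task label.  Window counts are derived from run lengths, never
hard-coded.

**Windowed connectivity and edge time series** (`dfc`).  Pearson
correlation per window yields W symmetric N×N matrices; stacking the upper
triangle (canonical order: pairs (i, j), i < j, lexicographic; 0-based
edge ids are upper-triangle ranks) gives the E × W edge-weight matrix,
E = N(N−1)/2.  A region constant within a window has undefined
correlations; they are set to 0 with a warning rather than aborting a
cohort run.

**Edge–edge graph** (`hypergraph`).  Pearson correlation between every pair
of edge rows; two-sided p-values from the t-transform
t = |r|·sqrt((W−2)/(1−r²)) with W−2 degrees of freedom (W ≥ 4 required;
constant rows get r = 0, p = 1).  The E(E−1)/2 upper-triangle p-values of
one subject form one FDR family, thresholded by Benjamini–Hochberg step-up
at α = 0.05 by default (`statsmodels.stats.multitest`); the
Benjamini–Yekutieli variant is available for dependence-robust control.
Surviving pairs keep their signed correlation in the sparse matrix ξ;
ξ′ = (ξ ≠ 0).  Both correlation signs produce links: relations are
absolute-valued.  The diagonal is excluded.  Matrices are stored sparse
(CSR), densified below a small-E threshold; the two storages are
value-identical by contract and test.

**Hyperedges** (`hypergraph.extract_hypergraph`).  Connected components of
ξ′ (`scipy.sparse.csgraph`).  Hyperedge size is the member-edge count —
the vertex count of the component — not the count of links inside it;
that reading makes singleton size 1 and caps the maximum at E.  The
intra-component link count is kept as a secondary diagnostic
(`Hyperedge.link_count`).  Cardinality = number of components with ≥ 2
edges; singletons are excluded from all metrics.  Node degree counts, per
node, the hyperedges containing at least one incident edge (each hyperedge
at most once).  The partition invariant — singleton count plus summed
sizes equals E — is enforced in the `Hypergraph` constructor on every run.

**Null model** (`hypergraph.shuffle_null`).  Each edge row's window
sequence is permuted independently and uniformly, exactly preserving
per-row mean and variance while destroying temporal correspondence between
edges.  On shuffled data the pipeline should find (almost) no hyperedge of
size > 1; see "Null soundness" below for the precise sense of "almost".

**Size distributions** (`hypergraph.size_distribution`, `powerlaw_fit`).
Cumulative counts (hyperedges with size ≥ s) pooled over subjects, with an
option to first drop each subject's single largest hyperedge (ties broken
by lowest member edge id).  The power-law summary is an ordinary
least-squares line through (log10 s, log10 count); it needs ≥ 3 distinct
sizes and returns the slope and the count-scale intercept 10^b.

**Task-specific hyperedges** (`taskspec`).  Coherence of a hyperedge on a
window set is the mean absolute pairwise Pearson correlation of its member
edge rows on those windows (the signed mean is available by option; the
absolute form matches the absolute-valued link definition).  For each
hyperedge and task with m_t windows, the null is the coherence on n_perm
(default 1000) uniform m_t-subsets drawn without replacement from all
windows; the one-sided add-one estimator p = (1 + #{null ≥ obs}) /
(1 + n_perm) never returns 0.  Bonferroni threshold α / (cardinality ×
n_tasks) within the subject; a hyperedge is labeled only when exactly one
task survives — multi-task associations remain unclassified.

**Individual differences** (`indiff`).  Measures are grouped into five
categories, demeaned — not variance-standardized; a standardize option
exists for mixed-unit tables, but the default keeps raw scale so a
dominant-variance measure (like age in years among demographics) dominates
its category factor.  Per category, an SVD with k = the smallest factor
count whose cumulative squared-singular-value fraction is ≥ 0.75; scores
are projections onto the top-k right singular directions (scale carries
the singular values), loadings are the unit-norm directions, each flipped
so its largest-magnitude loading is positive.  Directions can be fitted on
stacked tables from several studies and applied to one of them.  The
regression stage fits OLS (statsmodels) of a hypergraph metric on all
factors plus always-retained covariates (head motion, rest cardinality);
each category's contribution is R²(full) − R²(full without that category's
factors) — a hierarchical regression with every category entered last,
the conservative attribution.  Changes are nonnegative by nesting and
normalized to sum to 1; both properties are asserted at run time.
Coefficient t-tests are two-sided; the Bonferroni family defaults to the
tests of the current regression and is overridable to span a session.
Age analyses: Spearman rank correlation (average ranks for ties,
two-sided t-approximation p) between age and cardinality, and a per-region
comparison of mean hyperedge node degree between the youngest and oldest
age bins.  The group comparison defaults to Welch two-sample t-tests per
region (the bins contain different subjects); a paired variant pairing
regions across the two group-mean maps is available because group
comparisons are sometimes summarized that way.

## Synthetic data: what it emulates and what it does not

`synth.generate_subject` produces band-limited (0.06–0.125 Hz) regional
noise at fMRI-like TRs, organized in labeled runs, with K planted modules:
disjoint groups of ≥ 3 regions whose pairwise connectivity co-fluctuates
across 60 s windows, each surfacing downstream as exactly one hyperedge of
C(m, 2) edges.  The default subject has 40 regions and one 1740-volume run
at TR 2 s (58 windows), sizes chosen to mirror a realistic single-task
session length while keeping the E × E stage light.

Mechanism.  In each window a module is either *coherent* — all members
load on one shared band-limited carrier, pairwise correlation
M²/(M²+σ²) ≈ 0.89 at the defaults (modulation_strength M = 1, noise_sd
σ = 0.35) — or *anti-phase* — members load on zero-sum contrasts of
private carriers, pairwise correlation at the PSD limit −1/(m−1).  The
coherent fraction is 1/m with the state counts balanced exactly per
subject (a permuted fixed composition, not i.i.d. draws).  This makes the
time-averaged within-module correlation ≈ 0: within-module edge weights
swing coherently between ≈ +0.9 and ≈ −0.45 (high variance, the planted
signal), while the correlation that a module region's edges to *outside*
regions inherit from the shared carrier cancels between the two states.
The balance matters: a single amplitude-modulated shared component — the
obvious design — makes module regions near-copies of each other in
high-gain windows, so their edges to every third region co-fluctuate too
and the hypergraph floods with spurious hyperedges.  With ~8 independent
samples per 60 s window in this band, no amplitude-only setting separates
the two; the two-state balance does.

`generate_null_subject` emits pure band-limited noise (no cross-edge
temporal structure).  `generate_cohort` draws ages uniformly in 18–75 and
plants K(age) = base + round(slope × (age − 18)) modules per subject
(defaults: base 2, slope 1/15 per year — K from 2 to 6), plus a 42-measure
table in five categories: performance (6), demographics (4: age, years of
education, sex, handedness), state of mind (10), cognitive factors (10),
personality (12).  The exact per-category split of the 42 shared measures
is not recoverable from public sources; this allocation matches the four
demographic measures explicitly named and spreads the remainder
plausibly.  Non-demographic categories are 2-factor low-rank structure
with standard-normal residuals and dominant loadings, so the 75% rule
selects 1–2 factors; a head-motion proxy (scalar, mildly age-correlated)
is included as a covariate column.

Not emulated: hemodynamic response shapes, spatial/voxel structure,
realistic fMRI noise spectra (1/f, physiological bands), motion beyond the
scalar proxy, and connectivity sign conventions of real parcellations.
Passing the recovery tests therefore shows the *pipeline* isolates planted
co-fluctuation under FDR control at realistic window counts — not that
real cohorts contain such clean modules.

## Null soundness and the choice of FDR variant in recovery experiments

Two statistical facts shape the validation experiments, and both are
properties of FDR itself rather than of this implementation.

First, BH at α = 0.05 over the ~750k null pairs of a 50-region subject has
a ~5% nominal chance of at least one false link (the step-up rule's
minimum-p event).  Empirically the realized rate here is ~2–3% per
shuffled subject — the analytic t-tail slightly overstates the extreme
tail for these bounded, bimodal edge rows — so a 10-subject shuffle
experiment usually, but not always, shows no hyperedge of size > 1.  The
null-model claim is an FDR statement, not a guarantee.

Second, FDR control *by definition* tolerates E[false links] ≈ α × R where
R is the number of detected links.  A subject with K planted 3-region
modules has 3K true links, so BH at 0.05 leaves ≈ 0.15K spurious links per
subject in expectation — typically surfacing as extra size-2 hyperedges.
Exact cardinality recovery ("cardinality = K in ≥ 90% of subjects") is
therefore unattainable under BH for K ≥ 3 no matter how clean the planted
signal (measured: ~55% at K = 3, ~30% at K = 5).  The recovery
experiments (tests and acceptance script) consequently run the pipeline
with the Benjamini–Yekutieli option: the edge-pair family is strongly
dependent (every edge row enters E−1 tests), BY is the variant designed
for arbitrary dependence, and its extra harmonic-number factor shrinks the
false-link expectation ~13-fold, making exact structural recovery the
typical outcome (measured ≥ 95% per K).  BH at 0.05 remains the default
for ordinary inference, matching the analysis the pipeline models; the
choice of variant only matters when the question is exact recovery of
known structure.

## Numerical choices and degenerate inputs

- Constant signals/rows: correlations set to 0 (p = 1) with a warning;
  constancy detected at tolerance 1e-12 (exact zero fails on rounded
  constants).
- Correlations clipped to [−1, 1]; r² clipped below 1 before the
  t-transform to avoid division by zero at |r| = 1 (p underflows to 0
  there, which is correct for linking purposes).
- BH/BY at α = 0 rejects nothing (cardinality 0).
- Samples per window is floor(window_seconds / TR) with a 1e-9 guard
  against floating-point shortfall, so TR 2.5 s gives 24-sample (exactly
  60 s) windows and TR 1.6 s gives 37-sample (59.2 s) windows.
- "Largest hyperedge" ties break toward the lowest minimum member edge
  id; hyperedges are reported sorted by lowest member edge id.
- Permutation p-values use the add-one estimator, bounded away from 0.
- SVD sign indeterminacy is fixed by orienting each direction's
  largest-magnitude loading positive.
- All randomness flows from explicit integer seeds or
  `numpy.random.Generator` instances; identical spec + seed gives
  bit-identical synthetic data and byte-identical pipeline metrics.

## Problem sizes in the shipped experiments

Tests and the acceptance script use 20–50 regions (E up to 1225), 58
windows, 10–20 subjects per condition, and 10 cohorts of 30 subjects —
small enough that the full suite runs in a few minutes on one CPU while
every stage still operates in its intended regime (hundreds of thousands
of edge-pair tests per subject).  The pipeline itself has no such limits;
the N = 194 system size appears in tests only through the edge-index
identity E = 18,721.

## Known limitations

- The edge–edge stage materializes an E × E correlation matrix; at
  N = 194 (E = 18,721) that is ~2.8 GB in doubles.  Blockwise computation
  would remove the ceiling but is not implemented.
- Windows are non-overlapping and rectangular; tapered or overlapping
  windows are out of scope.
- The power-law summary is a descriptive log–log OLS fit, not a maximum-
  likelihood tail estimate.
- The task-specific test's statistic, resampling scheme, and permutation
  count are package choices (mean absolute pairwise r; without-replacement
  subsets; n_perm = 1000); alternatives are exposed as options but only
  the defaults are validated.
- The cohort generator links age only to module *count*; real aging
  effects on connectivity amplitude, noise, or motion are not modeled.
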