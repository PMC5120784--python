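"""Individual differences: recover a planted age effect on cardinality.

Simulates a 30-subject cohort in which older subjects carry more planted
connectivity modules, runs every subject through the hypergraph pipeline,
reduces the 42-measure individual-differences table to per-category SVD
factors (75% variance rule), and regresses cardinality on the factors plus
a head-motion covariate.  The demographics category — whose dominant factor
is age — should carry the largest normalized R^2 change.
"""

import numpy as np

from hyperdfc import (
    CohortSpec,
    MeasureTable,
    PipelineConfig,
    choose_factors,
    generate_cohort,
    r2_change_regression,
    spearman_age,
    subject_hypergraph,
)

spec = CohortSpec(n_subjects=30, seed=0)  # ages 18-75, +1 module per 15 y
subjects, table = generate_cohort(spec)
config = PipelineConfig(fdr_method="fdr_by")
cards = np.array(
    [subject_hypergraph(s, config).cardinality for s in subjects], dtype=float
)

measures = MeasureTable.from_frame(table.drop(columns=["head_motion"]))
factors = choose_factors(measures, threshold=0.75)
print("factors per category:", factors.n_factors)

result = r2_change_regression(
    cards, factors,
    extra_predictors={"head_motion": table["head_motion"].to_numpy()},
)
print(f"full-model R^2 = {result.r_squared:.3f}")
for cat, change in sorted(
    result.normalized_r2_change.items(), key=lambda kv: -kv[1]
):
    sig = any(
        result.significant[n] for n in result.significant.index
        if n.startswith(cat)
    )
    print(f"  {cat:18s} normalized R^2 change = {change:.3f}"
          f"{'  (Bonferroni-significant)' if sig else ''}")

rho, p = spearman_age(cards, table["age"].to_numpy())
print(f"Spearman(age, cardinality) = {rho:.3f} (p = {p:.2g})")
# Demographics should dominate the variance partition and age should rank-
# correlate strongly with cardinality, mirroring the planted slope.
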