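"""Planted-effect cohort: paired effect sizes and LOPO-CV classification.

Generates a 52-participant synthetic cohort whose features carry the
admission→discharge paired effect sizes of the microphone-channel study
defaults (e.g. total phrase duration d = -0.50, maximum phonation time
d = +0.49), recovers those effects with the paired Cohen's d, then trains
the L1-regularized logistic classifier under leave-one-participant-out
cross-validation with the lambda grid sweep.
"""

import warnings

from adhf_voice import (
    CohortSpec,
    assign_labels,
    build_model_input,
    effect_size_report,
    fit_final_model,
    lopo_cv,
    odds_ratios,
    select_lambda,
    synth_cohort,
)

warnings.filterwarnings("ignore")

table, truth = synth_cohort(CohortSpec(n_participants=52, seed=1))
table = assign_labels(table)

report = effect_size_report(table)
print("recovered paired Cohen's d (planted value in parentheses):")
for _, row in report.head(4).iterrows():
    print(f"  {row.feature:28s} d = {row.d:+.2f}  ({truth.effects[row.feature]:+.2f}), "
          f"n = {row.n_pairs} pairs")

mi = build_model_input(table, include_mpt=False)
lam, _ = select_lambda(mi.X, mi.y, mi.participants)
cv = lopo_cv(mi.X, mi.y, mi.participants, lam, mi.feature_names)
print(f"\nMPT- model: {len(mi)} input points from {mi.n_candidates} candidates")
print(f"selected lambda = {lam:.4f}")
print("cross-validated metrics:",
      {k: round(v, 3) for k, v in cv.metrics.items()})

final = fit_final_model(mi, lam)
print("\ntop odds ratios (per 1-SD feature increase, admission odds):")
print(odds_ratios(final).head(5).to_string(index=False))
print()
print("With the study-scale effect sizes the classifier sits modestly above")
print("chance, mirroring the weak-single-feature regime of the clinical data;")
print("features with odds ratios far from 1 carry the decision.")
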