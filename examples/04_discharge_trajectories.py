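"""Score every hospital day and summarize discharge-probability trajectories.

The final (non-cross-validated) model scores all daily rows of the
synthetic cohort — admission, intermediate, and discharge days — using the
training-time normalization.  The cohort summary counts how many
multi-day participants ended with a higher discharge probability than
they started with.  A small-multiples figure is written to scratch/ if
that directory exists.
"""

import warnings
from pathlib import Path

from adhf_voice import (
    CohortSpec,
    assign_labels,
    build_model_input,
    fit_final_model,
    plot_trajectories,
    score_all_days,
    select_lambda,
    synth_cohort,
    trajectory_summary,
)

warnings.filterwarnings("ignore")

table, _ = synth_cohort(CohortSpec(n_participants=52, seed=1))
table = assign_labels(table)
mi = build_model_input(table, include_mpt=False)
lam, _ = select_lambda(mi.X, mi.y, mi.participants)
model = fit_final_model(mi, lam)

trajs = score_all_days(model, table)
summary = trajectory_summary(trajs)

print(f"participants scored            : {len(trajs)}")
print(f"with more than one scored day  : {summary.n_multi_day}")
print(f"ended with higher P(discharge) : {summary.n_increased} "
      f"({100 * summary.fraction_increased:.0f} %)")
print("\nlargest first-to-last changes:")
print(summary.changes.head(5).to_string(index=False))

scratch = Path(__file__).resolve().parent.parent / "scratch"
if scratch.is_dir():
    fig = plot_trajectories(trajs)
    fig.savefig(scratch / "trajectories.png", dpi=150)
    print(f"\nwrote {scratch / 'trajectories.png'}")
print()
print("Severity declines toward discharge in the generator, so most")
print("participants' probabilities drift upward, with day-to-day noise.")
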