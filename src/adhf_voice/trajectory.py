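"""Day-to-day discharge-probability trajectories.

The final (non-cross-validated) model scores *every* daily recording, not
just admission and discharge days, giving each participant an ordered
series of discharge probabilities.  Rows are normalized with the column
means/SDs stored in the model at training time — never re-estimated — so
scoring does not depend on which days happen to be scored.  Rows with any
missing model feature are skipped.

The cohort summary counts, among participants with more than one scored
day, the fraction whose last-day discharge probability exceeds their
first-day probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import LogisticModel
from .cohort import assign_labels


@dataclass(frozen=True)
class Trajectory:
    """One participant's ordered (day, discharge probability, class) series."""

    participant: str
    days: np.ndarray
    p_discharge: np.ndarray
    predicted: np.ndarray  # +1 admission / -1 discharge

    def first_to_last_change(self) -> float:
        return float(self.p_discharge[-1] - self.p_discharge[0])

    def __len__(self) -> int:
        return len(self.days)


def score_all_days(model: LogisticModel, table: pd.DataFrame) -> list[Trajectory]:
    """Score every (participant, day) row with the fitted model.

    The table must contain all of the model's feature columns; rows with a
    missing feature are skipped.  Probabilities are deterministic given the
    model and table.
    """
    if model.feature_mean is None or model.feature_scale is None:
        raise ValueError(
            "model lacks stored normalization statistics; fit it with fit_final_model"
        )
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks model features: {missing}")
    if "label" not in table.columns:
        table = assign_labels(table)

    feats = list(model.feature_names)
    trajectories = []
    for pid, grp in table.groupby("participant", sort=True):
        grp = grp.sort_values("day")
        vals = grp[feats].to_numpy(dtype=float)
        ok = np.isfinite(vals).all(axis=1)
        if not ok.any():
            continue
        X = (vals[ok] - model.feature_mean) / model.feature_scale
        p = model.discharge_probability(X)
        pred = model.predict(X)
        trajectories.append(
            Trajectory(
                participant=str(pid),
                days=grp.day.to_numpy()[ok],
                p_discharge=p,
                predicted=pred,
            )
        )
    return trajectories


@dataclass(frozen=True)
class TrajectorySummary:
    n_multi_day: int       # participants with > 1 scored day
    n_increased: int       # of those, how many ended with higher P(discharge)
    fraction_increased: float
    changes: pd.DataFrame  # participant, first-to-last change, ordered desc


def trajectory_summary(trajectories: list[Trajectory]) -> TrajectorySummary:
    """First-to-last probability change per participant and the cohort rate.

    Participants with a single scored day are excluded from the
    denominator.  The change table is ordered greatest-to-least change,
    the order used for trajectory small-multiples plotting.
    """
    rows = [
        {"participant": t.participant, "change": t.first_to_last_change()}
        for t in trajectories
        if len(t) > 1
    ]
    changes = (
        pd.DataFrame(rows, columns=["participant", "change"])
        .sort_values("change", ascending=False)
        .reset_index(drop=True)
    )
    n_multi = len(changes)
    n_up = int((changes.change > 0).sum()) if n_multi else 0
    frac = n_up / n_multi if n_multi else math.nan
    return TrajectorySummary(
        n_multi_day=n_multi,
        n_increased=n_up,
        fraction_increased=frac,
        changes=changes,
    )


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Tidy (participant, day, probability, class) table for serialization."""
    rows = []
    for t in trajectories:
        for day, p, pred in zip(t.days, t.p_discharge, t.predicted):
            rows.append(
                {
                    "participant": t.participant,
                    "day": int(day),
                    "p_discharge": float(p),
                    "predicted": "discharge" if pred == -1 else "admission",
                }
            )
    return pd.DataFrame(rows, columns=["participant", "day", "p_discharge", "predicted"])


def plot_trajectories(trajectories: list[Trajectory], ncols: int = 8, ax_size: float = 1.4):
    """Small-multiples plot of per-participant discharge probabilities.

    Points below the dashed 0.5 line (admission predictions) are drawn as
    red squares, discharge predictions as black dots; panels are ordered by
    first-to-last change, greatest first.
    """
    import matplotlib.pyplot as plt

    order = sorted(
        trajectories,
        key=lambda t: -(t.first_to_last_change() if len(t) > 1 else -np.inf),
    )
    n = len(order)
    nrows = max(1, math.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(ncols * ax_size, nrows * ax_size),
        sharey=True, squeeze=False,
    )
    for k, ax in enumerate(axes.flat):
        if k >= n:
            ax.axis("off")
            continue
        t = order[k]
        x = np.arange(1, len(t) + 1)
        adm = t.predicted == 1
        ax.axhline(0.5, ls="--", lw=0.6, color="gray")
        ax.plot(x, t.p_discharge, lw=0.6, color="gray", zorder=1)
        ax.scatter(x[adm], t.p_discharge[adm], marker="s", s=12, color="red", zorder=2)
        ax.scatter(x[~adm], t.p_discharge[~adm], marker="o", s=12, color="black", zorder=2)
        ax.set_ylim(-0.05, 1.05)
        ax.set_xticks([])
        ax.set_title(t.participant, fontsize=6)
    fig.tight_layout()
    return fig
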