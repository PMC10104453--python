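"""Cohort assembly: per-day feature rows, labels, z-normalization, effects.

A cohort table holds one row per (participant, day) with named feature
columns.  Each participant's first recorded day is labelled ADMISSION (+1)
and the last DISCHARGE (−1); days in between are INTERMEDIATE and are used
only for trajectory scoring.  Model input keeps admission/discharge rows,
drops any row with a missing feature, and z-normalizes each column over
the retained rows.

Paired effect sizes use the paired Cohen's d: the mean admission→discharge
change divided by the sample SD of the per-participant differences.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ADMISSION, DISCHARGE, INTERMEDIATE = 1, -1, 0

KEY_COLUMNS = ("participant", "day", "sensor", "label")

#: Clinical CPP threshold (dB) below which a voice is considered dysphonic.
CPP_NORMATIVE_DB = 14.45


class Label(enum.IntEnum):
    ADMISSION = 1
    INTERMEDIATE = 0
    DISCHARGE = -1


def aggregate_day(task_rows: pd.DataFrame) -> pd.Series:
    """Average same-task repeats into a single value per measure per day.

    All rows must share (participant, day, sensor).  Missing repeats are
    ignored; a measure is missing only if it is missing in every repeat.
    """
    if task_rows.empty:
        raise ValueError("aggregate_day needs at least one task row")
    meta_cols = [c for c in ("participant", "day", "sensor") if c in task_rows]
    for c in meta_cols:
        if task_rows[c].nunique() > 1:
            raise ValueError(f"aggregate_day rows disagree on {c!r}")
    feature_cols = [c for c in task_rows.columns if c not in meta_cols and c != "repeat"]
    out = task_rows[feature_cols].mean(axis=0, skipna=True)
    for c in meta_cols:
        out[c] = task_rows[c].iloc[0]
    return out


def assign_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Label first day ADMISSION, last day DISCHARGE, others INTERMEDIATE.

    A participant with a single usable day contributes one ADMISSION row
    (and is excluded from paired statistics downstream).
    """
    table = table.copy()
    table["label"] = INTERMEDIATE
    for _, grp in table.groupby("participant"):
        first = grp.day.idxmin()
        last = grp.day.idxmax()
        table.loc[first, "label"] = ADMISSION
        if last != first:
            table.loc[last, "label"] = DISCHARGE
    return table


@dataclass(frozen=True)
class ModelInput:
    """Z-normalized design matrix with its provenance and column statistics."""

    X: np.ndarray
    y: np.ndarray
    participants: np.ndarray
    feature_names: tuple[str, ...]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_candidates: int  # labelled rows before missing-data exclusion

    def __len__(self) -> int:
        return len(self.y)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def build_model_input(
    table: pd.DataFrame,
    include_mpt: bool = False,
    normalize: bool = True,
) -> ModelInput:
    """Assemble the admission/discharge design matrix.

    Only first/last-day rows are candidates; with 52 fully recorded
    participants that is 104 input points.  Rows with any missing feature
    are excluded, then columns are z-normalized (mean 0, SD 1) over the
    retained rows.  ``include_mpt=False`` drops MPT columns first (the
    "MPT−" variant), keeping participants who never performed the task.
    """
    if "label" not in table.columns:
        table = assign_labels(table)
    feats = feature_columns(table)
    if not include_mpt:
        feats = [f for f in feats if not _is_mpt_feature(f)]
    if not feats:
        raise ValueError("no feature columns in table")

    labelled = table[table.label != INTERMEDIATE]
    n_candidates = len(labelled)
    complete = labelled.dropna(subset=feats)
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete rows after missing-data exclusion")
    y = complete.label.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("model input must contain both admission and discharge rows")

    X = complete[feats].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    if normalize:
        X = (X - mean) / scale
    return ModelInput(
        X=X,
        y=y,
        participants=complete.participant.to_numpy(),
        feature_names=tuple(feats),
        feature_mean=mean,
        feature_scale=scale,
        n_candidates=n_candidates,
    )


def _is_mpt_feature(name: str) -> bool:
    return name == "mpt" or name.startswith("mpt:") or name.endswith(":mpt")


@dataclass(frozen=True)
class EffectSize:
    feature: str
    d: float
    n_pairs: int


def paired_cohens_d(x1: np.ndarray, x2: np.ndarray) -> EffectSize:
    """Paired Cohen's d = (x̄2 − x̄1) / SD(x2i − x1i) over complete pairs.

    x1 holds admission values and x2 the participant-matched discharge
    values; pairs with either side missing are dropped.  A negative d
    means the measure decreased from admission to discharge.  If the
    differences have zero spread the effect is undefined (NaN d).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must be participant-aligned")
    ok = np.isfinite(x1) & np.isfinite(x2)
    x1, x2 = x1[ok], x2[ok]
    n = len(x1)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    diffs = x2 - x1
    sd = diffs.std(ddof=1)
    d = float((x2.mean() - x1.mean()) / sd) if sd > 0 else math.nan
    return EffectSize(feature="", d=d, n_pairs=n)


def effect_size_report(table: pd.DataFrame) -> pd.DataFrame:
    """Paired d for every feature, sorted by |d| descending.

    Participants without both an admission and a discharge row are
    excluded; per feature, pairs missing either side are dropped.
    """
    if "label" not in table.columns:
        table = assign_labels(table)
    adm = table[table.label == ADMISSION].set_index("participant")
    dis = table[table.label == DISCHARGE].set_index("participant")
    shared = adm.index.intersection(dis.index)
    rows = []
    for feat in feature_columns(table):
        x1 = adm.loc[shared, feat].to_numpy(dtype=float)
        x2 = dis.loc[shared, feat].to_numpy(dtype=float)
        ok = np.isfinite(x1) & np.isfinite(x2)
        if ok.sum() < 2:
            rows.append({"feature": feat, "d": math.nan, "n_pairs": int(ok.sum())})
            continue
        es = paired_cohens_d(x1[ok], x2[ok])
        rows.append({"feature": feat, "d": es.d, "n_pairs": es.n_pairs})
    report = pd.DataFrame(rows)
    return (
        report.reindex(report.d.abs().sort_values(ascending=False).index)
        .reset_index(drop=True)
    )


def cpp_responder_rate(
    admission_cpp: np.ndarray,
    discharge_cpp: np.ndarray,
    below_threshold: bool,
    threshold: float = CPP_NORMATIVE_DB,
) -> float:
    """Percent of speakers in a CPP stratum whose CPP rose with treatment.

    Speakers are stratified by whether their admission CPP lies below the
    normative threshold; within the chosen stratum the rate is the percent
    whose discharge CPP exceeds their admission CPP, rounded to the
    nearest integer percent.
    """
    adm = np.asarray(admission_cpp, dtype=float)
    dis = np.asarray(discharge_cpp, dtype=float)
    ok = np.isfinite(adm) & np.isfinite(dis)
    adm, dis = adm[ok], dis[ok]
    stratum = adm < threshold if below_threshold else adm >= threshold
    if not stratum.any():
        return math.nan
    return float(round(100.0 * np.mean(dis[stratum] > adm[stratum])))
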