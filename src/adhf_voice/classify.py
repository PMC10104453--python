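"""L1-regularized logistic classification of admission vs discharge.

The model scores a z-normalized feature vector x as
``f(x) = β0 + Σ βj xj`` and is fitted by minimizing the mean logistic loss
``log(1 + exp(-y f(x)))`` over labels y ∈ {+1 admission, −1 discharge},
plus an L1 penalty ``λ Σ |βj|`` on the feature weights (the intercept is
unpenalized, so for large enough λ the model falls back to predicting the
majority class).  The sign convention is fixed globally: +1 = admission,
so the discharge probability of a row is σ(−f(x)) and a row is predicted
"discharge" iff that probability strictly exceeds 0.5.

Evaluation uses leave-one-participant-out cross-validation: each fold
trains on every participant but one and scores all of the held-out
participant's rows, so each row is scored exactly once.  λ is chosen from
a 30-point geometric grid on [0.001, 1] by minimum cross-validated loss.

The optimizer is FISTA (accelerated proximal gradient with
soft-thresholding), which is deterministic for a fixed input — the
objective is convex, so the fit is reproducible to solver tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAMBDA_GRID_SIZE = 30
LAMBDA_RANGE = (0.001, 1.0)
MAX_ITER = 10_000
COEF_TOL = 1e-8


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class LogisticModel:
    """Fitted linear classifier: score f(x) = beta0 + x @ beta."""

    beta0: float
    beta: np.ndarray
    lam: float
    feature_names: tuple[str, ...] = ()
    converged: bool = True
    n_iter: int = 0
    # z-normalization statistics of the training table, stored so that
    # intermediate days can be scored on the training scale
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta

    def discharge_probability(self, X: np.ndarray) -> np.ndarray:
        """P(discharge) = σ(−f(x)) under the +1 = admission convention."""
        return _sigmoid(-self.decision(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 (admission) unless P(discharge) > 0.5; ties go to admission."""
        return np.where(self.discharge_probability(X) > 0.5, -1, 1)

    def nonzero_features(self) -> tuple[str, ...]:
        names = self.feature_names or tuple(f"x{j}" for j in range(len(self.beta)))
        return tuple(n for n, b in zip(names, self.beta) if b != 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic_loss(y: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Elementwise log(1 + exp(−y·f)), computed in softplus form."""
    margin = -np.asarray(y, dtype=float) * np.asarray(f, dtype=float)
    # log1p(exp(m)) = max(m, 0) + log1p(exp(-|m|))
    return np.maximum(margin, 0.0) + np.log1p(np.exp(-np.abs(margin)))


def _objective(X, y, beta0, beta, lam) -> float:
    f = beta0 + X @ beta
    return float(np.mean(logistic_loss(y, f)) + lam * np.sum(np.abs(beta)))


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_names: tuple[str, ...] = (),
    max_iter: int = MAX_ITER,
    tol: float = COEF_TOL,
    warm_start: LogisticModel | None = None,
) -> LogisticModel:
    """Minimize mean logistic loss + λ·Σ|βj| by FISTA (intercept free).

    Deterministic for fixed inputs.  If the coefficient change has not
    dropped below `tol` within `max_iter` iterations the model is returned
    with ``converged=False`` and a ConvergenceWarning — on linearly
    separable data at λ=0 the minimizer diverges and the cap is the only
    stopping rule, but the decision boundary is still usable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1.0, 1.0))) or len(classes) < 2:
        raise ValueError("y must contain both +1 and -1 labels")
    n, m = X.shape

    Xt = np.concatenate([np.ones((n, 1)), X], axis=1)
    # Lipschitz constant of the logistic gradient: ||X~||^2 / (4n)
    lip = np.linalg.norm(Xt, 2) ** 2 / (4.0 * n)
    step = 1.0 / lip

    if warm_start is not None and len(warm_start.beta) == m:
        w = np.concatenate([[warm_start.beta0], warm_start.beta])
    else:
        w = np.zeros(m + 1)
    z = w.copy()
    t_accel = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        margin = y * (Xt @ z)
        grad = -(Xt.T @ (y * _sigmoid(-margin))) / n
        w_new = z - step * grad
        # soft-threshold the feature weights only
        thresh = lam * step
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(np.abs(w_new[1:]) - thresh, 0.0)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_accel**2))
        z = w_new + ((t_accel - 1.0) / t_new) * (w_new - w)
        delta = np.max(np.abs(w_new - w))
        w, t_accel = w_new, t_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"L1 logistic fit did not converge in {max_iter} iterations "
            f"(last coefficient change {delta:.2e}, lambda={lam})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return LogisticModel(
        beta0=float(w[0]),
        beta=w[1:],
        lam=lam,
        feature_names=tuple(feature_names),
        converged=converged,
        n_iter=it,
    )


def lambda_grid(
    n: int = LAMBDA_GRID_SIZE,
    lo: float = LAMBDA_RANGE[0],
    hi: float = LAMBDA_RANGE[1],
) -> np.ndarray:
    """n logarithmically spaced penalties from lo to hi inclusive."""
    if n < 1:
        raise ValueError("need at least one grid point")
    if n == 1:
        return np.array([lo])
    if not 0 < lo < hi:
        raise ValueError("require 0 < lo < hi")
    return np.geomspace(lo, hi, n)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Per-row leave-one-participant-out predictions and summary metrics."""

    records: pd.DataFrame  # participant, y_true, y_pred, p_discharge, scored
    lam: float
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def confusion(self) -> dict[str, int]:
        r = self.records[self.records.scored]
        return {
            "TA": int(((r.y_true == 1) & (r.y_pred == 1)).sum()),
            "FD": int(((r.y_true == 1) & (r.y_pred == -1)).sum()),
            "TD": int(((r.y_true == -1) & (r.y_pred == -1)).sum()),
            "FA": int(((r.y_true == -1) & (r.y_pred == 1)).sum()),
        }

    def mean_loss(self) -> float:
        r = self.records[self.records.scored]
        f = -np.log(
            np.clip(r.p_discharge, 1e-12, 1 - 1e-12)
            / np.clip(1 - r.p_discharge, 1e-12, 1 - 1e-12)
        )
        return float(np.mean(logistic_loss(r.y_true.to_numpy(), f)))


def lopo_cv(
    X: np.ndarray,
    y: np.ndarray,
    participants: np.ndarray,
    lam: float,
    feature_names: tuple[str, ...] = (),
) -> CVResult:
    """Leave-one-participant-out CV: one fold per participant.

    Each row is scored exactly once, by the model trained with its
    participant held out.  A fold whose training set lacks one class is
    skipped with a warning and its rows marked unscored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    participants = np.asarray(participants)
    uniq = pd.unique(participants)
    if len(uniq) < 3:
        raise ValueError("leave-one-participant-out CV needs at least 3 participants")

    rows = []
    for pid in uniq:
        test = participants == pid
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(
                f"fold for participant {pid!r} has single-class training data; skipped",
                stacklevel=2,
            )
            for i in np.flatnonzero(test):
                rows.append((participants[i], y[i], np.nan, np.nan, False))
            continue
        model = fit_l1_logistic(X[train], y[train], lam, feature_names)
        p = model.discharge_probability(X[test])
        pred = model.predict(X[test])
        for i, idx in enumerate(np.flatnonzero(test)):
            rows.append((participants[idx], y[idx], pred[i], p[i], True))

    records = pd.DataFrame(
        rows, columns=["participant", "y_true", "y_pred", "p_discharge", "scored"]
    )
    result = CVResult(records=records, lam=lam)
    result.metrics = classification_metrics(result)
    return result


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    participants: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """λ minimizing the mean cross-validated logistic loss (ties → smallest).

    Returns the selected λ and the per-λ loss table.
    """
    grid = np.sort(lambda_grid() if grid is None else np.asarray(grid, dtype=float))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    participants = np.asarray(participants)
    uniq = pd.unique(participants)

    # fold-outer / λ-inner so each fold's fits warm-start down the sweep
    loss_sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    for pid in uniq:
        test = participants == pid
        train = ~test
        if len(np.unique(y[train])) < 2:
            continue
        warm = None
        for g in range(len(grid) - 1, -1, -1):
            warm = fit_l1_logistic(X[train], y[train], grid[g], warm_start=warm)
            f = warm.decision(X[test])
            loss_sums[g] += logistic_loss(y[test], f).sum()
            counts[g] += test.sum()
    table = pd.DataFrame({"lam": grid, "cv_loss": loss_sums / np.maximum(counts, 1)})
    best = table.loc[table.cv_loss.idxmin()]  # idxmin takes the first = smallest λ
    return float(best.lam), table


def classification_metrics(cv: CVResult) -> dict[str, float]:
    """Accuracy, AUC, TAR, TDR, APV, DPV with admission as the positive class.

    TAR (true admission rate) is sensitivity, TDR specificity; APV/DPV are
    the positive/negative predictive values.  AUC is the rank statistic
    over discharge probabilities with half-credit for ties.  Metrics whose
    denominator is empty are NaN.
    """
    c = cv.confusion
    ta, fd, td, fa = c["TA"], c["FD"], c["TD"], c["FA"]
    total = ta + fd + td + fa

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    r = cv.records[cv.records.scored]
    adm = r.loc[r.y_true == 1, "p_discharge"].to_numpy()
    dis = r.loc[r.y_true == -1, "p_discharge"].to_numpy()
    if len(adm) and len(dis):
        # P(discharge score of a discharge row > that of an admission row)
        greater = (dis[:, None] > adm[None, :]).sum()
        ties = (dis[:, None] == adm[None, :]).sum()
        auc = (greater + 0.5 * ties) / (len(adm) * len(dis))
    else:
        auc = math.nan
    return {
        "accuracy": ratio(ta + td, total),
        "auc": float(auc),
        "tar": ratio(ta, ta + fd),
        "tdr": ratio(td, td + fa),
        "apv": ratio(ta, ta + fa),
        "dpv": ratio(td, td + fd),
    }


def fit_final_model(model_input, lam: float) -> LogisticModel:
    """Refit on all admission/discharge rows (no CV) at the given λ.

    The returned model carries the training-table column means/SDs so that
    intermediate-day rows can later be scored on the same scale.  This is
    the model used for odds-ratio reporting and trajectory scoring.
    """
    import dataclasses

    model = fit_l1_logistic(
        model_input.X, model_input.y, lam, model_input.feature_names
    )
    return dataclasses.replace(
        model,
        feature_mean=np.asarray(model_input.feature_mean, dtype=float),
        feature_scale=np.asarray(model_input.feature_scale, dtype=float),
    )


def odds_ratios(model: LogisticModel) -> pd.DataFrame:
    """Per-feature odds ratios e^β, sorted by |log OR| descending.

    On z-normalized inputs each ratio is the multiplicative change in
    discharge odds per one-SD increase of the feature; ratios farther from
    1 indicate greater predictive power.
    """
    names = model.feature_names or tuple(f"x{j}" for j in range(len(model.beta)))
    df = pd.DataFrame(
        {
            "feature": names,
            "beta": model.beta,
            "odds_ratio": np.exp(model.beta),
            # under the +1 = admission convention, e^β multiplies the
            # admission odds; the discharge-odds view is its reciprocal
            "discharge_odds_ratio": np.exp(-model.beta),
        }
    )
    df["abs_log_or"] = np.abs(df.beta)
    return (
        df.sort_values("abs_log_or", ascending=False)
        .drop(columns="abs_log_or")
        .reset_index(drop=True)
    )
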