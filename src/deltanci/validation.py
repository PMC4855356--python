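"""OECD-style model quality metrics and the over-fit diagnostic.

All metrics are reported in kcal/mol (denormalized). R^2 is the squared
Pearson correlation on the training set (goodness-of-fit); q^2 is the
external predictive squared correlation on the test set and q^2cv its
cross-validated analogue on out-of-fold predictions, both in the
external-validation form

    q^2 = 1 - sum (p_i - o_i)^2 / sum (o_i - ybar_train)^2,

which may be negative for models worse than predicting the training mean.
Values of q^2 and q^2cv above 0.5 are conventionally deemed valid, and
R^2 - q^2cv > 0.3 flags an over-fit model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OVERFIT_GAP = 0.3
VALIDITY_THRESHOLD = 0.5


class UndefinedMetricError(ValueError):
    """Metric undefined for these inputs (e.g. constant observations)."""


def _pair(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError(f"length mismatch: {p.size} vs {o.size}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, o


def rmse(pred, obs) -> float:
    """Root mean square error."""
    p, o = _pair(pred, obs)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def mae(pred, obs) -> float:
    """Mean absolute error."""
    p, o = _pair(pred, obs)
    return float(np.mean(np.abs(p - o)))


def r2_fit(pred, obs) -> float:
    """Squared Pearson correlation (goodness-of-fit)."""
    p, o = _pair(pred, obs)
    if p.size < 2:
        raise UndefinedMetricError("need at least 2 points")
    if np.ptp(o) == 0.0 or np.ptp(p) == 0.0:
        raise UndefinedMetricError("constant vector: correlation undefined")
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)


def r2_determination(pred, obs) -> float:
    """Coefficient-of-determination variant: 1 - SS_res/SS_tot."""
    p, o = _pair(pred, obs)
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0.0:
        raise UndefinedMetricError("constant observations")
    return float(1.0 - np.sum((p - o) ** 2) / ss_tot)


def q2(pred_test, obs_test, train_mean: float) -> float:
    """Predictive squared correlation against an external test set.

    The denominator centers the test observations on the *training-set*
    mean (external-validation convention); the value may be negative.
    """
    p, o = _pair(pred_test, obs_test)
    denom = np.sum((o - train_mean) ** 2)
    if denom == 0.0:
        raise UndefinedMetricError(
            "test observations all equal the training mean"
        )
    return float(1.0 - np.sum((p - o) ** 2) / denom)


def q2cv(oof_pred, obs_train) -> float:
    """Cross-validated squared correlation from out-of-fold predictions."""
    p, o = _pair(oof_pred, obs_train)
    return q2(p, o, float(o.mean()))


@dataclass
class ValidationReport:
    """Quality metrics of one trained correction model."""

    rmse_train: float
    mae_train: float
    r2: float
    q2cv: float
    n_train: int
    rmse_test: float | None = None
    mae_test: float | None = None
    q2: float | None = None
    n_test: int = 0

    @property
    def overfit_flag(self) -> bool:
        return self.r2 - self.q2cv > OVERFIT_GAP

    @property
    def valid(self) -> bool:
        """Both predictive-power metrics above the 0.5 validity threshold."""
        checks = [self.q2cv > VALIDITY_THRESHOLD]
        if self.q2 is not None:
            checks.append(self.q2 > VALIDITY_THRESHOLD)
        return all(checks)

    def to_dict(self) -> dict:
        return {
            "rmse_train": self.rmse_train,
            "mae_train": self.mae_train,
            "rmse_test": self.rmse_test,
            "mae_test": self.mae_test,
            "r2": self.r2,
            "q2": self.q2,
            "q2cv": self.q2cv,
            "overfit_flag": self.overfit_flag,
            "valid": self.valid,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def build_report(
    *,
    train_pred,
    train_obs,
    oof_pred,
    test_pred=None,
    test_obs=None,
) -> ValidationReport:
    """Assemble a :class:`ValidationReport` from one pipeline run."""
    train_pred = np.asarray(train_pred, dtype=float)
    train_obs = np.asarray(train_obs, dtype=float)
    report = ValidationReport(
        rmse_train=rmse(train_pred, train_obs),
        mae_train=mae(train_pred, train_obs),
        r2=r2_fit(train_pred, train_obs),
        q2cv=q2cv(oof_pred, train_obs),
        n_train=train_obs.size,
    )
    if test_pred is not None and test_obs is not None:
        report.rmse_test = rmse(test_pred, test_obs)
        report.mae_test = mae(test_pred, test_obs)
        report.q2 = q2(test_pred, test_obs, float(train_obs.mean()))
        report.n_test = np.asarray(test_obs).size
    return report
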