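"""Validation-set performance indicators.

All metrics compare laboratory-measured values (``observed``) with model
predictions (``predicted``):

* RMSEP - root mean squared error of prediction,
* R^2 - coefficient of determination against the observed mean (can be
  negative for models worse than the mean),
* RPIQ - interquartile range of the observed values divided by RMSEP
  (quartiles by linear interpolation, "type 7"),
* bias - mean(observed - predicted), so systematic over-prediction is
  negative,
* Lin's concordance correlation coefficient (CCC) - agreement with the
  1:1 line, computed with n-1 moment denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import DegenerateInputError, UndefinedMetricError


@dataclass
class ValidationMetrics:
    rmsep: float
    r2: float
    rpiq: float
    bias: float
    ccc: float
    n: int
    iqr: float

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if len(obs) != len(pred):
        raise ValueError("observed and predicted lengths differ")
    return obs, pred


def rmsep(observed, predicted) -> float:
    obs, pred = _pair(observed, predicted)
    if len(obs) < 1:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r2_validation(observed, predicted) -> float:
    obs, pred = _pair(observed, predicted)
    if len(obs) < 2:
        raise ValueError("need at least 2 pairs")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("observed values have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def iqr(values) -> float:
    """Interquartile range with linear-interpolation (type-7) quartiles."""
    values = np.asarray(values, dtype=float).ravel()
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def rpiq(observed, rmsep_value: float) -> float:
    obs = np.asarray(observed, dtype=float).ravel()
    if len(obs) < 4:
        raise ValueError("need at least 4 observed values for quartiles")
    if rmsep_value <= 0:
        raise UndefinedMetricError("RPIQ is undefined for RMSEP <= 0")
    return iqr(obs) / rmsep_value


def rpiq_from_iqr(iqr_value: float, rmsep_value: float) -> float:
    """RPIQ from an already-known interquartile range (e.g. printed summary
    statistics of a validation set)."""
    if rmsep_value <= 0:
        raise UndefinedMetricError("RPIQ is undefined for RMSEP <= 0")
    return iqr_value / rmsep_value


def bias(observed, predicted) -> float:
    obs, pred = _pair(observed, predicted)
    if len(obs) < 1:
        raise ValueError("need at least 1 pair")
    return float(np.mean(obs - pred))


def lins_ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient,
    2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), n-1 denominators."""
    obs, pred = _pair(observed, predicted)
    if len(obs) < 2:
        raise ValueError("need at least 2 pairs")
    s_x = np.var(obs, ddof=1)
    s_y = np.var(pred, ddof=1)
    if s_x == 0 or s_y == 0:
        raise DegenerateInputError("zero variance in observed or predicted")
    s_xy = float(np.cov(obs, pred, ddof=1)[0, 1])
    return float(2 * s_xy / (s_x + s_y + (obs.mean() - pred.mean()) ** 2))


def evaluate(observed, predicted) -> ValidationMetrics:
    """All five indicators bundled, plus n and the observed IQR.

    A perfect prediction has RMSEP = 0, for which RPIQ is undefined; this
    raises :class:`UndefinedMetricError` rather than returning infinity.
    """
    obs, pred = _pair(observed, predicted)
    rm = rmsep(obs, pred)
    return ValidationMetrics(
        rmsep=rm,
        r2=r2_validation(obs, pred),
        rpiq=rpiq(obs, rm),
        bias=bias(obs, pred),
        ccc=lins_ccc(obs, pred),
        n=len(obs),
        iqr=iqr(obs),
    )
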