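"""Control-anchored classification and the composite progression score.

Two classifiers are built from the four discriminating CGM parameters
(glucose SD, TA140, TA160, TA180):

* **100 %-specificity thresholds** — the cutoff for each parameter is its
  maximum over the control group, and a case is flagged only when strictly
  above the cutoff.  By construction no derivation control is flagged, so
  specificity on those controls is exactly 1.  The any-k rule (default
  k = 2) flags a participant when at least k parameters are elevated.
* **Progression Prediction Score (PPS)** — an in-sample maximum-likelihood
  logistic regression of 1-year progression on the four parameters in their
  natural units (no standardization); the score is the fitted probability.
  Scores are banded at 0.19 and 0.4 (low < 0.19 <= mid <= 0.4 < high).

On complete separation the logistic fit falls back to a small L2 (ridge)
penalty, recorded in the model diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import DISCRIMINATING_METRICS


@dataclass(frozen=True)
class ThresholdSet:
    """Per-metric cutoffs derived from controls; flag iff strictly greater."""

    cutoffs: Mapping[str, float]
    n_controls: int

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(self.cutoffs)

    def is_elevated(self, metrics: Mapping[str, float]) -> dict[str, bool]:
        out = {}
        for name, cut in self.cutoffs.items():
            if name not in metrics or metrics[name] is None:
                raise ValueError(f"missing metric: {name}")
            out[name] = float(metrics[name]) > cut
        return out

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        """Display cutoffs; classification always uses the exact values."""
        return {k: round(v, decimals) for k, v in self.cutoffs.items()}

    def to_json(self) -> str:
        return json.dumps(
            {"cutoffs": dict(self.cutoffs), "direction": "flag_if_greater",
             "n_controls": self.n_controls},
            sort_keys=True, indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        d = json.loads(text)
        return cls(cutoffs=d["cutoffs"], n_controls=d["n_controls"])


def derive_thresholds(
    control_metrics: pd.DataFrame | Sequence[Mapping[str, float]],
    metric_names: Sequence[str] = DISCRIMINATING_METRICS,
) -> ThresholdSet:
    """Cutoff = exact control-group maximum of each metric."""
    df = pd.DataFrame(control_metrics)
    if df.empty:
        raise ValueError("control metrics are empty")
    missing = [m for m in metric_names if m not in df.columns]
    if missing:
        raise ValueError(f"metrics not present in control table: {missing}")
    cutoffs = {m: float(df[m].max()) for m in metric_names}
    return ThresholdSet(cutoffs=cutoffs, n_controls=len(df))


def count_elevated(metrics: Mapping[str, float], thresholds: ThresholdSet) -> int:
    """Number of threshold metrics strictly above their cutoff."""
    return int(sum(thresholds.is_elevated(metrics).values()))


def any_k_rule(
    metrics: Mapping[str, float], thresholds: ThresholdSet, k: int = 2
) -> bool:
    """True iff at least ``k`` of the threshold metrics are elevated."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(thresholds.cutoffs):
        raise ValueError("k exceeds the number of threshold metrics")
    return count_elevated(metrics, thresholds) >= k


@dataclass(frozen=True)
class PPSModel:
    """Logistic composite of the four CGM parameters -> progression probability."""

    intercept: float
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float] | None
    n_fit: int
    converged: bool
    penalized: bool
    ridge_alpha: float | None = None
    horizon_years: float = 1.0

    def score(self, metrics: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Fitted probability in (0, 1) for each row."""
        df = pd.DataFrame(metrics if isinstance(metrics, pd.DataFrame) else [metrics])
        eta = np.full(len(df), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            if name not in df.columns:
                raise ValueError(f"missing metric: {name}")
            eta += coef * df[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": dict(self.coefficients),
                "standard_errors": dict(self.standard_errors)
                if self.standard_errors is not None else None,
                "n_fit": self.n_fit,
                "converged": self.converged,
                "penalized": self.penalized,
                "ridge_alpha": self.ridge_alpha,
                "horizon_years": self.horizon_years,
            },
            sort_keys=True, indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PPSModel":
        d = json.loads(text)
        return cls(**d)


def fit_pps(
    metric_rows: pd.DataFrame,
    outcome: Sequence[bool],
    metric_names: Sequence[str] = DISCRIMINATING_METRICS,
    horizon_years: float = 1.0,
    ridge_alpha: float = 1e-4,
) -> PPSModel:
    """Maximum-likelihood logistic fit of the within-horizon outcome.

    ``outcome`` is the binary event indicator (progressed within the
    horizon).  With complete separation or a non-converged MLE the fit is
    repeated with an L2 penalty of ``ridge_alpha`` per parameter and the
    model is marked ``penalized``.
    """
    y = np.asarray(outcome, dtype=float)
    X = metric_rows[list(metric_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite inputs")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    Xc = sm.add_constant(X, has_constant="add")

    params = bse = None
    converged = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is handled explicitly below
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
            params = res.params
            bse = res.bse
    except Exception:  # PerfectSeparationError, LinAlgError, ...
        converged = False

    penalized = params is None
    if penalized:
        glm = sm.GLM(y, Xc, family=sm.families.Binomial())
        res = glm.fit_regularized(alpha=ridge_alpha, L1_wt=0.0)
        params = np.asarray(res.params)
        bse = None
        converged = True

    names = list(metric_names)
    return PPSModel(
        intercept=float(params[0]),
        coefficients={n: float(c) for n, c in zip(names, params[1:])},
        standard_errors=None if bse is None
        else {n: float(s) for n, s in zip(["intercept"] + names, bse)},
        n_fit=len(y),
        converged=converged,
        penalized=penalized,
        ridge_alpha=ridge_alpha if penalized else None,
        horizon_years=horizon_years,
    )


def pps_band(score: float, cut_low: float = 0.19, cut_high: float = 0.4) -> str:
    """Band a score: low < cut_low <= mid <= cut_high < high (cuts inclusive to mid)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must be in [0, 1]")
    if score < cut_low:
        return "low"
    if score <= cut_high:
        return "mid"
    return "high"


def progression_outcome(
    followup_years: Sequence[float],
    progressed: Sequence[bool],
    progression_time: Sequence[float],
    horizon_years: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Eligibility mask and within-horizon outcome for the PPS fit.

    Eligible: followed for at least the horizon, or progressed at any time.
    Outcome: progressed at or before the horizon.
    """
    fu = np.asarray(followup_years, dtype=float)
    ev = np.asarray(progressed, dtype=bool)
    t = np.asarray(progression_time, dtype=float)
    eligible = (fu >= horizon_years) | ev
    outcome = ev & (t <= horizon_years)
    return eligible, outcome
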