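"""LDH cytotoxicity dose-response analysis.

Converts plate absorbances to percent cytotoxicity relative to untreated
(negative) and lysed (positive) control wells, fits four-parameter logistic
(4PL) dose-response curves, inverts them for ICx estimation, and classifies
chemicals as acutely cytotoxic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "four_param_logistic",
    "cytotoxicity_percent",
    "FourParamLogistic",
    "fit_4pl",
    "estimate_icx",
    "classify_acute",
    "AcuteClassification",
]


def four_param_logistic(x, b, c, d, e):
    """Evaluate the 4PL curve f(x) = c + (d - c) / (1 + (x/e)^(-b)).

    ``c`` and ``d`` are the lower/upper response asymptotes, ``e`` the
    inflection concentration and ``b`` the hill slope.  The dose axis is
    kept in natural (not log) scale so x = 0 is well defined: for b > 0
    the curve rises from ``c`` at zero dose towards ``d``; for b < 0 it
    falls from ``d``.
    """
    x = np.asarray(x, dtype=float)
    if e <= 0:
        raise ValueError("inflection concentration e must be positive")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = np.where(x > 0, (x / e) ** b, 0.0 if b > 0 else np.inf)
        frac = np.where(np.isinf(t), 1.0, t / (1.0 + t))
    return c + (d - c) * frac


def cytotoxicity_percent(abs_sample, abs_nc, abs_pc):
    """Percent cytotoxicity from absorbances: 100*(A_s - A_nc)/(A_pc - A_nc).

    ``abs_nc`` is the untreated-well (negative control) absorbance and
    ``abs_pc`` the fully lysed (positive control) absorbance.  The result is
    0% at the negative control and 100% at the positive control, and may
    fall outside [0, 100] for wells beyond the controls.
    """
    abs_sample = np.asarray(abs_sample, dtype=float)
    denom = float(abs_pc) - float(abs_nc)
    if denom == 0:
        raise ZeroDivisionError(
            "positive- and negative-control absorbances are equal; "
            "cytotoxicity percentage is undefined"
        )
    out = 100.0 * (abs_sample - float(abs_nc)) / denom
    return float(out) if out.ndim == 0 else out


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose-response regression.

    Least-squares fit of ``f(x) = c + (d - c)/(1 + (x/e)^b)`` on natural
    concentration scale.  Follows the scikit-learn estimator protocol:
    ``fit(X, y)`` with X the concentrations, ``predict(X)`` the fitted
    response, plus an analytic ``icx`` inversion.

    Parameters
    ----------
    max_nfev : int
        Function-evaluation budget for the trust-region least-squares solver.

    Attributes
    ----------
    b_, c_, d_, e_ : float
        Hill slope, lower asymptote, upper asymptote (percent response), and
        inflection concentration (same units as the dose axis).
    residual_sd_ : float
        Residual standard deviation of the fit.
    converged_ : bool
        False for degenerate (flat) input or solver failure; ICx is then
        unavailable.
    flat_ : bool
        True when the responses carry no dose information (all identical).
    """

    def __init__(self, max_nfev: int = 10_000):
        self.max_nfev = max_nfev

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a 1-d concentration vector")
        return x

    def fit(self, X, y):
        x = self._as_1d(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y have mismatched lengths")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite concentrations or responses")
        if (x < 0).any():
            raise ValueError("negative concentrations")
        self.n_features_in_ = 1

        self.flat_ = bool(np.ptp(y) == 0.0)
        if self.flat_:
            self.b_, self.c_, self.d_ = 1.0, float(y[0]), float(y[0])
            self.e_ = float(np.exp(np.mean(np.log(x[x > 0])))) if (x > 0).any() else 1.0
            self.residual_sd_ = 0.0
            self.converged_ = False
            return self

        c0, d0 = float(np.min(y)), float(np.max(y))
        pos = x[x > 0]
        e0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
        p0 = np.array([1.0, c0, d0, e0])

        span = d0 - c0

        def resid(p):
            return four_param_logistic(x, *p) - y

        sol = optimize.least_squares(
            resid,
            p0,
            bounds=(
                [-50.0, c0 - 10 * span, c0 - 10 * span, 1e-12],
                [50.0, d0 + 10 * span, d0 + 10 * span, np.inf],
            ),
            max_nfev=self.max_nfev,
        )
        self.b_, self.c_, self.d_, self.e_ = (float(v) for v in sol.x)
        dof = max(x.size - 4, 1)
        self.residual_sd_ = float(np.sqrt(2.0 * sol.cost / dof))
        self.converged_ = bool(sol.success)
        return self

    def predict(self, X):
        check_is_fitted(self, "b_")
        return four_param_logistic(self._as_1d(X), self.b_, self.c_, self.d_, self.e_)

    def icx(self, x_percent: float) -> float:
        """Concentration giving ``x_percent`` response: the analytic inverse
        e * ((d - c)/(x - c) - 1)^(-1/b).  Requires c < x < d (ascending) or
        d < x < c (descending)."""
        check_is_fitted(self, "b_")
        if not self.converged_:
            raise RuntimeError("ICx unavailable: fit did not converge")
        lo, hi = sorted((self.c_, self.d_))
        if not (lo < x_percent < hi):
            raise ValueError(
                f"target response {x_percent} outside the open asymptote "
                f"interval ({lo:.4g}, {hi:.4g})"
            )
        return float(
            self.e_ * ((self.d_ - self.c_) / (x_percent - self.c_) - 1.0) ** (-1.0 / self.b_)
        )


@dataclasses.dataclass
class DoseResponseFit:
    """Summary of a fitted 4PL curve with ICx inversions."""

    b: float
    c: float
    d: float
    e: float
    residual_sd: float
    converged: bool
    flat: bool
    icx: dict

    @property
    def params(self) -> tuple:
        return (self.b, self.c, self.d, self.e)


def fit_4pl(concentrations, responses, icx_levels: Sequence[float] = (10.0, 50.0)) -> DoseResponseFit:
    """Fit a 4PL curve and report parameters plus requested ICx values."""
    est = FourParamLogistic().fit(concentrations, responses)
    icx: dict = {}
    for level in icx_levels:
        try:
            icx[float(level)] = est.icx(level)
        except (ValueError, RuntimeError):
            icx[float(level)] = math.nan
    return DoseResponseFit(
        b=est.b_, c=est.c_, d=est.d_, e=est.e_,
        residual_sd=est.residual_sd_, converged=est.converged_, flat=est.flat_,
        icx=icx,
    )


def estimate_icx(fit, x: float) -> float:
    """Invert a fitted 4PL curve at response level ``x`` (percent)."""
    if isinstance(fit, FourParamLogistic):
        return fit.icx(x)
    est = FourParamLogistic()
    est.b_, est.c_, est.d_, est.e_ = fit.b, fit.c, fit.d, fit.e
    est.converged_ = fit.converged
    est.n_features_in_ = 1
    return est.icx(x)


@dataclasses.dataclass
class AcuteClassification:
    chemical: str
    cytotoxic: bool
    f_pvalue: float
    max_response: float
    fit: DoseResponseFit


def classify_acute(
    plate: pd.DataFrame,
    f_alpha: float = 0.05,
    min_response: float = 10.0,
    icx_levels: Sequence[float] = (10.0, 50.0),
) -> Mapping[str, AcuteClassification]:
    """Classify each chemical on an LDH plate as acutely cytotoxic or not.

    ``plate`` columns: well_id, chemical, concentration_uM, role
    (sample|NC|PC), absorbance.  Responses are converted to percent
    cytotoxicity against the plate's mean NC/PC absorbances, a 4PL curve is
    fitted per chemical, and a chemical is called cytotoxic when the 4PL fit
    beats a constant-mean model (extra-sum-of-squares F-test, p < ``f_alpha``)
    and the fitted maximal response reaches ``min_response`` percent.
    """
    required = {"chemical", "concentration_uM", "role", "absorbance"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    nc = plate.loc[plate["role"] == "NC", "absorbance"]
    pc = plate.loc[plate["role"] == "PC", "absorbance"]
    if nc.empty or pc.empty:
        raise ValueError("plate must contain NC and PC control wells")
    abs_nc, abs_pc = float(nc.mean()), float(pc.mean())

    out: dict[str, AcuteClassification] = {}
    samples = plate[plate["role"] == "sample"]
    for chem, grp in samples.groupby("chemical", sort=True):
        x = grp["concentration_uM"].to_numpy(float)
        y = cytotoxicity_percent(grp["absorbance"].to_numpy(float), abs_nc, abs_pc)
        fit = fit_4pl(x, y, icx_levels=icx_levels)
        if not fit.converged:
            out[str(chem)] = AcuteClassification(str(chem), False, 1.0, float(np.ptp(y)) if y.size else 0.0, fit)
            continue
        pred = four_param_logistic(x, *fit.params)
        rss1 = float(np.sum((y - pred) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        dof1 = x.size - 4
        if dof1 <= 0:
            raise ValueError(f"too few wells for {chem}: need > 4")
        if rss1 <= 0:  # perfect fit: F-test degenerates, treat as maximal evidence
            f_p = 0.0 if rss0 > rss1 else 1.0
        else:
            f_stat = ((rss0 - rss1) / 3.0) / (rss1 / dof1)
            f_p = float(stats.f.sf(f_stat, 3, dof1))
        max_resp = float(np.max(pred))
        out[str(chem)] = AcuteClassification(
            chemical=str(chem),
            cytotoxic=bool(f_p < f_alpha and max_resp >= min_response),
            f_pvalue=f_p,
            max_response=max_resp,
            fit=fit,
        )
    return out
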