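"""Single-hit Poisson limiting-dilution analysis.

Estimates the tumour-initiating-cell frequency from all-or-none
dose/response data: under the single-hit model an animal transplanted
with ``d`` cells responds unless none of them initiates, so

    P(response | dose d) = 1 - (1 - theta)^d

with theta the per-cell hit rate.  The exact ``(1 - theta)^d`` form is
used rather than the exp(-theta*d) approximation; the two agree to
<0.5% at typical transplantation doses but the exact form remains
correct at small doses.  Frequencies are reported the conventional way
as "1 in N" with N = 1/theta.

The API follows the Model/Results idiom: build a
:class:`SingleHitModel` from an :class:`~marrowmap.containers.LDADataset`
(or DataFrame), call :meth:`~SingleHitModel.fit`, and read estimates,
confidence intervals and :meth:`~SingleHitResults.summary` off the
results object.  :func:`compare_groups` is the likelihood-ratio test of
equal frequency between two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit

from .containers import LDADataset
from .errors import BoundaryEstimateError, ValidationError

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _log_likelihood(theta: float, dose: np.ndarray, n: np.ndarray,
                    r: np.ndarray) -> float:
    """Binomial log-likelihood of the single-hit model at theta."""
    if not (0.0 < theta < 1.0):
        return -np.inf
    log_q = dose * np.log1p(-theta)          # log P(no response)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(log_q))     # log P(response)
    ll = r * log_p + (n - r) * log_q
    return float(np.sum(ll))


@dataclass
class SingleHitResults:
    """Fitted single-hit frequency with 95% CI on the cloglog scale.

    ``frequency_denominator`` is the "1 in N" value (N = 1/theta_hat);
    the CI denominators bracket it, the lower denominator corresponding
    to the upper frequency bound.
    """

    group_id: str
    theta_hat: float
    frequency_denominator: float
    ci_lower_denominator: float
    ci_upper_denominator: float
    log_likelihood: float
    converged: bool
    se_cloglog: float
    model: "SingleHitModel"

    def predict_nonresponse(self, doses) -> np.ndarray:
        """Fitted fraction of non-responding animals at each dose."""
        if not self.converged:
            raise ValidationError("fit", "cannot predict from a "
                                         "non-converged fit")
        doses = np.asarray(doses, dtype=float)
        return np.exp(doses * np.log1p(-self.theta_hat))

    def summary(self) -> str:
        lines = [
            f"Single-hit limiting dilution fit: group {self.group_id}",
            f"  frequency          : 1 in {self.frequency_denominator:.1f}",
            f"  95% CI             : 1 in {self.ci_lower_denominator:.1f}"
            f" to 1 in {self.ci_upper_denominator:.1f}",
            f"  theta_hat          : {self.theta_hat:.6g}",
            f"  log-likelihood     : {self.log_likelihood:.4f}",
            f"  converged          : {self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "theta_hat": self.theta_hat,
            "frequency_denominator": self.frequency_denominator,
            "ci_lower_denominator": self.ci_lower_denominator,
            "ci_upper_denominator": self.ci_upper_denominator,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
        }


class SingleHitModel:
    """Single-hit Poisson model for one limiting-dilution group."""

    def __init__(self, dose, n_tested, n_responding,
                 group_id: str = "group"):
        self.dose = np.asarray(dose, dtype=float)
        self.n_tested = np.asarray(n_tested, dtype=float)
        self.n_responding = np.asarray(n_responding, dtype=float)
        self.group_id = group_id
        if np.any(self.dose <= 0):
            raise ValidationError("dose", "doses must be positive")
        if np.any(self.n_responding > self.n_tested) or \
                np.any(self.n_responding < 0):
            raise ValidationError("n_responding",
                                  "must satisfy 0 <= r <= n")

    @classmethod
    def from_dataset(cls, data: LDADataset,
                     group_id: str) -> "SingleHitModel":
        sub = data.group(group_id)
        return cls(sub["dose"], sub["n_tested"], sub["n_responding"],
                   group_id=group_id)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       group_id: str | None = None) -> "SingleHitModel":
        data = LDADataset(df)
        if group_id is None:
            groups = data.groups
            if len(groups) != 1:
                raise ValidationError("group",
                                      "specify group_id when the table "
                                      "holds several groups")
            group_id = groups[0]
        return cls.from_dataset(data, group_id)

    def loglike(self, theta: float) -> float:
        return _log_likelihood(theta, self.dose, self.n_tested,
                               self.n_responding)

    def _check_boundary(self) -> None:
        if np.all(self.n_responding == self.n_tested):
            raise BoundaryEstimateError(
                "high", "all animals responded at every dose; frequency "
                        "unbounded high")
        if np.all(self.n_responding == 0):
            raise BoundaryEstimateError(
                "low", "no animal responded at any dose; frequency "
                       "unbounded low")

    def fit(self, ci_method: str = "wald") -> SingleHitResults:
        """Maximize the likelihood over theta and build the 95% CI.

        Optimization is a bounded scalar search on the log-odds of
        theta (deterministic bracket, no randomness).  ``ci_method`` is
        ``"wald"`` (Wald interval on the complementary log-log scale,
        the default) or ``"profile"`` (likelihood-ratio inversion).
        """
        self._check_boundary()
        res = optimize.minimize_scalar(
            lambda eta: -self.loglike(float(expit(eta))),
            bounds=(-30.0, 30.0), method="bounded",
            options={"xatol": 1e-12})
        theta = float(expit(res.x))
        ll = self.loglike(theta)
        converged = bool(res.success)

        phi_hat = np.log(-np.log1p(-theta))  # cloglog scale
        if ci_method == "wald":
            se = self._se_cloglog(phi_hat)
            lo_phi, hi_phi = phi_hat - _Z95 * se, phi_hat + _Z95 * se
            theta_lo = -np.expm1(-np.exp(lo_phi))
            theta_hi = -np.expm1(-np.exp(hi_phi))
        elif ci_method == "profile":
            se = self._se_cloglog(phi_hat)
            theta_lo, theta_hi = self._profile_ci(theta, ll)
        else:
            raise ValidationError("ci_method",
                                  f"unknown method {ci_method!r}")
        return SingleHitResults(
            group_id=self.group_id, theta_hat=theta,
            frequency_denominator=1.0 / theta,
            ci_lower_denominator=1.0 / theta_hi,
            ci_upper_denominator=1.0 / theta_lo,
            log_likelihood=ll, converged=converged,
            se_cloglog=float(se), model=self)

    def _se_cloglog(self, phi_hat: float) -> float:
        """SE of the cloglog parameter from the observed information."""
        h = 1e-5

        def nll(phi: float) -> float:
            theta = -np.expm1(-np.exp(phi))
            return -self.loglike(float(theta))

        info = (nll(phi_hat + h) - 2 * nll(phi_hat) + nll(phi_hat - h)) \
            / h ** 2
        if info <= 0:
            return float("inf")
        return float(1.0 / np.sqrt(info))

    def _profile_ci(self, theta_hat: float,
                    ll_hat: float) -> tuple[float, float]:
        """95% CI by inverting the likelihood-ratio statistic."""
        crit = sps.chi2.ppf(0.95, df=1) / 2.0

        def drop(theta: float) -> float:
            return ll_hat - self.loglike(theta) - crit

        eps = 1e-12
        lo = optimize.brentq(drop, eps, theta_hat) \
            if drop(eps) > 0 else eps
        hi = optimize.brentq(drop, theta_hat, 1 - eps) \
            if drop(1 - eps) > 0 else 1 - eps
        return float(lo), float(hi)


def fit_single_hit(data: LDADataset, group_id: str,
                   ci_method: str = "wald") -> SingleHitResults:
    """Fit the single-hit model to one group of an LDA dataset."""
    return SingleHitModel.from_dataset(data, group_id).fit(
        ci_method=ci_method)


def predict_nonresponse_curve(fit: SingleHitResults, doses) -> np.ndarray:
    """Non-response fraction exp(d * log(1 - theta_hat)) per dose."""
    return fit.predict_nonresponse(doses)


@dataclass
class LDAComparison:
    """Likelihood-ratio comparison of two groups' frequencies."""

    group_a: str
    group_b: str
    lr_statistic: float
    df: int
    p_value: float

    def summary(self) -> str:
        return (f"LDA comparison {self.group_a} vs {self.group_b}: "
                f"LR = {self.lr_statistic:.4f} (df={self.df}), "
                f"p = {self.p_value:.4g}")

    def to_dict(self) -> dict:
        return {"group_a": self.group_a, "group_b": self.group_b,
                "lr_statistic": self.lr_statistic, "df": self.df,
                "p_value": self.p_value}


def compare_groups(data: LDADataset, group_a: str,
                   group_b: str) -> LDAComparison:
    """Test equal frequency in two groups (chi-square, 1 df).

    LR = 2 * (l_a + l_b - l_pooled), where the pooled likelihood
    refits one common theta to the concatenated dose/response rows.
    Symmetric in argument order.
    """
    fit_a = fit_single_hit(data, group_a)
    fit_b = fit_single_hit(data, group_b)
    sub = pd.concat([data.group(group_a), data.group(group_b)])
    pooled = SingleHitModel(sub["dose"], sub["n_tested"],
                            sub["n_responding"], group_id="pooled").fit()
    lr = 2.0 * (fit_a.log_likelihood + fit_b.log_likelihood
                - pooled.log_likelihood)
    lr = max(lr, 0.0)  # clamp the 1e-8-scale numerical slack
    p = float(sps.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return LDAComparison(group_a=group_a, group_b=group_b,
                         lr_statistic=float(lr), df=1, p_value=p)
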