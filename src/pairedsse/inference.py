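"""Final-analysis Wald test and confidence interval for a rate ratio.

The statistic works on the log of the estimated ratio of sensitivities
(or specificities).  Writing g for the estimated ratio, r_B for the
estimated comparator rate and j for the estimated joint agreement rate
within the relevant stratum of size m, the variance of log g is estimated
by

    se^2 = ((g + 1) r_B - 2 j) / (m * g * r_B^2),

the same variance structure whose inversion for m gives the planning
formulas, so the power computed from this test at the planned size is the
nominal power by construction.  The two-sided (1 - alpha) interval for the
ratio is exp(log g -+ z_{1-alpha/2} se); the test rejects exactly when the
interval excludes 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import DegenerateDataError, InputError
from .study_model import PairedCounts

__all__ = ["RatioTestResult", "ratio_test"]


@dataclass(frozen=True)
class RatioTestResult:
    """Wald test of H0: ratio = 1 on one endpoint.

    ``degenerate`` marks tables where the statistic is inestimable (a zero
    marginal or zero standard error); a degenerate result never rejects.
    """

    endpoint: str
    gamma_hat: float
    log_se: float
    z_stat: float
    reject: bool
    ci_low: float
    ci_high: float
    alpha: float
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint, "gamma_hat": self.gamma_hat,
            "log_se": self.log_se, "z_stat": self.z_stat,
            "reject": self.reject, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "alpha": self.alpha,
            "degenerate": self.degenerate,
        }


def _degenerate(endpoint: str, gamma_hat: float, alpha: float) -> RatioTestResult:
    nan = float("nan")
    return RatioTestResult(endpoint=endpoint, gamma_hat=gamma_hat,
                           log_se=nan, z_stat=nan, reject=False,
                           ci_low=nan, ci_high=nan, alpha=alpha,
                           degenerate=True)


def ratio_test(counts: PairedCounts, endpoint: str = "sensitivity",
               alpha: float = 0.05) -> RatioTestResult:
    """Two-sided Wald test of equal sensitivities (or specificities).

    Parameters
    ----------
    counts : PairedCounts
        Pooled study data.
    endpoint : {"sensitivity", "specificity"}
        Which rate ratio to test; sensitivity uses the diseased stratum,
        specificity the non-diseased one.
    alpha : float
        Two-sided significance level.
    """
    if endpoint not in ("sensitivity", "specificity"):
        raise InputError("endpoint must be 'sensitivity' or 'specificity'")
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie strictly in (0, 1)")

    if endpoint == "sensitivity":
        m = counts.n_diseased
        if m == 0:
            raise DegenerateDataError("diseased stratum is empty")
        x1, x2, x3, _ = counts.diseased_cells
        rate_a = (x1 + x2) / m
        rate_b = (x1 + x3) / m
        joint = x1 / m
    else:
        m = counts.n_nondiseased
        if m == 0:
            raise DegenerateDataError("non-diseased stratum is empty")
        rate_a = (counts.n_g + counts.n_h) / m
        rate_b = (counts.n_f + counts.n_h) / m
        joint = counts.n_h / m

    if rate_b == 0.0 or rate_a == 0.0:
        return _degenerate(endpoint, math.inf if rate_b == 0.0 else 0.0, alpha)

    gamma_hat = rate_a / rate_b
    var = ((gamma_hat + 1.0) * rate_b - 2.0 * joint) / (m * gamma_hat * rate_b ** 2)
    if var <= 0.0:
        return _degenerate(endpoint, gamma_hat, alpha)

    log_se = math.sqrt(var)
    z = math.log(gamma_hat) / log_se
    zcrit = float(norm.ppf(1.0 - alpha / 2.0))
    half = zcrit * log_se
    return RatioTestResult(
        endpoint=endpoint, gamma_hat=gamma_hat, log_se=log_se, z_stat=z,
        reject=abs(z) > zcrit,
        ci_low=math.exp(math.log(gamma_hat) - half),
        ci_high=math.exp(math.log(gamma_hat) + half),
        alpha=alpha, degenerate=False,
    )
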