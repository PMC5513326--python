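"""Constrained multinomial MLE of the joint agreement probability.

At a planned interim the four cells of one gold-standard stratum follow a
multinomial law whose cell probabilities are pinned to the hypothesised
marginals (the design sensitivities or specificities of the two tests).
With p1 the both-agree probability, the stratum probability vector is

    p = (p1, mA - p1, mB - p1, 1 - mA - mB + p1),

so the likelihood is one-dimensional in p1 over the feasible interval
[max(0, mB - (1 - mA)), mB].  Maximising it yields an estimate of the
conditional dependence (TPPR for sensitivity, TNNR for specificity) that
respects the design hypotheses, unlike the naive plug-in of raw observed
proportions, which can even imply a negative sample size.  The MLE is then
fed back into the closed-form sample-size formulas to re-estimate the
study size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq, minimize_scalar

from .errors import DegenerateDataError, InfeasibleError, InputError, NoDataError
from .sample_size import (
    joint_prob_bounds,
    raw_sensitivity_sample_size,
    raw_specificity_sample_size,
    round_size,
)
from .study_model import DesignHypotheses, PairedCounts, observed_rates

__all__ = [
    "JointCellProbs",
    "ReEstimationResult",
    "NaiveReEstimate",
    "constrained_nll",
    "mle_joint_prob",
    "specificity_orientation",
    "prevalence_mle",
    "reestimate",
    "naive_reestimate",
]


@dataclass(frozen=True)
class JointCellProbs:
    """Probability vector of one stratum under fixed marginals.

    Order: (both agree-positive, A-only, B-only, both agree-negative) in the
    orientation of the endpoint under study.  ``covariance`` is the
    conditional covariance between the tests within the stratum
    (e_b for the diseased stratum, e_a for the non-diseased one).
    """

    p1: float
    p2: float
    p3: float
    p4: float
    marginal_a: float
    marginal_b: float

    def __post_init__(self) -> None:
        probs = (self.p1, self.p2, self.p3, self.p4)
        if any(p < -1e-12 for p in probs):
            raise InfeasibleError(f"negative cell probability in {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise InfeasibleError(f"cell probabilities {probs} do not sum to 1")
        if abs(self.p1 + self.p2 - self.marginal_a) > 1e-12:
            raise InfeasibleError("p1 + p2 must equal marginal_a")
        if abs(self.p1 + self.p3 - self.marginal_b) > 1e-12:
            raise InfeasibleError("p1 + p3 must equal marginal_b")

    @property
    def covariance(self) -> float:
        return self.p1 - self.marginal_a * self.marginal_b

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)


def constrained_nll(p1: float, x, marginal_a: float, marginal_b: float) -> float:
    """Negative log-likelihood of stratum counts ``x`` at candidate ``p1``.

    ``x`` is the ordered 4-tuple (both+, A-only, B-only, both-).  A factor
    with zero count contributes nothing regardless of its base (0*log 0 := 0),
    which makes boundary values of p1 legitimate when the corresponding cell
    was not observed.  If a positively-weighted factor is non-positive the
    likelihood is zero and ``inf`` is returned as a sentinel rather than an
    exception, so optimisers may probe the boundary freely.
    """
    x1, x2, x3, x4 = x
    out = 0.0
    for count, base in ((x1, p1), (x2, marginal_a - p1),
                        (x3, marginal_b - p1),
                        (x4, 1.0 - marginal_a - marginal_b + p1)):
        if count > 0:
            if base <= 0.0:
                return math.inf
            out -= count * math.log(base)
    return out


def _score(p1: float, x, marginal_a: float, marginal_b: float) -> float:
    """Derivative of the log-likelihood in p1 (zero at an interior MLE)."""
    x1, x2, x3, x4 = x
    out = 0.0
    if x1:
        out += x1 / p1
    if x2:
        out -= x2 / (marginal_a - p1)
    if x3:
        out -= x3 / (marginal_b - p1)
    if x4:
        out += x4 / (1.0 - marginal_a - marginal_b + p1)
    return out


def mle_joint_prob(x, marginal_a: float, marginal_b: float,
                   tol: float = 1e-10) -> tuple[float, bool]:
    """Maximum-likelihood p1 over its closed feasible interval.

    Returns ``(estimate, boundary_flag)``; the flag is set when the optimum
    sits at an interval endpoint.  Uses bounded scalar minimisation of
    :func:`constrained_nll` (golden-section/parabolic hybrid) to absolute
    tolerance ``tol``, then compares against the exact endpoints, which the
    bounded optimiser never evaluates.
    """
    x = tuple(int(v) for v in x)
    if any(v < 0 for v in x):
        raise InputError(f"counts must be non-negative, got {x}")
    if sum(x) == 0:
        raise NoDataError("all four stratum counts are zero; p1 is inestimable")
    bounds = joint_prob_bounds(marginal_a, marginal_b)
    lo, hi = bounds.lower, bounds.upper
    if hi - lo <= tol:
        return lo, True

    res = minimize_scalar(constrained_nll, bounds=(lo, hi),
                          args=(x, marginal_a, marginal_b),
                          method="bounded", options={"xatol": tol})
    best_p, best_f = float(res.x), float(res.fun)
    # polish strictly interior optima on the score equation: the bounded
    # minimiser controls the position, not the gradient
    h = max(100.0 * tol, 1e-7 * (hi - lo))
    a, b = max(lo + 1e-13, best_p - h), min(hi - 1e-13, best_p + h)
    if a < b:
        sa = _score(a, x, marginal_a, marginal_b)
        sb = _score(b, x, marginal_a, marginal_b)
        if sa * sb < 0.0:
            root = brentq(_score, a, b, args=(x, marginal_a, marginal_b),
                          xtol=1e-15)
            f_root = constrained_nll(root, x, marginal_a, marginal_b)
            # the root of the score is the exact interior optimum; accept it
            # even when round-off puts its NLL a hair above the probe value
            if f_root <= best_f + 1e-9 * max(1.0, abs(best_f)):
                best_p, best_f = float(root), min(float(f_root), best_f)
    boundary = False
    for endpoint in (lo, hi):
        f_end = constrained_nll(endpoint, x, marginal_a, marginal_b)
        if f_end <= best_f:
            best_p, best_f, boundary = endpoint, f_end, True
    if not boundary and min(best_p - lo, hi - best_p) <= 10.0 * tol:
        boundary = True
    return best_p, boundary


def specificity_orientation(counts: PairedCounts) -> tuple[int, int, int, int]:
    """Non-diseased cells reordered for the specificity endpoint.

    Position 1 is both-negative (pairs with TNNR), position 2 is A-/B+
    (completes the TNR_A marginal), position 3 is A+/B- (completes TNR_B),
    position 4 both-positive.
    """
    return (counts.n_h, counts.n_g, counts.n_f, counts.n_e)


def prevalence_mle(counts: PairedCounts) -> float:
    """Observed prevalence n_diseased / n_total (the binomial MLE)."""
    if counts.n_total == 0:
        raise NoDataError("empty table; prevalence is inestimable")
    return counts.n_diseased / counts.n_total


@dataclass(frozen=True)
class ReEstimationResult:
    """Interim sample-size re-estimate based on the constrained MLEs."""

    tppr_mle: float
    tnnr_mle: float
    prevalence_hat: float
    prevalence_source: str
    n_sensitivity: int
    n_specificity: int
    n_overall: int
    interim_n: int
    rounding: str
    tppr_at_boundary: bool
    tnnr_at_boundary: bool
    already_sufficient: bool

    def to_dict(self) -> dict:
        return {
            "tppr_mle": self.tppr_mle, "tnnr_mle": self.tnnr_mle,
            "prevalence_hat": self.prevalence_hat,
            "prevalence_source": self.prevalence_source,
            "n_sensitivity": self.n_sensitivity,
            "n_specificity": self.n_specificity,
            "n_overall": self.n_overall, "interim_n": self.interim_n,
            "rounding": self.rounding,
            "tppr_at_boundary": self.tppr_at_boundary,
            "tnnr_at_boundary": self.tnnr_at_boundary,
            "already_sufficient": self.already_sufficient,
        }


def reestimate(counts: PairedCounts, h: DesignHypotheses,
               prevalence_source: str = "interim",
               rounding: str = "nearest") -> ReEstimationResult:
    """Re-estimate both endpoint sizes from interim data.

    TPPR and TNNR come from the constrained multinomial MLE under the
    hypothesised marginals; prevalence either from the interim data
    (default, its binomial MLE) or retained from the design.  MLEs are
    carried at full precision into the sample-size formulas; the overall
    size is the larger endpoint size, floored at the interim sample already
    observed (recruiting fewer subjects than seen is meaningless), with a
    flag when the interim sample alone already suffices.
    """
    if prevalence_source not in ("interim", "design"):
        raise InputError("prevalence_source must be 'interim' or 'design'")
    if counts.n_diseased == 0:
        raise DegenerateDataError("diseased stratum is empty; TPPR inestimable")
    if counts.n_nondiseased == 0:
        raise DegenerateDataError("non-diseased stratum is empty; TNNR inestimable")

    tppr_mle, tppr_bd = mle_joint_prob(counts.diseased_cells, h.tpr_a, h.tpr_b)
    tnnr_mle, tnnr_bd = mle_joint_prob(specificity_orientation(counts),
                                       h.tnr_a, h.tnr_b)
    if prevalence_source == "interim":
        pi_hat = prevalence_mle(counts)
    else:
        pi_hat = h.prevalence
    h_used = DesignHypotheses(alpha=h.alpha, beta=h.beta,
                              tpr_a=h.tpr_a, tpr_b=h.tpr_b,
                              tnr_a=h.tnr_a, tnr_b=h.tnr_b,
                              prevalence=pi_hat)
    n_sens = round_size(raw_sensitivity_sample_size(h_used, tppr_mle), rounding)
    n_spec = round_size(raw_specificity_sample_size(h_used, tnnr_mle), rounding)
    interim_n = counts.n_total
    n_required = max(n_sens, n_spec)
    return ReEstimationResult(
        tppr_mle=tppr_mle, tnnr_mle=tnnr_mle,
        prevalence_hat=pi_hat, prevalence_source=prevalence_source,
        n_sensitivity=n_sens, n_specificity=n_spec,
        n_overall=max(n_required, interim_n), interim_n=interim_n,
        rounding=rounding,
        tppr_at_boundary=tppr_bd, tnnr_at_boundary=tnnr_bd,
        already_sufficient=interim_n >= n_required,
    )


@dataclass(frozen=True)
class NaiveReEstimate:
    """Plug-in re-estimate from raw observed rates (for comparison only)."""

    n_sensitivity: int
    n_specificity: int
    sensitivity_feasible: bool
    specificity_feasible: bool
    tppr_hat: float
    tnnr_hat: float
    prevalence_hat: float

    def to_dict(self) -> dict:
        return {
            "n_sensitivity": self.n_sensitivity,
            "n_specificity": self.n_specificity,
            "sensitivity_feasible": self.sensitivity_feasible,
            "specificity_feasible": self.specificity_feasible,
            "tppr_hat": self.tppr_hat, "tnnr_hat": self.tnnr_hat,
            "prevalence_hat": self.prevalence_hat,
        }


def naive_reestimate(counts: PairedCounts, h: DesignHypotheses,
                     rounding: str = "nearest",
                     rate_precision: int | None = None) -> NaiveReEstimate:
    """Plug observed TPPR/TNNR and prevalence straight into the formulas.

    The hypothesised marginals are retained; only the joint probabilities
    and prevalence are replaced by their raw interim estimates.  Because an
    observed joint rate can fall outside the interval feasible under the
    hypothesised marginals, the formula is evaluated permissively and a
    negative or out-of-bounds result is returned flagged infeasible rather
    than suppressed.  ``rate_precision`` optionally rounds the observed
    rates to that many decimals before plug-in (as one would when reading
    them off a report); default is full precision.
    """
    rates = observed_rates(counts)
    tppr, tnnr, pi = rates.tppr_hat, rates.tnnr_hat, rates.prevalence_hat
    if rate_precision is not None:
        tppr = round(tppr, rate_precision)
        tnnr = round(tnnr, rate_precision)
        pi = round(pi, rate_precision)
    h_used = DesignHypotheses(alpha=h.alpha, beta=h.beta,
                              tpr_a=h.tpr_a, tpr_b=h.tpr_b,
                              tnr_a=h.tnr_a, tnr_b=h.tnr_b,
                              prevalence=pi)
    raw_sens = raw_sensitivity_sample_size(h_used, tppr, mode="permissive")
    raw_spec = raw_specificity_sample_size(h_used, tnnr, mode="permissive")
    sens_ok = joint_prob_bounds(h.tpr_a, h.tpr_b).contains(tppr)
    spec_ok = joint_prob_bounds(h.tnr_a, h.tnr_b).contains(tnnr)
    return NaiveReEstimate(
        n_sensitivity=round_size(raw_sens, rounding),
        n_specificity=round_size(raw_spec, rounding),
        sensitivity_feasible=sens_ok, specificity_feasible=spec_ok,
        tppr_hat=tppr, tnnr_hat=tnnr, prevalence_hat=pi,
    )
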