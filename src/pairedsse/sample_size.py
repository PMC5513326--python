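"""Closed-form sample sizes for paired superiority comparisons.

The study tests H0: gamma = 1 against a two-sided alternative for the ratio
of sensitivities (gamma1 = TPR_A / TPR_B) and, separately, of specificities
(gamma2 = TNR_A / TNR_B).  The per-endpoint size for the sensitivity
comparison is

    n = ((z_{1-beta} + z_{1-alpha/2}) / log gamma1)^2
        * ((gamma1 + 1) TPR_B - 2 TPPR) / (gamma1 TPR_B^2)  / pi

where TPPR is the probability a diseased subject is positive on both
tests.  The specificity formula is identical with TNR/TNNR and 1 - pi.
TPPR encodes the conditional dependence between the tests within the
diseased stratum (covariance e_b = TPPR - TPR_A * TPR_B): the weaker the
dependence, the larger the study, so the feasible interval of TPPR maps to
a best-case / worst-case sample-size range.  The overall study size is the
larger of the two endpoint sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import InfeasibleError, InputError, OrientationError, UndefinedEffectError
from .study_model import DesignHypotheses

__all__ = [
    "DependenceBounds",
    "SampleSizePlan",
    "joint_prob_bounds",
    "round_size",
    "raw_sensitivity_sample_size",
    "raw_specificity_sample_size",
    "sensitivity_sample_size",
    "specificity_sample_size",
    "plan_study",
]

_ROUNDINGS = ("nearest", "up", "down")


def round_size(raw: float, rounding: str = "nearest") -> int:
    """Apply a rounding convention to a raw (real-valued) sample size.

    ``nearest`` rounds halves upward (598.5 -> 599),
    ``up`` is the ceiling, ``down`` the floor.  Negative raw values (from
    permissive plug-in estimates) round the same way on the real line.
    """
    if rounding not in _ROUNDINGS:
        raise InputError(f"rounding must be one of {_ROUNDINGS}, got {rounding!r}")
    if rounding == "nearest":
        return math.floor(raw + 0.5)
    if rounding == "up":
        return math.ceil(raw)
    return math.floor(raw)


@dataclass(frozen=True)
class DependenceBounds:
    """Feasible range of a joint probability given the two marginals.

    ``lower`` corresponds to maximal negative conditional dependence,
    ``upper`` (= the smaller marginal) to maximal positive dependence.
    ``cov_min``/``cov_max`` are the matching conditional covariances
    (joint minus product of marginals).
    """

    lower: float
    upper: float
    cov_min: float
    cov_max: float

    def contains(self, joint: float, tol: float = 1e-12) -> bool:
        return self.lower - tol <= joint <= self.upper + tol


def joint_prob_bounds(marginal_a: float, marginal_b: float) -> DependenceBounds:
    """Feasible interval for the both-positive (or both-negative) probability.

    For marginals with ``marginal_a + marginal_b > 1`` the lower endpoint is
    ``marginal_b - (1 - marginal_a)``; otherwise it is clamped at 0 (a joint
    probability cannot be negative).  The upper endpoint is ``marginal_b``,
    the smaller marginal.  Test A must be the better test
    (``marginal_a >= marginal_b``).
    """
    if not (0.0 < marginal_a <= 1.0) or not (0.0 < marginal_b <= 1.0):
        raise InputError("marginals must lie in (0, 1]")
    if marginal_a < marginal_b:
        raise OrientationError(
            "marginal_a < marginal_b: label the hypothesised-better test as A "
            "(the feasibility algebra assumes marginal_a >= marginal_b)"
        )
    lower = max(0.0, marginal_b - (1.0 - marginal_a))
    upper = marginal_b
    prod = marginal_a * marginal_b
    return DependenceBounds(lower=lower, upper=upper,
                            cov_min=lower - prod, cov_max=upper - prod)


def _quantile_sum(alpha: float, beta: float) -> float:
    # full double-precision normal quantiles; no two-decimal truncation
    return float(norm.ppf(1.0 - beta) + norm.ppf(1.0 - alpha / 2.0))


def _raw_size(alpha: float, beta: float, marginal_a: float, marginal_b: float,
              joint: float, stratum_fraction: float, mode: str) -> float:
    if not 0.0 < stratum_fraction < 1.0:
        raise InputError("prevalence must lie strictly in (0, 1)")
    if marginal_a == marginal_b:
        raise UndefinedEffectError(
            "hypothesised rates are equal (gamma = 1): log gamma = 0 and the "
            "sample-size formula is undefined"
        )
    bounds = joint_prob_bounds(marginal_a, marginal_b)
    if mode == "strict" and not bounds.contains(joint):
        raise InfeasibleError(
            f"joint probability {joint} outside the feasible interval "
            f"[{bounds.lower}, {bounds.upper}] implied by marginals "
            f"({marginal_a}, {marginal_b})"
        )
    gamma = marginal_a / marginal_b
    z = _quantile_sum(alpha, beta)
    factor = ((gamma + 1.0) * marginal_b - 2.0 * joint) / (gamma * marginal_b ** 2)
    return (z / math.log(gamma)) ** 2 * factor / stratum_fraction


def raw_sensitivity_sample_size(h: DesignHypotheses, tppr: float,
                                mode: str = "strict") -> float:
    """Unrounded diseased-endpoint size; ``mode='permissive'`` skips the
    TPPR feasibility check (used by the naive plug-in re-estimator, where
    the result may legitimately be negative)."""
    if mode not in ("strict", "permissive"):
        raise InputError(f"mode must be 'strict' or 'permissive', got {mode!r}")
    return _raw_size(h.alpha, h.beta, h.tpr_a, h.tpr_b, tppr, h.prevalence, mode)


def raw_specificity_sample_size(h: DesignHypotheses, tnnr: float,
                                mode: str = "strict") -> float:
    if mode not in ("strict", "permissive"):
        raise InputError(f"mode must be 'strict' or 'permissive', got {mode!r}")
    return _raw_size(h.alpha, h.beta, h.tnr_a, h.tnr_b, tnnr,
                     1.0 - h.prevalence, mode)


def sensitivity_sample_size(h: DesignHypotheses, tppr: float,
                            rounding: str = "nearest",
                            mode: str = "strict") -> int:
    """Participants needed to power the sensitivity comparison at the
    hypothesised TPPR (joint both-positive probability among diseased)."""
    return round_size(raw_sensitivity_sample_size(h, tppr, mode), rounding)


def specificity_sample_size(h: DesignHypotheses, tnnr: float,
                            rounding: str = "nearest",
                            mode: str = "strict") -> int:
    """Participants needed to power the specificity comparison at the
    hypothesised TNNR (joint both-negative probability among non-diseased)."""
    return round_size(raw_specificity_sample_size(h, tnnr, mode), rounding)


@dataclass(frozen=True)
class SampleSizePlan:
    """Planned study size: both endpoint sizes and their maximum."""

    n_sensitivity: int
    n_specificity: int
    n_overall: int
    rounding: str
    raw_sensitivity: float
    raw_specificity: float
    tppr: float
    tnnr: float
    dependence: str  # "worst-case" | "best-case" | "supplied"

    def to_dict(self) -> dict:
        return {
            "n_sensitivity": self.n_sensitivity,
            "n_specificity": self.n_specificity,
            "n_overall": self.n_overall,
            "rounding": self.rounding,
            "raw_sensitivity": self.raw_sensitivity,
            "raw_specificity": self.raw_specificity,
            "tppr": self.tppr,
            "tnnr": self.tnnr,
            "dependence": self.dependence,
        }


def plan_study(h: DesignHypotheses, tppr: float | None = None,
               tnnr: float | None = None, assume: str | None = None,
               rounding: str = "nearest") -> SampleSizePlan:
    """Size the whole study: the larger of the two endpoint sizes.

    Either supply both joint probabilities explicitly, or set
    ``assume='worst'`` (maximal negative dependence, largest study) or
    ``assume='best'`` (maximal positive dependence, smallest study).
    """
    if assume is not None:
        if tppr is not None or tnnr is not None:
            raise InputError("pass either assume= or explicit tppr/tnnr, not both")
        if assume not in ("worst", "best"):
            raise InputError(f"assume must be 'worst' or 'best', got {assume!r}")
        sens_b = joint_prob_bounds(h.tpr_a, h.tpr_b)
        spec_b = joint_prob_bounds(h.tnr_a, h.tnr_b)
        if assume == "worst":
            tppr, tnnr = sens_b.lower, spec_b.lower
            dependence = "worst-case"
        else:
            tppr, tnnr = sens_b.upper, spec_b.upper
            dependence = "best-case"
    else:
        if tppr is None or tnnr is None:
            raise InputError("supply both tppr and tnnr, or assume='worst'|'best'")
        dependence = "supplied"

    raw_sens = raw_sensitivity_sample_size(h, tppr)
    raw_spec = raw_specificity_sample_size(h, tnnr)
    n_sens = round_size(raw_sens, rounding)
    n_spec = round_size(raw_spec, rounding)
    return SampleSizePlan(
        n_sensitivity=n_sens, n_specificity=n_spec,
        n_overall=max(n_sens, n_spec), rounding=rounding,
        raw_sensitivity=raw_sens, raw_specificity=raw_spec,
        tppr=tppr, tnnr=tnnr, dependence=dependence,
    )
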