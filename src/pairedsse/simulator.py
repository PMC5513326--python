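"""Monte-Carlo engine for the adaptive paired-accuracy design.

Each replicate runs the full adaptive pipeline: draw an interim cohort
from the true (generating) multinomial law, re-estimate the sample size
from the constrained MLE of the joint agreement probability under the
*design* hypotheses, recruit the shortfall from the same law, pool, and
test the rate ratio at the design's alpha.  Aggregating replicates yields
the operating characteristics of the procedure: type-I error or power,
the distribution of the final sample size, bias of the ratio estimate,
confidence-interval coverage, and the RMSE of the re-estimated size
against the closed-form size at the true dependence.

The generating law is specified separately from the design hypotheses:
under the null the two tests share a common true rate, while the study is
still planned and re-estimated under its (false) alternative hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .inference import ratio_test
from .interim_mle import JointCellProbs, mle_joint_prob, specificity_orientation
from .sample_size import (
    joint_prob_bounds,
    raw_sensitivity_sample_size,
    raw_specificity_sample_size,
    round_size,
)
from .study_model import DesignHypotheses, PairedCounts

__all__ = [
    "Scenario",
    "TrialRecord",
    "SimulationSummary",
    "stratum_cell_probs",
    "draw_counts",
    "run_trial",
    "run_experiment",
    "fixed_n_power",
]


def stratum_cell_probs(marginal_a: float, marginal_b: float,
                       joint: float) -> JointCellProbs:
    """Stratum probability vector implied by the marginals and p1.

    p = (p1, mA - p1, mB - p1, 1 - mA - mB + p1); the one free parameter p1
    must lie in its feasible interval.  Tiny negative round-off in the
    derived cells is clipped to zero.
    """
    bounds = joint_prob_bounds(marginal_a, marginal_b)
    if not bounds.contains(joint):
        raise InputError(
            f"joint probability {joint} outside feasible interval "
            f"[{bounds.lower}, {bounds.upper}]"
        )
    p2 = marginal_a - joint
    p3 = marginal_b - joint
    p4 = 1.0 - marginal_a - marginal_b + joint
    p1, p2, p3, p4 = (max(0.0, v) for v in (joint, p2, p3, p4))
    s = p1 + p2 + p3 + p4
    return JointCellProbs(p1=p1 / s, p2=p2 / s, p3=p3 / s, p4=p4 / s,
                          marginal_a=marginal_a, marginal_b=marginal_b)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_counts(diseased_probs: JointCellProbs,
                nondiseased_probs: JointCellProbs,
                prevalence: float, n: int, seed) -> PairedCounts:
    """One cohort of ``n`` subjects from the 8-category multinomial.

    ``diseased_probs`` is in sensitivity orientation (cells A, B, C, D);
    ``nondiseased_probs`` in specificity orientation (both-negative first),
    i.e. its vector maps to cells (H, G, F, E).  A single multinomial draw
    over all eight categories (probabilities pi * p_d and (1 - pi) * p_nd)
    is distributionally identical to disease status first, stratum second.
    """
    if n < 0:
        raise InputError("cohort size must be non-negative")
    if not 0.0 <= prevalence <= 1.0:
        raise InputError("prevalence must lie in [0, 1]")
    rng = _as_rng(seed)
    q = nondiseased_probs.as_tuple()
    pvals = np.array([
        prevalence * p for p in diseased_probs.as_tuple()
    ] + [
        (1.0 - prevalence) * p for p in (q[3], q[2], q[1], q[0])  # E,F,G,H
    ])
    cells = rng.multinomial(n, pvals / pvals.sum())
    return PairedCounts(*(int(c) for c in cells))


@dataclass(frozen=True)
class Scenario:
    """One simulation cell: a generating law plus the design under test.

    ``design`` drives planning, re-estimation and testing; the ``true_*``
    fields drive data generation and default to the design's values, so an
    alternative-hypothesis scenario only needs ``true_tppr``.  A null
    scenario sets equal true marginals while the design keeps its
    (now false) alternative hypotheses.  ``true_tnnr`` defaults to
    conditional independence in the non-diseased stratum.
    """

    design: DesignHypotheses
    true_tppr: float
    interim_n: int
    reps: int
    seed: int
    endpoint: str = "sensitivity"
    true_tpr_a: float | None = None
    true_tpr_b: float | None = None
    true_tnr_a: float | None = None
    true_tnr_b: float | None = None
    true_tnnr: float | None = None
    true_prevalence: float | None = None
    prevalence_source: str = "interim"
    rounding: str = "nearest"

    def __post_init__(self) -> None:
        if self.endpoint not in ("sensitivity", "specificity"):
            raise InputError("endpoint must be 'sensitivity' or 'specificity'")
        if self.interim_n < 1:
            raise InputError("interim_n must be >= 1")
        if self.reps < 1:
            raise InputError("reps must be >= 1")
        # materialise generating defaults and validate feasibility eagerly
        object.__setattr__(self, "true_tpr_a",
                           self.design.tpr_a if self.true_tpr_a is None else self.true_tpr_a)
        object.__setattr__(self, "true_tpr_b",
                           self.design.tpr_b if self.true_tpr_b is None else self.true_tpr_b)
        object.__setattr__(self, "true_tnr_a",
                           self.design.tnr_a if self.true_tnr_a is None else self.true_tnr_a)
        object.__setattr__(self, "true_tnr_b",
                           self.design.tnr_b if self.true_tnr_b is None else self.true_tnr_b)
        object.__setattr__(self, "true_tnnr",
                           self.true_tnr_a * self.true_tnr_b
                           if self.true_tnnr is None else self.true_tnnr)
        object.__setattr__(self, "true_prevalence",
                           self.design.prevalence
                           if self.true_prevalence is None else self.true_prevalence)
        self.diseased_probs()
        self.nondiseased_probs()

    def diseased_probs(self) -> JointCellProbs:
        return stratum_cell_probs(self.true_tpr_a, self.true_tpr_b, self.true_tppr)

    def nondiseased_probs(self) -> JointCellProbs:
        """Specificity-orientation probabilities of the non-diseased stratum."""
        return stratum_cell_probs(self.true_tnr_a, self.true_tnr_b, self.true_tnnr)

    @property
    def true_gamma(self) -> float:
        """Generating ratio for the endpoint under study."""
        if self.endpoint == "sensitivity":
            return self.true_tpr_a / self.true_tpr_b
        return self.true_tnr_a / self.true_tnr_b

    @property
    def true_joint(self) -> float:
        return self.true_tppr if self.endpoint == "sensitivity" else self.true_tnnr

    def reference_n(self) -> float:
        """Closed-form endpoint size at the true dependence (RMSE reference).

        Evaluated with the *design* marginals — the quantity the adaptive
        procedure is trying to recover — at the true joint probability and
        true prevalence.
        """
        h = replace(self.design, prevalence=self.true_prevalence)
        if self.endpoint == "sensitivity":
            return raw_sensitivity_sample_size(h, self.true_joint)
        return raw_specificity_sample_size(h, self.true_joint)


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one simulated adaptive trial."""

    final_n: int
    reestimated_n: int
    joint_mle: float
    prevalence_used: float
    reject: bool
    gamma_hat: float
    ci_low: float
    ci_high: float
    degenerate: bool
    fallback: bool


def _reestimate_endpoint(sc: Scenario, interim: PairedCounts) -> tuple[int, float, float, bool]:
    """(re-estimated endpoint n, joint MLE, prevalence used, fallback flag)."""
    d = sc.design
    fallback = False
    if sc.endpoint == "sensitivity":
        stratum, ma, mb = interim.diseased_cells, d.tpr_a, d.tpr_b
        stratum_n = interim.n_diseased
        raw_fn = raw_sensitivity_sample_size
    else:
        stratum, ma, mb = specificity_orientation(interim), d.tnr_a, d.tnr_b
        stratum_n = interim.n_nondiseased
        raw_fn = raw_specificity_sample_size

    if stratum_n == 0:
        # no information on the endpoint: fall back to the worst-case plan
        joint = joint_prob_bounds(ma, mb).lower
        mle = math.nan
        fallback = True
    else:
        mle, _ = mle_joint_prob(stratum, ma, mb)
        joint = mle

    if sc.prevalence_source == "interim":
        pi_hat = interim.n_diseased / interim.n_total
        if not 0.0 < pi_hat < 1.0:
            pi_hat = d.prevalence
            fallback = True
    else:
        pi_hat = d.prevalence

    h_used = replace(d, prevalence=pi_hat)
    n_new = round_size(raw_fn(h_used, joint), sc.rounding)
    return n_new, mle, pi_hat, fallback


def run_trial(sc: Scenario, rng) -> TrialRecord:
    """One adaptive trial: interim draw, re-estimate, complete, pool, test."""
    rng = _as_rng(rng)
    dp, np_ = sc.diseased_probs(), sc.nondiseased_probs()
    interim = draw_counts(dp, np_, sc.true_prevalence, sc.interim_n, rng)

    n_new, mle, pi_hat, fallback = _reestimate_endpoint(sc, interim)
    final_n = max(n_new, sc.interim_n)
    extra = draw_counts(dp, np_, sc.true_prevalence, final_n - sc.interim_n, rng)
    pooled = PairedCounts(*(a + b for a, b in
                            zip(interim.as_tuple(), extra.as_tuple())))

    try:
        res = ratio_test(pooled, sc.endpoint, sc.design.alpha)
        return TrialRecord(
            final_n=final_n, reestimated_n=n_new, joint_mle=mle,
            prevalence_used=pi_hat, reject=res.reject,
            gamma_hat=res.gamma_hat, ci_low=res.ci_low, ci_high=res.ci_high,
            degenerate=res.degenerate, fallback=fallback,
        )
    except Exception:
        # empty endpoint stratum even after completion: inestimable
        nan = math.nan
        return TrialRecord(final_n=final_n, reestimated_n=n_new, joint_mle=mle,
                           prevalence_used=pi_hat, reject=False,
                           gamma_hat=nan, ci_low=nan, ci_high=nan,
                           degenerate=True, fallback=fallback)


@dataclass(frozen=True)
class SimulationSummary:
    """Operating characteristics aggregated over replicates.

    ``rejection_rate`` is the power under an alternative scenario and the
    type-I error under a null one; degenerate replicates count as
    non-rejections and are tallied in ``degenerate_count``.  ``bias_gamma``
    and ``coverage`` refer to the ratio estimate and its CI over the
    non-degenerate replicates.  ``rmse_n`` is measured against the
    closed-form endpoint size at the true joint probability.
    """

    rejection_rate: float
    mean_final_n: float
    sd_final_n: float
    bias_gamma: float
    coverage: float
    rmse_n: float
    degenerate_count: int
    mc_se_rejection: float
    reps: int
    reference_n: float
    scenario: Scenario = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "rejection_rate": self.rejection_rate,
            "mean_final_n": self.mean_final_n, "sd_final_n": self.sd_final_n,
            "bias_gamma": self.bias_gamma, "coverage": self.coverage,
            "rmse_n": self.rmse_n, "degenerate_count": self.degenerate_count,
            "mc_se_rejection": self.mc_se_rejection, "reps": self.reps,
            "reference_n": self.reference_n,
        }


def run_experiment(sc: Scenario) -> SimulationSummary:
    """Aggregate :func:`run_trial` over independent seeded substreams.

    Replicates use seed-sequence spawns, so results are independent of
    execution order and bit-identical across runs with the same scenario.
    """
    if sc.reps < 2:
        raise InputError("reps must be >= 2 to summarise")
    children = np.random.SeedSequence(sc.seed).spawn(sc.reps)
    records = [run_trial(sc, np.random.default_rng(c)) for c in children]

    rejections = np.array([r.reject for r in records], dtype=float)
    final_n = np.array([r.final_n for r in records], dtype=float)
    ok = np.array([not r.degenerate for r in records], dtype=bool)
    gamma = np.array([r.gamma_hat for r in records], dtype=float)
    lo = np.array([r.ci_low for r in records], dtype=float)
    hi = np.array([r.ci_high for r in records], dtype=float)

    rate = float(rejections.mean())
    g_true = sc.true_gamma
    ref = sc.reference_n()
    if ok.any():
        bias = float(gamma[ok].mean() - g_true)
        coverage = float(((lo[ok] <= g_true) & (g_true <= hi[ok])).mean())
    else:
        bias = math.nan
        coverage = math.nan
    return SimulationSummary(
        rejection_rate=rate,
        mean_final_n=float(final_n.mean()),
        sd_final_n=float(final_n.std(ddof=1)),
        bias_gamma=bias, coverage=coverage,
        rmse_n=float(np.sqrt(((final_n - ref) ** 2).mean())),
        degenerate_count=int((~ok).sum()),
        mc_se_rejection=math.sqrt(rate * (1.0 - rate) / sc.reps),
        reps=sc.reps, reference_n=ref, scenario=sc,
    )


def fixed_n_power(h: DesignHypotheses, true_tppr: float, n: int,
                  reps: int, seed: int,
                  true_tpr_a: float | None = None,
                  true_tpr_b: float | None = None) -> float:
    """Rejection rate of the sensitivity test at a fixed size (no interim).

    Generates cohorts of ``n`` at the true marginals (default: the design's)
    and dependence ``true_tppr``, with an independent non-diseased stratum,
    and tests at ``h.alpha``.  Degenerate tables count as non-rejections.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    ta = h.tpr_a if true_tpr_a is None else true_tpr_a
    tb = h.tpr_b if true_tpr_b is None else true_tpr_b
    dp = stratum_cell_probs(ta, tb, true_tppr)
    np_ = stratum_cell_probs(h.tnr_a, h.tnr_b, h.tnr_a * h.tnr_b)
    hits = 0
    for child in np.random.SeedSequence(seed).spawn(reps):
        counts = draw_counts(dp, np_, h.prevalence, n, np.random.default_rng(child))
        if counts.n_diseased == 0:
            continue
        if ratio_test(counts, "sensitivity", h.alpha).reject:
            hits += 1
    return hits / reps
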