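"""Prevalence estimation for direct and (extended) crosswise questioning.

Model
-----
Each group is a binomial experiment.  Under direct questioning the
probability of an affirmative answer is the prevalence ``pi`` itself.
Under the crosswise design, a respondent reports "I agree with exactly one
of the two statements"; a carrier of the sensitive attribute does so iff
the non-sensitive statement (prevalence ``p``) is false, a non-carrier iff
it is true, giving the option-A probability

    lambda(pi) = pi * (1 - p) + (1 - pi) * p = p + pi * (1 - 2p).

The extended crosswise model (ECWM) runs two crosswise groups with
complementary randomization probabilities ``p`` and ``1 - p`` under a
common ``pi``; the shared parameter is estimated by expectation
maximization over the joint product-binomial likelihood, with standard
errors from the inverse observed Fisher information

    I(pi) = sum_g  n_g * (1 - 2 p_g)^2 / (lambda_g (1 - lambda_g)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
from scipy.stats import norm

from .designs import GroupObservation, QuestionDesign, StudyDataset, ValidationError

__all__ = [
    "ModelPrediction",
    "PrevalenceEstimate",
    "EMSettings",
    "ConvergenceError",
    "response_prob",
    "estimate_group",
    "estimate_pooled",
    "log_likelihood",
    "group_information",
]

logger = logging.getLogger(__name__)

Z_95 = norm.ppf(0.975)


@dataclass(frozen=True)
class ModelPrediction:
    """Predicted option-A probability for one group at a given prevalence."""

    lam: float

    def __float__(self) -> float:
        return self.lam


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence estimate with its Wald standard error and 95% CI.

    ``pi_hat`` is the raw estimate and may fall outside [0, 1] for
    crosswise data (sampling noise can push ``lambda_hat`` past the design
    bounds); ``pi_hat_clipped`` is the truncated companion and ``truncated``
    records whether clipping occurred.  Raw values are never silently
    discarded — out-of-range estimates are diagnostic, not noise.
    """

    pi_hat: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # "closed_form" | "maximum_likelihood"
    label: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("standard error must be non-negative")

    @property
    def pi_hat_clipped(self) -> float:
        return min(1.0, max(0.0, self.pi_hat))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "pi_hat": self.pi_hat,
            "pi_hat_clipped": self.pi_hat_clipped,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "truncated": self.truncated,
        }


@dataclass(frozen=True)
class EMSettings:
    """EM controls: absolute tolerance on successive pi, iteration cap, start."""

    tol: float = 1e-10
    max_iter: int = 10_000
    pi_init: float = 0.5

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")
        if not (0.0 < self.pi_init < 1.0):
            raise ValidationError("pi_init must lie strictly in (0, 1)")


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the iteration trace of pi values."""

    def __init__(self, message: str, trace: Sequence[float]):
        super().__init__(message)
        self.trace = list(trace)


def response_prob(pi: float, design: QuestionDesign) -> ModelPrediction:
    """Option-A probability under the processing tree of the given design."""
    if not (0.0 <= pi <= 1.0):
        raise ValidationError(f"pi must lie in [0, 1], got {pi}")
    if design.is_crosswise:
        return ModelPrediction(design.p + pi * (1.0 - 2.0 * design.p))
    return ModelPrediction(pi)


def _wald_ci(pi_hat: float, se: float) -> tuple[float, float]:
    lo, hi = pi_hat - Z_95 * se, pi_hat + Z_95 * se
    return max(0.0, lo), min(1.0, hi)


def estimate_group(obs: GroupObservation) -> PrevalenceEstimate:
    """Closed-form per-group estimator with delta-method standard error.

    Direct:    pi_hat = count_a / n,            SE = sqrt(pi(1-pi)/n).
    Crosswise: pi_hat = (lambda_hat - p)/(1-2p), SE = sqrt(lambda(1-lambda)/(n (1-2p)^2)).
    """
    lam_hat = obs.prop_a
    if obs.design.is_crosswise:
        p = obs.design.p
        pi_hat = (lam_hat - p) / (1.0 - 2.0 * p)
        se = math.sqrt(lam_hat * (1.0 - lam_hat) / (obs.n * (1.0 - 2.0 * p) ** 2))
    else:
        pi_hat = lam_hat
        se = math.sqrt(lam_hat * (1.0 - lam_hat) / obs.n)
    lo, hi = _wald_ci(pi_hat, se)
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        ci_low=lo,
        ci_high=hi,
        method="closed_form",
        label=obs.label,
        truncated=not (0.0 <= pi_hat <= 1.0),
    )


def group_information(pi: float, design: QuestionDesign, n: float) -> float:
    """Observed Fisher information contribution of one group at prevalence pi.

    ``n * (dlambda/dpi)^2 / (lambda (1 - lambda))`` with slope 1 for direct
    questioning and ``1 - 2p`` for crosswise.
    """
    lam = response_prob(pi, design).lam
    if lam <= 0.0 or lam >= 1.0:
        raise ValidationError(f"information undefined at boundary lambda={lam}")
    slope = (1.0 - 2.0 * design.p) if design.is_crosswise else 1.0
    return n * slope**2 / (lam * (1.0 - lam))


def _as_pis(dataset: StudyDataset, pis: Union[float, Sequence[float]]) -> list[float]:
    if np.isscalar(pis):
        return [float(pis)] * len(dataset)
    pis = list(pis)
    if len(pis) != len(dataset):
        raise ValidationError(f"got {len(pis)} pi values for {len(dataset)} groups")
    return [float(v) for v in pis]


def log_likelihood(dataset: StudyDataset, pis: Union[float, Sequence[float]]) -> float:
    """Product-binomial log likelihood (kernel; binomial coefficients omitted).

    ``pis`` is either one shared prevalence or one value per group.  The
    constant coefficients cancel in every likelihood-ratio statistic the
    package computes.  A boundary ``lambda`` contradicting the observed
    counts yields ``-inf`` rather than an exception (0*log 0 = 0).
    """
    total = 0.0
    for g, pi in zip(dataset, _as_pis(dataset, pis)):
        lam = response_prob(pi, g.design).lam
        c, m = g.count_a, g.n - g.count_a
        for count, prob in ((c, lam), (m, 1.0 - lam)):
            if count > 0:
                if prob <= 0.0:
                    return -math.inf
                total += count * math.log(prob)
    return total


def _pooled_se(dataset: StudyDataset, pi: float) -> float:
    info = sum(group_information(pi, g.design, g.n) for g in dataset)
    return math.sqrt(1.0 / info)


def estimate_pooled(
    dataset: StudyDataset, settings: EMSettings = EMSettings()
) -> PrevalenceEstimate:
    """Shared-prevalence MLE across crosswise groups via expectation maximization.

    E-step: expected carrier counts per group — among option-A responders
    ``count_a * pi (1-p) / lambda``, among the rest ``(n - count_a) * pi p /
    (1 - lambda)``.  M-step: pi <- total expected carriers / total n.  The
    one-parameter likelihood is unimodal, so the fixed point is the MLE;
    agreement with direct numerical maximization is asserted in the test
    suite.  SE from the inverse observed Fisher information at the solution
    (at a boundary solution the information is evaluated at the boundary and
    the estimate flagged).
    """
    groups = list(dataset)
    if not groups:
        raise ValidationError("empty dataset")
    if any(not g.design.is_crosswise for g in groups):
        raise ValidationError("pooled ECWM estimation requires crosswise groups only")
    total_n = sum(g.n for g in groups)

    def em_step(pi: float) -> float:
        carriers = 0.0
        for g in groups:
            p = g.design.p
            lam = p + pi * (1.0 - 2.0 * p)
            # carriers among "exactly one" answers and among "both/none" answers
            if lam > 0.0:
                carriers += g.count_a * pi * (1.0 - p) / lam
            if lam < 1.0:
                carriers += (g.n - g.count_a) * pi * p / (1.0 - lam)
        return min(1.0, max(0.0, carriers / total_n))

    pi = settings.pi_init
    trace = [pi]
    converged = False
    for _ in range(settings.max_iter):
        pi1 = em_step(pi)
        trace.append(pi1)
        if abs(pi1 - pi) < settings.tol:
            pi, converged = pi1, True
            break
        pi2 = em_step(pi1)
        trace.append(pi2)
        if abs(pi2 - pi1) < settings.tol:
            pi, converged = pi2, True
            break
        # Aitken extrapolation: EM converges linearly, painfully so when the
        # maximum sits near a boundary; jump to the geometric limit whenever
        # that does not decrease the likelihood
        pi_next = pi2
        denom = (pi2 - pi1) - (pi1 - pi)
        if denom != 0.0:
            acc = min(1.0, max(0.0, pi - (pi1 - pi) ** 2 / denom))
            if log_likelihood(dataset, acc) >= log_likelihood(dataset, pi2):
                pi_next = acc
                trace.append(acc)
        pi = pi_next
    if not converged:
        raise ConvergenceError(
            f"EM did not converge within {settings.max_iter} iterations "
            f"(last |dpi| = {abs(trace[-1] - trace[-2]):.3e})",
            trace,
        )

    logger.info(
        "EM converged: pi=%.10f after %d iterations, logL=%.6f",
        pi, len(trace) - 1, log_likelihood(dataset, pi),
    )
    # EM stays inside [0,1]; an estimate pinned against 0 or 1 means the
    # unconstrained maximum lies outside the parameter space.
    boundary = pi < 10.0 * settings.tol or pi > 1.0 - 10.0 * settings.tol
    se_point = min(1.0 - 1e-9, max(1e-9, pi)) if boundary else pi
    se = _pooled_se(dataset, se_point)
    lo, hi = _wald_ci(pi, se)
    return PrevalenceEstimate(
        pi_hat=pi,
        se=se,
        ci_low=lo,
        ci_high=hi,
        method="maximum_likelihood",
        label="+".join(g.label for g in groups),
        truncated=boundary,
    )
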