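"""Likelihood-ratio (G²) tests and contingency analyses.

All model comparisons are nested: an unrestricted model is compared with a
restricted one (equal prevalences across groups, or prevalence fixed at a
constant) via twice the log-likelihood difference, asymptotically
chi-squared with as many degrees of freedom as restrictions.  The ECWM
goodness-of-fit test is the special case comparing the saturated two-group
model (one option-A probability per group) against the one-parameter
shared-prevalence model; its single degree of freedom is what the extended
design buys over the plain crosswise model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, chi2_contingency

from .designs import StudyDataset, ValidationError
from .estimation import EMSettings, estimate_pooled, log_likelihood

__all__ = [
    "GofResult",
    "LRComparison",
    "ContingencyResult",
    "goodness_of_fit",
    "compare_prevalences",
    "test_against_constant",
    "pearson_2x2",
    "fit_shared_pi",
]

logger = logging.getLogger(__name__)

_NEG_TOL = 1e-8  # numerical leeway before a negative statistic is an error


def _chisq_p(stat: float, df: int) -> float:
    if math.isinf(stat):
        return 0.0
    return float(chi2.sf(stat, df))


def _clip_stat(stat: float, what: str) -> float:
    if stat < -_NEG_TOL:
        raise RuntimeError(f"{what} came out negative ({stat}); nested fit failed")
    return max(0.0, stat)


@dataclass(frozen=True)
class GofResult:
    """Goodness of fit: G², degrees of freedom, upper-tail χ² p-value."""

    g_squared: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"g_squared": self.g_squared, "df": self.df, "p_value": self.p_value}


@dataclass(frozen=True)
class LRComparison:
    """Nested-model comparison: ΔG², df, p-value, and the restriction tested.

    ``boundary`` flags a restricted model with zero likelihood (e.g. testing
    pi = 0 against data containing affirmative direct answers), in which
    case ``delta_g_squared`` is ``+inf`` — reported as such, never replaced
    by a large finite surrogate.
    """

    delta_g_squared: float
    df: int
    p_value: float
    restriction: str
    boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "delta_g_squared": self.delta_g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "restriction": self.restriction,
            "boundary": self.boundary,
        }


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson χ² with Cramér's V = sqrt(χ² / (N (min(r,c) - 1)))."""

    chi_squared: float
    df: int
    p_value: float
    cramers_v: float

    def to_dict(self) -> dict:
        return {
            "chi_squared": self.chi_squared,
            "df": self.df,
            "p_value": self.p_value,
            "cramers_v": self.cramers_v,
        }


def fit_shared_pi(dataset: StudyDataset, xatol: float = 1e-10) -> float:
    """Maximize the joint likelihood over one shared prevalence in [0, 1].

    Works for any mixture of direct and crosswise groups (the one-parameter
    likelihood remains unimodal); bounded Brent search.  For all-crosswise
    datasets this agrees with the EM route, which the test suite asserts.
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    res = minimize_scalar(
        lambda pi: -log_likelihood(dataset, pi),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": xatol},
    )
    if not res.success:
        raise RuntimeError(f"shared-prevalence fit failed: {res.message}")
    logger.info(
        "shared-pi fit converged: pi=%.10f after %d evaluations, logL=%.6f",
        res.x, res.nfev, -res.fun,
    )
    return float(res.x)


def goodness_of_fit(
    dataset: StudyDataset, settings: EMSettings = EMSettings()
) -> GofResult:
    """ECWM fit test: shared-prevalence model against the saturated model.

    G² = 2 [l_saturated - l_pooled]; the saturated model matches each
    group's observed proportion exactly, the restricted model fits one pi
    across both groups by EM.  df = 1 for the two-group design.
    """
    cw = dataset.crosswise_groups
    if len(dataset) != 2 or len(cw) != 2:
        raise ValidationError("goodness of fit needs exactly two crosswise groups")
    pooled = estimate_pooled(dataset, settings)
    # saturated model: each group's option-A probability free at c/n
    ll_sat = 0.0
    for g in dataset:
        for count in (g.count_a, g.n - g.count_a):
            if count > 0:
                ll_sat += count * math.log(count / g.n)
    ll_pooled = log_likelihood(dataset, pooled.pi_hat)
    g2 = _clip_stat(2.0 * (ll_sat - ll_pooled), "G²")
    return GofResult(g_squared=g2, df=1, p_value=_chisq_p(g2, 1))


def _fit_single_pi(dataset: StudyDataset) -> float:
    """MLE of one shared prevalence, exact where a closed form exists."""
    if len(dataset) == 1 and not dataset[0].design.is_crosswise:
        return dataset[0].prop_a
    if all(g.design.is_crosswise for g in dataset):
        return estimate_pooled(dataset).pi_hat
    return fit_shared_pi(dataset)


def compare_prevalences(
    dataset_a: StudyDataset, dataset_b: StudyDataset
) -> LRComparison:
    """Test equality of the prevalences underlying two datasets.

    Unrestricted model: one prevalence per dataset.  Restricted model: a
    single shared prevalence over the combined groups, fitted by bounded
    1-D maximization.  ΔG² = 2 [l_free - l_shared], df = 1.
    """
    pi_a, pi_b = _fit_single_pi(dataset_a), _fit_single_pi(dataset_b)
    ll_free = log_likelihood(dataset_a, pi_a) + log_likelihood(dataset_b, pi_b)
    combined = StudyDataset(list(dataset_a) + list(dataset_b))
    pi_shared = fit_shared_pi(combined)
    ll_shared = log_likelihood(combined, pi_shared)
    stat = _clip_stat(2.0 * (ll_free - ll_shared), "ΔG²")
    return LRComparison(
        delta_g_squared=stat,
        df=1,
        p_value=_chisq_p(stat, 1),
        restriction="pi_a = pi_b",
    )


def test_against_constant(dataset: StudyDataset, pi0: float) -> LRComparison:
    """Test the dataset's prevalence against a fixed constant.

    ΔG² = 2 [l(pi_hat) - l(pi0)], df = 1.  When the constant assigns zero
    probability to an observed answer (e.g. pi0 = 0 for direct data with
    affirmative answers) the statistic is +inf and the result is flagged
    as a boundary case.
    """
    if not (0.0 <= pi0 <= 1.0):
        raise ValidationError(f"pi0 must lie in [0, 1], got {pi0}")
    pi_hat = _fit_single_pi(dataset)
    ll_free = log_likelihood(dataset, pi_hat)
    ll_null = log_likelihood(dataset, pi0)
    if math.isinf(ll_null):
        return LRComparison(
            delta_g_squared=math.inf,
            df=1,
            p_value=0.0,
            restriction=f"pi = {pi0}",
            boundary=True,
        )
    stat = _clip_stat(2.0 * (ll_free - ll_null), "ΔG²")
    return LRComparison(
        delta_g_squared=stat, df=1, p_value=_chisq_p(stat, 1), restriction=f"pi = {pi0}"
    )


def pearson_2x2(table) -> ContingencyResult:
    """Pearson χ² (no continuity correction) and Cramér's V for an r×c table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(f"need an r×c table with r,c >= 2, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValidationError("negative cell counts")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValidationError("zero marginal: every row and column needs observations")
    stat, p, df, _ = chi2_contingency(arr, correction=False)
    n = arr.sum()
    v = math.sqrt(stat / (n * (min(arr.shape) - 1)))
    return ContingencyResult(
        chi_squared=float(stat), df=int(df), p_value=float(p), cramers_v=v
    )
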