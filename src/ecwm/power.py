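"""Design-based power and sample-size calculations.

Randomization inflates the variance of a crosswise prevalence estimate by
the factor ``lambda (1 - lambda) / (pi (1 - pi) (1 - 2p)^2)`` relative to a
direct question at the same n, which is why crosswise arms need larger
samples.  Power here is the normal-approximation (Wald) power of the
two-sided test of equal prevalences, with each arm's variance evaluated at
its assumed prevalence.  An ECWM arm is represented as its two
complementary-p groups; its variance is the inverse of the summed group
Fisher informations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

from scipy.stats import norm

from .designs import QuestionDesign, ValidationError
from .estimation import group_information

__all__ = [
    "DesignArm",
    "PowerSpec",
    "PowerResult",
    "design_variance",
    "posthoc_power",
    "required_total_n",
]

ArmLike = Union[QuestionDesign, Sequence[QuestionDesign]]


def _as_designs(design: ArmLike) -> list[QuestionDesign]:
    if isinstance(design, QuestionDesign):
        return [design]
    return list(design)


def design_variance(pi: float, design: ArmLike, n: Union[int, Sequence[int]]) -> float:
    """Sampling variance of the prevalence estimate for one arm.

    ``design`` is a single QuestionDesign, or a sequence of designs (an
    ECWM pair) with ``n`` a matching sequence of group sizes; multi-group
    variance is the inverse of the summed Fisher informations, evaluated
    at the assumed prevalence.
    """
    designs = _as_designs(design)
    ns = [n] * len(designs) if isinstance(n, (int, float)) else list(n)
    if len(ns) != len(designs):
        raise ValidationError(f"{len(designs)} designs but {len(ns)} group sizes")
    if any(v < 1 for v in ns):
        raise ValidationError("group sizes must be positive")
    info = sum(group_information(pi, d, m) for d, m in zip(designs, ns))
    return 1.0 / info


@dataclass(frozen=True)
class DesignArm:
    """One arm of a comparison: assumed prevalence, design(s), group size(s)."""

    pi: float
    design: ArmLike
    n: Union[int, Sequence[int]]

    @property
    def variance(self) -> float:
        return design_variance(self.pi, self.design, self.n)


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a two-arm prevalence comparison."""

    arm_a: DesignArm
    arm_b: DesignArm
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class PowerResult:
    power: float
    se_diff: float
    z_effect: float

    def to_dict(self) -> dict:
        return {"power": self.power, "se_diff": self.se_diff, "z_effect": self.z_effect}


def posthoc_power(spec: PowerSpec) -> PowerResult:
    """Wald power of the test of equal prevalences between two arms.

    z_effect = |pi_a - pi_b| / sqrt(var_a + var_b);
    two-sided power = Phi(z_effect - z_{1-alpha/2}) + Phi(-z_effect - z_{1-alpha/2}).
    At zero effect this reduces to alpha, as it must.
    """
    var = spec.arm_a.variance + spec.arm_b.variance
    se_diff = math.sqrt(var)
    z_eff = abs(spec.arm_a.pi - spec.arm_b.pi) / se_diff
    if spec.two_sided:
        z_crit = norm.ppf(1.0 - spec.alpha / 2.0)
        power = norm.cdf(z_eff - z_crit) + norm.cdf(-z_eff - z_crit)
    else:
        z_crit = norm.ppf(1.0 - spec.alpha)
        power = norm.cdf(z_eff - z_crit)
    return PowerResult(power=float(power), se_diff=se_diff, z_effect=z_eff)


def _split_arm_n(designs: list[QuestionDesign], n_arm: int) -> list[int]:
    """Split an arm's total over its groups, near-equally (floor/ceil)."""
    k = len(designs)
    base, extra = divmod(n_arm, k)
    return [base + (1 if i >= k - extra else 0) for i in range(k)]


def _power_at_total(
    total_n: int,
    pi_a: float,
    pi_b: float,
    design_a: ArmLike,
    design_b: ArmLike,
    allocation_ratio: float,
    alpha: float,
) -> float:
    da, db = _as_designs(design_a), _as_designs(design_b)
    n_a = max(len(da), round(total_n * allocation_ratio / (1.0 + allocation_ratio)))
    n_b = max(len(db), total_n - n_a)
    spec = PowerSpec(
        DesignArm(pi_a, da, _split_arm_n(da, n_a)),
        DesignArm(pi_b, db, _split_arm_n(db, n_b)),
        alpha=alpha,
    )
    return posthoc_power(spec).power


def required_total_n(
    pi_a: float,
    pi_b: float,
    design_a: ArmLike,
    design_b: ArmLike,
    allocation_ratio: float = 2.0,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> int:
    """Smallest total sample size reaching the target power.

    The total is allocated ``allocation_ratio : 1`` between arm a and arm b
    (default 2:1, the convention of assigning twice as many respondents to
    the less efficient indirect arm), and each multi-group arm splits its
    share near-equally over its groups.  Minimality is guaranteed: the
    returned N reaches the target and N - 1 does not.
    """
    if pi_a == pi_b:
        raise ValidationError("zero effect: target power is unreachable")
    if allocation_ratio <= 0:
        raise ValidationError("allocation_ratio must be positive")
    if not (0.0 < target_power < 1.0):
        raise ValidationError("target_power must lie in (0, 1)")

    k_min = len(_as_designs(design_a)) + len(_as_designs(design_b))

    def ok(total: int) -> bool:
        return (
            _power_at_total(total, pi_a, pi_b, design_a, design_b, allocation_ratio, alpha)
            >= target_power
        )

    hi = max(k_min, 8)
    while not ok(hi):
        hi *= 2
        if hi > 10**9:
            raise ValidationError("target power unreachable at any feasible sample size")
    lo = k_min
    # power is monotone in total n at fixed allocation; bisect the threshold
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    # integer allocation rounding can dent strict monotonicity by one unit;
    # walk down until N - 1 genuinely fails
    while hi > k_min and ok(hi - 1):
        hi -= 1
    return hi
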