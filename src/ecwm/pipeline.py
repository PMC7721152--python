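"""Full study analysis: estimates, fit test, comparisons, power, dropout.

`run_paper_analysis` orchestrates the complete analysis of a two-arm
prevalence study (a complementary-p ECWM pair plus a direct-questioning
control): per-group closed-form estimates, the pooled EM estimate, the
ECWM goodness-of-fit test, likelihood-ratio comparisons (ECWM vs DQ and
each arm vs zero), post-hoc power of the arm comparison, and optionally a
dropout-by-condition contingency test.  A bundled fixture carries the
reconstructed counts of the published survey this pipeline reproduces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .designs import StudyDataset, ValidationError, read_counts
from .estimation import PrevalenceEstimate, estimate_group, estimate_pooled
from .inference import (
    ContingencyResult,
    GofResult,
    LRComparison,
    compare_prevalences,
    goodness_of_fit,
    pearson_2x2,
    test_against_constant,
)
from .power import DesignArm, PowerResult, PowerSpec, posthoc_power

__all__ = [
    "PaperAnalysisReport",
    "run_paper_analysis",
    "load_reconstructed_counts",
    "load_dropout_table",
]


def load_reconstructed_counts() -> StudyDataset:
    """The bundled reconstructed counts fixture (ECWM pair + DQ control)."""
    ref = resources.files("ecwm.data").joinpath("reconstructed_counts.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_counts(fh)


def load_dropout_table() -> np.ndarray:
    """The bundled dropout-by-condition 2x2 table (rows DQ/ECWM)."""
    ref = resources.files("ecwm.data").joinpath("dropout_table.json")
    with ref.open("r", encoding="utf-8") as fh:
        return np.array(json.load(fh)["table"], dtype=int)


@dataclass(frozen=True)
class PaperAnalysisReport:
    """Every statistic of the full study analysis, unrounded.

    ``interpretable`` applies the decision rule of the extended design: the
    pooled estimate is only meaningful when the goodness-of-fit test does
    not reject (a misfit means respondents systematically preferred one
    answer option, so the estimates must not be interpreted).
    """

    group_estimates: tuple[PrevalenceEstimate, ...]
    pooled: PrevalenceEstimate
    fit: GofResult
    ecwm_vs_dq: LRComparison
    ecwm_vs_zero: LRComparison
    dq_vs_zero: LRComparison
    posthoc_power: PowerResult
    alpha: float = 0.05
    dropout_test: ContingencyResult | None = None

    @property
    def interpretable(self) -> bool:
        return self.fit.p_value > self.alpha

    def to_dict(self) -> dict:
        out = {
            "group_estimates": [e.to_dict() for e in self.group_estimates],
            "pooled": self.pooled.to_dict(),
            "fit": self.fit.to_dict(),
            "ecwm_vs_dq": self.ecwm_vs_dq.to_dict(),
            "ecwm_vs_zero": self.ecwm_vs_zero.to_dict(),
            "dq_vs_zero": self.dq_vs_zero.to_dict(),
            "posthoc_power": self.posthoc_power.to_dict(),
            "alpha": self.alpha,
            "interpretable": self.interpretable,
        }
        if self.dropout_test is not None:
            out["dropout_test"] = self.dropout_test.to_dict()
        return out


def _split_study(counts: StudyDataset) -> tuple[StudyDataset, StudyDataset]:
    cw = counts.crosswise_groups
    dq = counts.direct_groups
    if len(cw) != 2 or len(dq) != 1:
        raise ValidationError(
            "expected one direct group and one complementary-p crosswise pair; "
            f"got {len(cw)} crosswise and {len(dq)} direct group(s)"
        )
    ecwm = StudyDataset(sorted(cw, key=lambda g: g.design.p))
    if not ecwm.is_ecwm_pair(tol=1e-6):
        raise ValidationError(
            "crosswise randomization probabilities are not complementary "
            f"(p = {cw[0].design.p}, {cw[1].design.p})"
        )
    return ecwm, StudyDataset(dq)


def run_paper_analysis(
    counts: StudyDataset,
    demographics=None,
    alpha: float = 0.05,
) -> PaperAnalysisReport:
    """Run the complete two-arm analysis on aggregate counts.

    ``counts`` must contain one direct group and one complementary-p
    crosswise pair (any order); ``demographics`` is an optional 2x2
    dropout-by-condition table.  All numbers are kept at full precision;
    rounding happens only at the presentation layer.
    """
    ecwm, dq_ds = _split_study(counts)
    dq = dq_ds[0]

    group_estimates = tuple(estimate_group(g) for g in list(ecwm) + [dq])
    pooled = estimate_pooled(ecwm)
    fit = goodness_of_fit(ecwm)
    ecwm_vs_dq = compare_prevalences(ecwm, dq_ds)
    ecwm_vs_zero = test_against_constant(ecwm, 0.0)
    dq_vs_zero = test_against_constant(dq_ds, 0.0)

    dq_est = estimate_group(dq)
    power = posthoc_power(
        PowerSpec(
            DesignArm(pooled.pi_hat_clipped, [g.design for g in ecwm], [g.n for g in ecwm]),
            DesignArm(dq_est.pi_hat_clipped, dq.design, dq.n),
            alpha=alpha,
        )
    )

    dropout = pearson_2x2(demographics) if demographics is not None else None
    return PaperAnalysisReport(
        group_estimates=group_estimates,
        pooled=pooled,
        fit=fit,
        ecwm_vs_dq=ecwm_vs_dq,
        ecwm_vs_zero=ecwm_vs_zero,
        dq_vs_zero=dq_vs_zero,
        posthoc_power=power,
        alpha=alpha,
        dropout_test=dropout,
    )
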