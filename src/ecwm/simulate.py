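"""Respondent-level answer simulation with non-adherence mechanisms.

Each simulated respondent is a carrier of the sensitive attribute with
probability ``pi_true`` and holds a true non-sensitive statement with
probability ``p`` (the design's randomization probability).  Before
answering, a mechanism is assigned:

* ``careless`` (rate ``c``): the respondent ignores the question and picks
  an answer by a fair coin — the "biased towards 50%" behavior.  Because a
  fair coin shifts both complementary ECWM groups symmetrically
  (``lambda' = (1 - c) lambda + c/2`` preserves ``lambda_2 = 1 - lambda_1``),
  this bias is invisible to the goodness-of-fit test.
* ``preference`` (rate ``d``, optionally restricted to carriers or
  non-carriers): the respondent deterministically picks one answer option.
  This breaks the complementarity of the two ECWM groups and is exactly
  what the fit test detects.
* ``adherent`` (the rest): answers per the processing tree — direct:
  "agree" iff carrier; crosswise: "exactly one" iff carrier XOR statement.

Mechanisms are disjoint and assigned in the order careless-then-preference
from one uniform draw, so the marginal rates stay interpretable and the
closed-form biased answer probabilities in :func:`bias_implied_estimates`
are exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd

from .designs import GroupObservation, QuestionDesign, StudyDataset, ValidationError
from .estimation import PrevalenceEstimate, estimate_group

__all__ = [
    "SimulationConfig",
    "RespondentRecord",
    "simulate_study",
    "replicate_counts",
    "bias_implied_estimates",
    "biased_response_prob",
    "records_to_csv",
]

OPTION_A, OPTION_B = "option_a", "option_b"
SCOPES = ("all", "carriers_only", "noncarriers_only")


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters and bias rates for one simulated study.

    ``designs`` lists ``(QuestionDesign, n)`` pairs, one per group; group
    labels default to ``g1, g2, ...`` in order.  ``careless_rate`` and
    ``preference_rate`` are disjoint mechanism probabilities (their sum may
    not exceed 1).  The seed governs a single stream; per-group substreams
    are derived deterministically from (seed, group label).
    """

    pi_true: float
    designs: Sequence[tuple[QuestionDesign, int]]
    careless_rate: float = 0.0
    preference_rate: float = 0.0
    preference_target: str = OPTION_B
    preference_scope: str = "all"
    seed: int = 0
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_true <= 1.0):
            raise ValidationError(f"pi_true must lie in [0, 1], got {self.pi_true}")
        for rate, name in (
            (self.careless_rate, "careless_rate"),
            (self.preference_rate, "preference_rate"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {rate}")
        if self.careless_rate + self.preference_rate > 1.0:
            raise ValidationError("careless_rate + preference_rate exceeds 1")
        if self.preference_target not in (OPTION_A, OPTION_B):
            raise ValidationError(f"unknown preference_target {self.preference_target!r}")
        if self.preference_scope not in SCOPES:
            raise ValidationError(f"unknown preference_scope {self.preference_scope!r}")
        if not self.designs:
            raise ValidationError("at least one (design, n) pair required")
        if self.labels is not None and len(self.labels) != len(self.designs):
            raise ValidationError("labels must match designs in length")

    @property
    def group_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [f"g{i + 1}" for i in range(len(self.designs))]


@dataclass(frozen=True)
class RespondentRecord:
    """Latent states and observed answer of one simulated respondent."""

    group_label: str
    carrier: bool
    statement_true: bool
    mechanism: str  # adherent | careless | preference
    answer_a: bool


def _group_rng(seed: int, label: str) -> np.random.Generator:
    # substream keyed on (seed, crc32(label)): reproducible and
    # insensitive to group order
    return np.random.default_rng([seed, zlib.crc32(label.encode("utf-8"))])


def _simulate_group(
    cfg: SimulationConfig, design: QuestionDesign, n: int, label: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rng = _group_rng(cfg.seed, label)
    carrier = rng.random(n) < cfg.pi_true
    p = design.p if design.is_crosswise else 0.0
    statement = rng.random(n) < p
    u = rng.random(n)
    coin = rng.random(n) < 0.5

    careless = u < cfg.careless_rate
    in_scope = {
        "all": np.ones(n, dtype=bool),
        "carriers_only": carrier,
        "noncarriers_only": ~carrier,
    }[cfg.preference_scope]
    preference = (
        ~careless & (u < cfg.careless_rate + cfg.preference_rate) & in_scope
    )
    adherent = ~careless & ~preference

    if design.is_crosswise:
        adherent_answer = carrier ^ statement
    else:
        adherent_answer = carrier
    answer = np.where(
        careless,
        coin,
        np.where(preference, cfg.preference_target == OPTION_A, adherent_answer),
    )
    mechanism = np.where(careless, "careless", np.where(preference, "preference", "adherent"))
    return carrier, statement, mechanism, answer.astype(bool)


def simulate_study(
    config: SimulationConfig,
) -> tuple[StudyDataset, list[RespondentRecord]]:
    """Simulate every respondent and aggregate to group counts.

    Returns the aggregate :class:`StudyDataset` (what the estimation
    pipeline consumes) together with the full respondent records.  Fully
    reproducible: the same config (including seed) yields identical output.
    """
    groups: list[GroupObservation] = []
    records: list[RespondentRecord] = []
    for label, (design, n) in zip(config.group_labels, config.designs):
        if n < 1:
            raise ValidationError(f"group {label!r}: n must be positive")
        carrier, statement, mechanism, answer = _simulate_group(config, design, n, label)
        groups.append(GroupObservation(label, design, n, int(answer.sum())))
        records.extend(
            RespondentRecord(label, bool(ca), bool(st), str(me), bool(an))
            for ca, st, me, an in zip(carrier, statement, mechanism, answer)
        )
    return StudyDataset(groups), records


def biased_response_prob(
    pi_true: float,
    design: QuestionDesign,
    careless_rate: float = 0.0,
    preference_rate: float = 0.0,
    preference_target: str = OPTION_B,
    preference_scope: str = "all",
) -> float:
    """Large-sample option-A probability under the bias mechanisms.

    Mixes the per-status answer probabilities: carriers and non-carriers
    each answer A with probability ``c/2 + d_s 1[target = A] + (1 - c - d_s)
    lambda_s`` where ``d_s`` is the preference rate if the status is in
    scope (else 0) and ``lambda_s`` the adherent answer probability for
    that status.
    """
    c, d = careless_rate, preference_rate
    pref_a = 1.0 if preference_target == OPTION_A else 0.0
    p = design.p if design.is_crosswise else None

    def status_prob(is_carrier: bool) -> float:
        if design.is_crosswise:
            lam_s = (1.0 - p) if is_carrier else p
        else:
            lam_s = 1.0 if is_carrier else 0.0
        scoped = (
            preference_scope == "all"
            or (preference_scope == "carriers_only" and is_carrier)
            or (preference_scope == "noncarriers_only" and not is_carrier)
        )
        d_s = d if scoped else 0.0
        return c / 2.0 + d_s * pref_a + (1.0 - c - d_s) * lam_s

    return pi_true * status_prob(True) + (1.0 - pi_true) * status_prob(False)


def bias_implied_estimates(
    pi_true: float,
    designs: Sequence[QuestionDesign],
    careless_rate: float = 0.0,
    preference_rate: float = 0.0,
    preference_target: str = OPTION_B,
    preference_scope: str = "all",
) -> tuple[float, ...]:
    """Large-sample per-group prevalence estimates implied by biased answering.

    Analytic, no sampling: each group's biased answer probability is pushed
    through that group's closed-form estimator.  For a complementary-p ECWM
    pair, careless responding leaves the two implied estimates equal (the
    bias is undetectable by fit), whereas an option preference drives them
    apart — the signature the goodness-of-fit test picks up.
    """
    out = []
    for design in designs:
        lam = biased_response_prob(
            pi_true, design, careless_rate, preference_rate,
            preference_target, preference_scope,
        )
        if design.is_crosswise:
            out.append((lam - design.p) / (1.0 - 2.0 * design.p))
        else:
            out.append(lam)
    return tuple(out)


def replicate_counts(
    config: SimulationConfig, n_reps: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw option-A counts for ``n_reps`` independent studies, vectorized.

    Mechanisms are iid across respondents, so each group's count is exactly
    Binomial(n, lambda') with ``lambda'`` the biased answer probability —
    the same marginal law as aggregating :func:`simulate_study` output.
    Returns an (n_reps, n_groups) integer array.  This is the fast path for
    Monte-Carlo calibration studies; respondent records are not produced.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lams = [
        biased_response_prob(
            config.pi_true, design, config.careless_rate, config.preference_rate,
            config.preference_target, config.preference_scope,
        )
        for design, _ in config.designs
    ]
    ns = [n for _, n in config.designs]
    return rng.binomial(ns, lams, size=(n_reps, len(ns)))


def records_to_csv(records: Sequence[RespondentRecord], sink: Union[str, IO[str]]) -> None:
    """Export respondent records for inspection (one row per respondent)."""
    pd.DataFrame(
        {
            "group_label": [r.group_label for r in records],
            "carrier": [r.carrier for r in records],
            "statement_true": [r.statement_true for r in records],
            "mechanism": [r.mechanism for r in records],
            "answer_a": [r.answer_a for r in records],
        }
    ).to_csv(sink, index=False)
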