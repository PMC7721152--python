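"""Questioning designs, observed group counts, and tabular I/O.

The package works with aggregate answer frequencies: for every experimental
group we keep the questioning design (direct, or crosswise with a known
randomization probability ``p``), the number of respondents, and the number
of "option A" answers.  Option A is fixed throughout the package as

* direct questioning: "yes / I agree" to the sensitive statement;
* crosswise: "I agree with *exactly one* of the two statements", whose
  model probability is ``pi*(1-p) + (1-pi)*p``.

Keeping one orientation everywhere prevents silent sign flips between the
estimator, the likelihood and the simulator.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "QuestionDesign",
    "GroupObservation",
    "StudyDataset",
    "ValidationError",
    "ReconstructionError",
    "read_counts",
    "write_counts",
    "write_report",
    "read_report",
    "reconstruct_count",
    "round_half_away",
]

COUNT_COLUMNS = ("group_id", "design", "p", "n_total", "count_a")


class ValidationError(ValueError):
    """Raised when input data violate a design or count invariant."""


class ReconstructionError(ValueError):
    """Raised when no (or no unique) integer count matches a printed estimate."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed survey tables.

    Python's builtin ``round`` is banker's rounding; published percentages
    are conventionally rounded half-up, which matters when matching counts
    against printed two-decimal values.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class QuestionDesign:
    """A question format: ``direct``, or ``crosswise`` with randomization probability ``p``.

    ``p`` is the known prevalence of the non-sensitive statement (e.g. a
    birth-month category).  The crosswise estimator divides by ``1 - 2p``,
    so ``p = 0.5`` is excluded (the design carries no information there).
    """

    kind: str
    p: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "crosswise"):
            raise ValidationError(f"unknown design kind {self.kind!r}")
        if self.kind == "direct":
            if self.p is not None:
                raise ValidationError("direct design takes no randomization probability")
        else:
            if self.p is None or not (0.0 < self.p < 1.0):
                raise ValidationError(f"crosswise p must lie in (0,1), got {self.p!r}")
            if self.p == 0.5:
                raise ValidationError("crosswise p = 0.5 leaves the prevalence unidentified")

    @classmethod
    def direct(cls) -> "QuestionDesign":
        return cls("direct")

    @classmethod
    def crosswise(cls, p: float) -> "QuestionDesign":
        return cls("crosswise", p)

    @property
    def is_crosswise(self) -> bool:
        return self.kind == "crosswise"


@dataclass(frozen=True)
class GroupObservation:
    """One experimental group's aggregate data.

    ``count_a`` counts option-A answers: "agree" under direct questioning,
    "exactly one statement" under crosswise questioning.
    """

    label: str
    design: QuestionDesign
    n: int
    count_a: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.label!r}: n must be positive, got {self.n}")
        if not (0 <= self.count_a <= self.n):
            raise ValidationError(
                f"group {self.label!r}: count_a={self.count_a} outside [0, n={self.n}]"
            )

    @property
    def prop_a(self) -> float:
        """Observed option-A proportion (the saturated-model lambda-hat)."""
        return self.count_a / self.n


@dataclass(frozen=True)
class StudyDataset:
    """An ordered collection of group observations with unique labels."""

    groups: tuple[GroupObservation, ...]

    def __init__(self, groups: Iterable[GroupObservation]):
        object.__setattr__(self, "groups", tuple(groups))
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate group labels: {labels}")

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def __getitem__(self, i: int) -> GroupObservation:
        return self.groups[i]

    @property
    def crosswise_groups(self) -> tuple[GroupObservation, ...]:
        return tuple(g for g in self.groups if g.design.is_crosswise)

    @property
    def direct_groups(self) -> tuple[GroupObservation, ...]:
        return tuple(g for g in self.groups if not g.design.is_crosswise)

    def is_ecwm_pair(self, tol: float = 1e-9) -> bool:
        """True for exactly two crosswise groups with complementary p (p2 = 1 - p1)."""
        cw = self.crosswise_groups
        if len(self.groups) != 2 or len(cw) != 2:
            return False
        return math.isclose(cw[0].design.p + cw[1].design.p, 1.0, abs_tol=tol)

    def subset(self, labels: Sequence[str]) -> "StudyDataset":
        by_label = {g.label: g for g in self.groups}
        missing = [l for l in labels if l not in by_label]
        if missing:
            raise ValidationError(f"unknown group labels: {missing}")
        return StudyDataset(by_label[l] for l in labels)

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)


def _parse_row(i: int, row: pd.Series) -> GroupObservation:
    kind = str(row["design"]).strip().lower()
    if kind not in ("direct", "crosswise"):
        raise ValidationError(f"row {i}: design must be 'direct' or 'crosswise', got {row['design']!r}")
    if kind == "crosswise":
        try:
            p = float(row["p"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {i}: crosswise row needs a numeric p, got {row['p']!r}")
        if math.isnan(p):
            raise ValidationError(f"row {i}: crosswise row needs p")
        try:
            design = QuestionDesign.crosswise(p)
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    else:
        design = QuestionDesign.direct()
    try:
        n = int(row["n_total"])
        count_a = int(row["count_a"])
    except (TypeError, ValueError):
        raise ValidationError(f"row {i}: n_total and count_a must be integers")
    try:
        return GroupObservation(str(row["group_id"]), design, n, count_a)
    except ValidationError as e:
        raise ValidationError(f"row {i}: {e}") from None


def read_counts(source: Union[str, IO[str]]) -> StudyDataset:
    """Read a counts table (CSV: group_id,design,p,n_total,count_a; '#' comments).

    ``p`` is parsed only for crosswise rows; validation errors name the
    offending row and field.
    """
    df = pd.read_csv(source, comment="#", dtype={"group_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    return StudyDataset(_parse_row(i, row) for i, row in df.iterrows())


def write_counts(dataset: StudyDataset, sink: Union[str, IO[str]]) -> None:
    """Write a StudyDataset in the counts-CSV dialect (lossless round trip)."""
    df = pd.DataFrame(
        {
            "group_id": [g.label for g in dataset],
            "design": [g.design.kind for g in dataset],
            "p": [g.design.p if g.design.is_crosswise else "" for g in dataset],
            "n_total": [g.n for g in dataset],
            "count_a": [g.count_a for g in dataset],
        }
    )
    df.to_csv(sink, index=False)


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def write_report(results: dict, sink: Union[str, IO[str], None] = None) -> str:
    """Serialize a mapping of estimates/tests to a JSON document.

    Every result object exposing ``to_dict`` is expanded; infinities are
    encoded as the strings ``"inf"``/``"-inf"`` so the document stays valid
    JSON and round-trips.
    """
    if not results:
        raise ValidationError("empty report")
    text = json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n"
    if sink is not None:
        if isinstance(sink, (str,)):
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text)
        else:
            sink.write(text)
    return text


def _restore_inf(obj):
    if obj == "inf":
        return math.inf
    if obj == "-inf":
        return -math.inf
    if isinstance(obj, dict):
        return {k: _restore_inf(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore_inf(v) for v in obj]
    return obj


def read_report(source: Union[str, IO[str]]) -> dict:
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            return _restore_inf(json.load(fh))
    return _restore_inf(json.load(source))


def _point_estimate_percent(c: int, n: int, design: QuestionDesign) -> float:
    lam = c / n
    if design.is_crosswise:
        return 100.0 * (lam - design.p) / (1.0 - 2.0 * design.p)
    return 100.0 * lam


def reconstruct_count(
    pi_printed_percent: float, design: QuestionDesign, n: int
) -> int:
    """Recover the integer answer count behind a printed prevalence estimate.

    Searches c in 0..n for the count whose closed-form point estimate,
    rounded half-away-from-zero to two decimals in percent, equals the
    printed value.  Published tables occasionally round an intermediate
    proportion before the final division, shifting the last printed digit
    by one; when no count matches exactly, a unique candidate within one
    unit of the last printed digit (0.01) is accepted.  Anything else
    signals a transcription error.
    """
    if not (0.0 <= pi_printed_percent <= 100.0):
        raise ValidationError(f"printed percent {pi_printed_percent} outside [0, 100]")
    estimates = [_point_estimate_percent(c, n, design) for c in range(n + 1)]
    exact = [c for c, e in enumerate(estimates) if round_half_away(e) == round_half_away(pi_printed_percent)]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        raise ReconstructionError(
            f"{len(exact)} counts reproduce {pi_printed_percent}% at n={n}: {exact}"
        )
    near = [c for c, e in enumerate(estimates) if abs(e - pi_printed_percent) <= 0.01 + 1e-12]
    if len(near) == 1:
        return near[0]
    raise ReconstructionError(
        f"no integer count in [0, {n}] reproduces {pi_printed_percent}% "
        f"for design {design.kind} (closest: "
        f"{min(range(n + 1), key=lambda c: abs(estimates[c] - pi_printed_percent))})"
    )
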