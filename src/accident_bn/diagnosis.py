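"""Backward reasoning: behavior posteriors given an accident, and the
iterative identification of critical behavior groups.

Backward reasoning conditions on an accident type having occurred and asks
how likely each unsafe behavior is to have been involved:

    P(B_i = Yes | Y = k, clamped behaviors)

The critical-group procedure iterates: among unselected behaviors whose
occurrence frequency within the accident type clears a floor (default 8%),
pick the one with the highest posterior; clamp it to Yes and repeat until
the best remaining posterior falls below the stopping threshold (default
15%).  The selected behaviors form the critical group for that accident
type — the co-occurring behaviors that transmit the most probability to it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalog_io import ACCIDENT_TYPES, CaseMatrix, behavior_index
from .inference import as_evidence, class_posterior, _class_likelihoods, _check_codes
from .tan_model import TanModel

__all__ = [
    "DiagnosisThresholds",
    "DiagnosisStep",
    "DiagnosisTrace",
    "RootCandidate",
    "behavior_posterior",
    "behavior_frequency",
    "critical_group",
    "select_root",
]


@dataclass(frozen=True)
class DiagnosisThresholds:
    """Eligibility floor on within-type frequency and the stopping posterior."""

    frequency_floor: float = 0.08
    stop_posterior: float = 0.15

    def __post_init__(self) -> None:
        for name in ("frequency_floor", "stop_posterior"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def behavior_posterior(
    model: TanModel,
    behavior: str,
    accident_type: str,
    extra_evidence: Mapping[str, int] | Sequence | None = None,
) -> float:
    """Exact P(behavior = Yes | Y = accident_type, extra evidence)."""
    ev = as_evidence(extra_evidence) if extra_evidence else {}
    if behavior in ev:
        raise ValueError(f"behavior {behavior} is already clamped in the evidence")
    _check_codes(model, {**ev, behavior: 1})
    k = model.class_index(accident_type)
    num = _class_likelihoods(model, {**ev, behavior: 1})[k]
    den = _class_likelihoods(model, ev)[k]
    if den <= 0:
        raise ValueError("evidence has zero probability under the model")
    return float(num / den)


def behavior_frequency(
    matrix: CaseMatrix,
    behavior: str,
    accident_type: str,
    per_type_denominator: bool = True,
) -> float:
    """Occurrence rate of a behavior among cases of one accident type.

    The default denominator is the number of cases of that type (the base
    that makes the worked eligibility checks come out); set
    ``per_type_denominator=False`` to divide by all cases instead.
    """
    if per_type_denominator:
        return matrix.frequency(behavior, accident_type)
    mask = matrix.accident_types == accident_type
    if not mask.any():
        raise ValueError(f"no cases of accident type {accident_type}")
    return float((matrix.data[behavior] & mask).sum() / matrix.n_cases)


@dataclass(frozen=True)
class DiagnosisStep:
    """One round of the loop: all eligible candidates and the selection.

    ``selected`` is None on the final (stopping) round.
    """

    candidate_posteriors: Mapping[str, float]
    selected: str | None
    selected_posterior: float | None


@dataclass(frozen=True)
class DiagnosisTrace:
    """Ordered record of the backward-diagnosis loop for one accident type."""

    accident_type: str
    thresholds: DiagnosisThresholds
    steps: tuple[DiagnosisStep, ...]

    @property
    def group(self) -> tuple[str, ...]:
        """The critical group, in selection order."""
        return tuple(s.selected for s in self.steps if s.selected is not None)

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace: one row per (round, candidate)."""
        records = []
        for step_no, step in enumerate(self.steps, start=1):
            for code, post in step.candidate_posteriors.items():
                records.append(
                    {
                        "step": step_no,
                        "behavior": code,
                        "posterior": post,
                        "selected": code == step.selected,
                    }
                )
        return pd.DataFrame.from_records(
            records, columns=["step", "behavior", "posterior", "selected"]
        )


def critical_group(
    model: TanModel,
    matrix: CaseMatrix,
    accident_type: str,
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
) -> DiagnosisTrace:
    """Identify the critical group of unsafe behaviors for one accident type.

    Deterministic given (model, matrix, thresholds); posterior ties are
    broken toward the lowest behavior-code number.  The trace records every
    round's eligible candidates and their posteriors, including the final
    round where the loop stops.
    """
    missing = set(model.features) - set(matrix.behaviors)
    if missing:
        raise ValueError(f"model and matrix behavior sets differ: {sorted(missing)}")
    eligible = [
        b
        for b in model.features
        if behavior_frequency(matrix, b, accident_type) >= thresholds.frequency_floor
    ]
    evidence: dict[str, int] = {}
    steps: list[DiagnosisStep] = []
    while True:
        remaining = [b for b in eligible if b not in evidence]
        posteriors = {
            b: behavior_posterior(model, b, accident_type, evidence)
            for b in remaining
        }
        if not posteriors:
            steps.append(DiagnosisStep(posteriors, None, None))
            break
        best = min(posteriors, key=lambda b: (-posteriors[b], behavior_index(b)))
        if posteriors[best] < thresholds.stop_posterior:
            steps.append(DiagnosisStep(posteriors, None, None))
            break
        steps.append(DiagnosisStep(posteriors, best, posteriors[best]))
        evidence[best] = 1
    return DiagnosisTrace(accident_type, thresholds, tuple(steps))


@dataclass(frozen=True)
class RootCandidate:
    """One behavior's root-node credentials, with the ranking rationale."""

    code: str
    per_type_counts: Mapping[str, int]
    total: int
    in_all_types: bool
    strength_spread: float
    rationale: str


def select_root(matrix: CaseMatrix, top: int | None = None) -> list[RootCandidate]:
    """Rank behaviors as root-node candidates.

    A good root occurs in all four accident types, occurs often, and has a
    *weak* accident attribute (its presence should not swing the class
    posterior).  The empirical attribute strength of behavior B for type k
    is taken as P̂(Y=k | B=Yes) − P̂(Y=k); its spread is the largest absolute
    strength across types.  Ranking: occurs-in-all-types first, then spread
    ascending, then total occurrences descending — a frequent behavior with
    a strong class signature (e.g. one almost exclusive to falls) is demoted
    despite its count.
    """
    if matrix.n_cases == 0:
        raise ValueError("cannot rank root candidates on an empty matrix")
    class_counts = matrix.class_counts()
    types = [t for t in ACCIDENT_TYPES if t in class_counts]
    prior = {t: class_counts[t] / matrix.n_cases for t in types}

    candidates = []
    for code in matrix.behaviors:
        col = matrix.data[code]
        per_type = {
            t: int((col & (matrix.accident_types == t)).sum()) for t in types
        }
        total = sum(per_type.values())
        in_all = len(types) == len(ACCIDENT_TYPES) and all(
            per_type[t] >= 1 for t in types
        )
        if total == 0:
            spread = float("inf")  # never observed: strength undefined, rank last
        else:
            strengths = {t: per_type[t] / total - prior[t] for t in types}
            spread = max(abs(s) for s in strengths.values())
        notes = []
        notes.append("occurs in all four types" if in_all else "missing from some types")
        notes.append(f"total occurrences {total}")
        notes.append(
            "strength spread undefined (never observed)"
            if total == 0
            else f"attribute-strength spread {spread:.3f}"
        )
        candidates.append(
            RootCandidate(code, per_type, total, in_all, spread, "; ".join(notes))
        )

    if not any(c.in_all_types for c in candidates):
        warnings.warn(
            "no behavior occurs in all four accident types; ranking by "
            "occurrence count and attribute-strength spread only",
            stacklevel=2,
        )
        key = lambda c: (-c.total, c.strength_spread, behavior_index(c.code))
    else:
        key = lambda c: (
            not c.in_all_types,
            c.strength_spread,
            -c.total,
            behavior_index(c.code),
        )
    ranked = sorted(candidates, key=key)
    return ranked[:top] if top is not None else ranked
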