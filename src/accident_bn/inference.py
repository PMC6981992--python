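"""Exact forward reasoning: accident-type posteriors under behavior evidence.

Forward reasoning answers "given that these unsafe behaviors were observed,
how likely is each accident type?":

    P(Y_k | B_c) = P(Y_k, B_c) / P(B_c)

with the evidence set ``B_c`` a collection of behavior observations
(typically ``Yes``).  Because the behaviors form a tree given the class,
the likelihood P(B_c | Y_k) is collected exactly by a single sum-product
pass over the tree; unobserved behaviors marginalize out.  A brute-force
joint-enumeration oracle is provided for cross-checking on small models.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tan_model import CLASS_NODE, TanModel, _state01, _topological_order

__all__ = [
    "as_evidence",
    "class_posterior",
    "sequential_prediction",
    "attribute_strength",
    "brute_force_posterior",
    "PredictionTrajectory",
]

#: Enumeration bound for the brute-force oracle.
_MAX_BRUTE_FORCE_FEATURES = 14


def as_evidence(
    observations: Sequence[str | tuple[str, object]] | Mapping[str, object],
) -> dict[str, int]:
    """Normalize evidence to ``{code: 0|1}``; bare codes mean ``Yes``.

    Raises on a code observed twice (contradictory or redundant evidence).
    """
    if isinstance(observations, Mapping):
        items = [(code, _state01(state)) for code, state in observations.items()]
    else:
        items = []
        for obs in observations:
            if isinstance(obs, str):
                items.append((obs, 1))
            else:
                code, state = obs
                items.append((code, _state01(state)))
    evidence: dict[str, int] = {}
    for code, state in items:
        if code in evidence:
            raise ValueError(f"behavior {code} observed twice in the evidence set")
        evidence[code] = state
    return evidence


def _check_codes(model: TanModel, evidence: Mapping[str, int]) -> None:
    unknown = set(evidence) - set(model.features)
    if unknown:
        raise KeyError(f"evidence code(s) not in model: {sorted(unknown)}")


def _class_likelihoods(model: TanModel, evidence: Mapping[str, int]) -> np.ndarray:
    """P(evidence | Y=k) for every class k, by sum-product over the tree."""
    structure = model.structure
    children = structure.children()
    K = len(model.class_states)

    # visit in reverse topological order so child messages exist before parents
    order = _topological_order(structure)
    # message[f][k, ps] = P(evidence in f's subtree | Y=k, parent state ps)
    message: dict[str, np.ndarray] = {}
    for f in reversed(order):
        cpt = model.cpts[f].table  # root: (2,K); child: (2,K,ps)
        parent = structure.parents[f]
        table = cpt[:, :, None] if parent is None else cpt  # (2, K, n_ps)
        states = [evidence[f]] if f in evidence else [0, 1]
        msg = np.zeros((K, table.shape[2]))
        for s in states:
            term = table[s]  # (K, n_ps)
            for ch in children[f]:
                term = term * message[ch][:, s][:, None]
            msg += term
        message[f] = msg
    return message[structure.root][:, 0]


def class_posterior(
    model: TanModel,
    evidence: Mapping[str, int] | Sequence | None = None,
) -> pd.Series:
    """Exact accident-type posterior P(Y | evidence) as a Series over classes.

    Empty evidence returns the (smoothed) class prior.
    """
    ev = as_evidence(evidence) if evidence else {}
    _check_codes(model, ev)
    weights = model.class_prior * _class_likelihoods(model, ev)
    total = weights.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    return pd.Series(weights / total, index=list(model.class_states), name="posterior")


@dataclass(frozen=True)
class PredictionTrajectory:
    """Posterior after each evidence insertion, in input order."""

    observations: tuple[tuple[str, int], ...]
    posteriors: tuple[pd.Series, ...]
    prior: pd.Series

    @property
    def final(self) -> pd.Series:
        return self.posteriors[-1] if self.posteriors else self.prior

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        """One row per evidence prefix (first row: no evidence)."""
        labels = ["No evidence"]
        rows = [self.prior]
        parts: list[str] = []
        for (code, state), post in zip(self.observations, self.posteriors):
            parts.append(f"P({code})={state}")
            labels.append(", ".join(parts))
            rows.append(post)
        frame = pd.DataFrame(rows, index=pd.Index(labels, name="evidence"))
        if percent:
            frame = (frame * 100).round(1)
        return frame


def sequential_prediction(
    model: TanModel,
    ordered_evidence: Sequence[str | tuple[str, object]],
) -> PredictionTrajectory:
    """Accumulate evidence one behavior at a time, recording each posterior.

    The final posterior equals ``class_posterior`` on the full set; the path
    (growth rate per step) is what depends on the behaviors' accident
    attributes, the final value does not depend on input order.
    """
    full = as_evidence(ordered_evidence)  # validates duplicates up front
    _check_codes(model, full)
    running: dict[str, int] = {}
    posteriors = []
    observations = []
    for code, state in full.items():
        running[code] = state
        observations.append((code, state))
        posteriors.append(class_posterior(model, dict(running)))
    return PredictionTrajectory(
        observations=tuple(observations),
        posteriors=tuple(posteriors),
        prior=class_posterior(model, {}),
    )


def attribute_strength(
    model: TanModel,
    behavior: str,
    accident_type: str | None = None,
    context: Mapping[str, int] | Sequence | None = None,
) -> float | pd.Series:
    """Increment in an accident type's posterior when *behavior* is observed.

    ``P(Y_k | context + {behavior=Yes}) - P(Y_k | context)``; with
    *accident_type* omitted the signed increment is reported for every type.
    """
    ctx = as_evidence(context) if context else {}
    if behavior in ctx:
        raise ValueError(f"behavior {behavior} is already in the evidence context")
    base = class_posterior(model, ctx)
    with_b = class_posterior(model, {**ctx, behavior: 1})
    delta = with_b - base
    if accident_type is None:
        return delta
    return float(delta[accident_type])


def brute_force_posterior(
    model: TanModel,
    query: str,
    evidence: Mapping[str, int] | Sequence | None = None,
) -> pd.Series:
    """Posterior of *query* by exhaustive enumeration of the joint.

    Test oracle only — enumerates all class x behavior assignments, so it
    refuses models with more than 14 behaviors.
    """
    m = len(model.features)
    if m > _MAX_BRUTE_FORCE_FEATURES:
        raise ValueError(
            f"brute-force enumeration limited to {_MAX_BRUTE_FORCE_FEATURES} "
            f"behaviors, model has {m}"
        )
    ev = as_evidence(evidence) if evidence else {}
    _check_codes(model, ev)
    K = len(model.class_states)
    pos = {f: i for i, f in enumerate(model.features)}

    assignments = np.array(list(itertools.product((0, 1), repeat=m)), dtype=int)
    joint = np.tile(model.class_prior[:, None], (1, len(assignments)))
    for f in model.features:
        col = assignments[:, pos[f]]
        parent = model.structure.parents[f]
        table = model.cpts[f].table
        if parent is None:
            joint *= table[col, :].T  # (K, n_assign)
        else:
            pcol = assignments[:, pos[parent]]
            joint *= np.stack([table[col, k, pcol] for k in range(K)])
    for code, state in ev.items():
        joint *= (assignments[:, pos[code]] == state)[None, :]

    if query == CLASS_NODE:
        weights = joint.sum(axis=1)
        index = list(model.class_states)
    elif query in model.features:
        col = assignments[:, pos[query]]
        weights = np.array([joint[:, col == s].sum() for s in (0, 1)])
        index = ["No", "Yes"]
    else:
        raise KeyError(f"unknown query variable {query!r}")
    total = weights.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    return pd.Series(weights / total, index=index, name="posterior")
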