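"""Synthetic accident datasets from a known ground-truth network.

The real 287-case matrix behind the source study is not public, so learning,
inference and diagnosis are validated against data sampled from a fully
specified tree-augmented model.  The generator's defaults mirror the study's
published marginals — 287 cases split 191/39/33/24 across fall, collapse,
struck-by and lifting, 37 binary behavior indicators, sparse occurrence
rates — while the co-occurrence structure (the feature tree and the planted
per-type signature behaviors) is necessarily invented; see docs/methods.md.

Planted triples ``(behavior, type, lift)`` force a marginal separation
``P(B=Yes | Y=k) - P(B=Yes | Y!=k) >= lift``, which both pins down the
expected critical group per accident type and fixes the expected ordering
of attribute strengths.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import ACCIDENT_TYPES, BehaviorChain, CaseMatrix, behavior_index
from .tan_model import CLASS_NODE, Cpt, SmoothingPolicy, TanModel, TanStructure

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "DEFAULT_PLANTED",
    "build_ground_truth",
    "sample_cases",
    "sample_chains",
]

logger = logging.getLogger(__name__)

# Published-shape class mix: 191 fall, 39 collapse, 33 struck-by, 24 lifting.
_DEFAULT_CLASS_PROBS = {"S": 33 / 287, "C": 39 / 287, "F": 191 / 287, "L": 24 / 287}

#: Default planted per-type signature behaviors (code, accident type, lift).
#: Codes follow the study's worked examples (PPE and edge-protection lapses
#: drive falls, machine-operation lapses drive struck-by/lifting, formwork
#: lapses drive collapses); the lifts are invented.
DEFAULT_PLANTED: tuple[tuple[str, str, float], ...] = (
    ("B12", "F", 0.40),
    ("B11", "F", 0.30),
    ("B24", "F", 0.12),
    ("B13", "F", 0.12),
    ("B6", "S", 0.25),
    ("B1", "S", 0.15),
    ("B17", "C", 0.25),
    ("B16", "C", 0.18),
    ("B18", "L", 0.30),
    ("B10", "L", 0.22),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and ground-truth parameters of a synthetic accident dataset.

    Parameters
    ----------
    seed
        Mandatory; every sampling decision derives from it.
    n_cases, class_probs, n_behaviors
        Dataset shape; defaults are the published study shape.
    tree_edges
        Explicit feature-tree edges, or None for a seeded random tree.
    base_rate
        Background P(B=Yes) per behavior and class (sparse by default).
    rate_concentration
        If set, per-behavior background rates are drawn from a Beta
        distribution with this concentration around ``base_rate``.
    parent_coupling
        Strength of the co-occurrence dependence along tree edges for
        non-planted behaviors (0 = class-conditionally independent).
    planted
        ``(behavior, type, lift)`` triples; planted behaviors depend on the
        class only, so the lift holds exactly in the marginal.
    explicit_cpts
        Full override: mapping node -> table, echoed into the model as-is.
    """

    seed: int
    n_cases: int = 287
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROBS)
    )
    n_behaviors: int = 37
    tree_edges: tuple[tuple[str, str], ...] | None = None
    base_rate: float = 0.08
    rate_concentration: float | None = None
    parent_coupling: float = 0.10
    planted: tuple[tuple[str, str, float], ...] = DEFAULT_PLANTED
    explicit_cpts: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must lie in (0, 1)")
        for code, t, lift in self.planted:
            if t not in self.class_probs:
                raise ValueError(f"planted triple ({code}, {t}, {lift}): unknown type")
            if not 0 < lift < 1:
                raise ValueError(f"planted triple ({code}, {t}, {lift}): bad lift")


@dataclass(frozen=True)
class GroundTruth:
    """The generating model plus the planted critical set per accident type."""

    model: TanModel
    planted_sets: Mapping[str, tuple[str, ...]]
    config: GeneratorConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": json.loads(self.model.to_json()),
                "planted_sets": {t: list(v) for t, v in self.planted_sets.items()},
                "config": _config_doc(self.config),
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _config_doc(config: GeneratorConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["class_probs"] = dict(config.class_probs)
    doc["planted"] = [list(t) for t in config.planted]
    if config.tree_edges is not None:
        doc["tree_edges"] = [list(e) for e in config.tree_edges]
    if config.explicit_cpts is not None:
        doc["explicit_cpts"] = {
            k: np.asarray(v).tolist() for k, v in config.explicit_cpts.items()
        }
    return doc


def _random_tree(features: Sequence[str], rng: np.random.Generator) -> dict[str, str | None]:
    """Random recursive tree: each node attaches to a uniform earlier node."""
    parents: dict[str, str | None] = {features[0]: None}
    for k in range(1, len(features)):
        parents[features[k]] = features[int(rng.integers(0, k))]
    return parents


def _parents_from_edges(
    features: Sequence[str], edges: Sequence[tuple[str, str]]
) -> dict[str, str | None]:
    adjacency: dict[str, list[str]] = {f: [] for f in features}
    for u, v in edges:
        adjacency[u].append(v)
        adjacency[v].append(u)
    root = features[0]
    parents: dict[str, str | None] = {root: None}
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in sorted(adjacency[node], key=behavior_index):
            if nb not in parents:
                parents[nb] = node
                stack.append(nb)
    if len(parents) != len(features):
        raise ValueError("tree_edges do not connect all behaviors")
    return parents


def build_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Construct the generating model; deterministic given the config seed.

    Raises ``ValueError`` naming the offending triple if a planted lift is
    not achieved by the finished CPTs (e.g. two planted types on one
    behavior crowding each other out).
    """
    rng = np.random.default_rng(config.seed)
    features = tuple(f"B{k}" for k in range(1, config.n_behaviors + 1))
    class_states = tuple(t for t in ACCIDENT_TYPES if t in config.class_probs)
    prior = np.array([config.class_probs[t] for t in class_states])
    K = len(class_states)

    if config.tree_edges is not None:
        parents = _parents_from_edges(features, config.tree_edges)
    else:
        parents = _random_tree(features, rng)
    structure = TanStructure(
        class_states=class_states,
        features=features,
        parents=parents,
        root=features[0],
    )

    lifts: dict[str, dict[str, float]] = {}
    for code, t, lift in config.planted:
        if code not in structure.features:
            raise ValueError(f"planted behavior {code} outside B1..B{config.n_behaviors}")
        lifts.setdefault(code, {})[t] = lift

    cpts: dict[str, Cpt] = {CLASS_NODE: Cpt(CLASS_NODE, (), prior)}
    for f in features:
        if config.explicit_cpts is not None and f in config.explicit_cpts:
            table = np.asarray(config.explicit_cpts[f], dtype=float)
            parent = parents[f]
            cpts[f] = Cpt(f, (CLASS_NODE,) if parent is None else (CLASS_NODE, parent), table)
            continue
        if config.rate_concentration is not None:
            c = config.rate_concentration
            r = float(
                rng.beta(c * config.base_rate, c * (1 - config.base_rate))
            )
            r = min(max(r, 0.01), 0.99)
        else:
            r = config.base_rate
        p_yes = np.full(K, r)
        for t, lift in lifts.get(f, {}).items():
            k = class_states.index(t)
            p_yes[k] = r + lift
        if np.any(p_yes >= 1) or np.any(p_yes <= 0):
            raise ValueError(f"behavior {f}: planted lifts push P(Yes|Y) outside (0,1)")
        parent = parents[f]
        if parent is None:
            table = np.stack([1 - p_yes, p_yes])  # (2, K)
            cpts[f] = Cpt(f, (CLASS_NODE,), table)
        else:
            if f in lifts:
                hi = lo = p_yes  # planted behaviors depend on the class only
            else:
                cpl = config.parent_coupling
                hi = np.clip(p_yes + cpl * (1 - p_yes), 1e-6, 1 - 1e-6)
                lo = np.clip(p_yes * (1 - cpl), 1e-6, 1 - 1e-6)
            table = np.empty((2, K, 2))
            table[1, :, 0] = lo
            table[1, :, 1] = hi
            table[0] = 1 - table[1]
            cpts[f] = Cpt(f, (CLASS_NODE, parent), table)

    model = TanModel(
        structure,
        cpts,
        SmoothingPolicy(0.0),
        {"source": "synthetic ground truth", "seed": config.seed},
    )

    # verify every planted lift against the finished model's marginals
    marginals = model.feature_marginals()
    for code, t, lift in config.planted:
        k = class_states.index(t)
        p_in = marginals[code][k, 1]
        others = np.delete(np.arange(K), k)
        p_out = float(
            (prior[others] @ marginals[code][others, 1]) / prior[others].sum()
        )
        if p_in - p_out < lift - 1e-9:
            raise ValueError(
                f"planted triple ({code}, {t}, {lift}) infeasible: achieved "
                f"separation {p_in - p_out:.4f}"
            )

    planted_sets: dict[str, tuple[str, ...]] = {}
    for t in class_states:
        members = [(code, lifts[code][t]) for code in lifts if t in lifts[code]]
        members.sort(key=lambda cl: (-cl[1], behavior_index(cl[0])))
        planted_sets[t] = tuple(code for code, _ in members)

    return GroundTruth(model=model, planted_sets=planted_sets, config=config)


def sample_cases(truth: GroundTruth, n: int, seed: int) -> CaseMatrix:
    """Ancestral sampling: class from the prior, behaviors down the tree."""
    if n < 1:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(seed)
    model = truth.model
    K = len(model.class_states)
    y = rng.choice(K, size=n, p=model.class_prior)

    from .tan_model import _topological_order

    values: dict[str, np.ndarray] = {}
    for f in _topological_order(model.structure):
        table = model.cpts[f].table
        parent = model.structure.parents[f]
        if parent is None:
            p = table[1, y]
        else:
            p = table[1, y, values[parent]]
        values[f] = (rng.random(n) < p).astype(int)

    index = pd.Index([f"A{i + 1:05d}" for i in range(n)], name="case_id")
    data = pd.DataFrame(
        {f: values[f].astype(bool) for f in model.features}, index=index
    )
    types = pd.Series([model.class_states[k] for k in y], index=index)
    return CaseMatrix(data, types)


def sample_chains(matrix: CaseMatrix, seed: int) -> list[BehaviorChain]:
    """Impose a uniformly random time order on each case's Yes behaviors.

    Time order carries no probability in the model, so no ordering model is
    fitted.  Rows with fewer than two Yes entries cannot form a chain and
    are skipped (logged).
    """
    rng = np.random.default_rng(seed)
    chains: list[BehaviorChain] = []
    skipped = 0
    for case_id in matrix.data.index:
        codes = [c for c in matrix.behaviors if matrix.data.at[case_id, c]]
        if len(codes) < 2:
            skipped += 1
            logger.info("case %s has %d Yes behavior(s); no chain", case_id, len(codes))
            continue
        order = rng.permutation(len(codes))
        chains.append(
            BehaviorChain(
                case_id,
                str(matrix.accident_types[case_id]),
                tuple(codes[i] for i in order),
            )
        )
    if skipped:
        logger.info("skipped %d case(s) with fewer than 2 behaviors", skipped)
    return chains
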