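"""Tree-augmented naive Bayes model over binary unsafe-behavior indicators.

The network has one 4-state class node (the accident type) and one binary
node per unsafe behavior.  Every behavior node has the class as a parent
plus at most one other behavior; the behavior-behavior edges form a spanning
tree chosen by maximizing class-conditional mutual information (the
Chow-Liu criterion applied conditionally on the class).  Conditional
probability tables are estimated from Yes/No counts with a small-cell
pseudocount adjustment so rare behavior/accident combinations keep nonzero
probability.

Array conventions: behavior states are indexed ``0 = No, 1 = Yes``; class
states follow ``TanStructure.class_states``.  A behavior CPT with a tree
parent has shape ``(2, K, 2)`` indexed ``[child_state, class, parent_state]``;
the tree root's CPT has shape ``(2, K)``; the class prior has shape ``(K,)``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import ACCIDENT_TYPES, CaseMatrix, behavior_index

__all__ = [
    "CLASS_NODE",
    "SmoothingPolicy",
    "TanStructure",
    "Cpt",
    "TanModel",
    "RootedView",
    "conditional_mutual_information",
    "learn_tan_structure",
    "estimate_cpts",
    "fit_tan",
    "joint_probability",
    "reroot",
]

#: Name of the accident-type (class) node.
CLASS_NODE = "accident_type"


@dataclass(frozen=True)
class SmoothingPolicy:
    """Pseudocount added to every count cell (the small-cell adjustment)."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("smoothing pseudocount must be >= 0")


def _state01(value) -> int:
    """Normalize a behavior state (bool / 0 / 1 / 'Yes' / 'No') to 0 or 1."""
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("yes", "y", "true", "1"):
            return 1
        if v in ("no", "n", "false", "0"):
            return 0
        raise ValueError(f"unrecognized behavior state {value!r}")
    return int(bool(value))


def _class_indices(matrix: CaseMatrix, class_states: Sequence[str]) -> np.ndarray:
    lookup = {s: k for k, s in enumerate(class_states)}
    try:
        return matrix.accident_types.map(lookup).to_numpy(dtype=int)
    except (TypeError, ValueError):
        unknown = sorted(set(matrix.accident_types) - set(class_states))
        raise ValueError(f"cases with accident type(s) {unknown} not in model classes")


def _observed_classes(matrix: CaseMatrix) -> tuple[str, ...]:
    counts = matrix.class_counts()
    missing = [t for t in ACCIDENT_TYPES if t not in counts]
    if missing:
        warnings.warn(
            f"accident type(s) {', '.join(missing)} have no cases and are "
            "dropped from the model",
            stacklevel=3,
        )
    return tuple(counts)


def conditional_mutual_information(
    matrix: CaseMatrix,
    i: str,
    j: str,
    smoothing: SmoothingPolicy = SmoothingPolicy(),
) -> float:
    """Class-conditional mutual information I(B_i; B_j | Y) in nats.

    Probabilities are the smoothed empirical frequencies of the full
    (class x B_i x B_j) contingency table (pseudocount ``alpha`` per cell);
    the marginals entering the ratio are derived from that same smoothed
    joint, so independence in counts gives exactly zero at ``alpha = 0``.
    Tiny negative rounding noise is clamped to zero.
    """
    if i == j:
        raise ValueError(f"conditional MI needs two distinct behaviors, got {i} twice")
    if matrix.n_cases == 0:
        raise ValueError("cannot compute conditional MI on an empty matrix")
    class_states = tuple(matrix.class_counts())
    y = _class_indices(matrix, class_states)
    a = matrix.data[i].to_numpy(dtype=int)
    b = matrix.data[j].to_numpy(dtype=int)
    K = len(class_states)
    counts = np.zeros((K, 2, 2))
    np.add.at(counts, (y, a, b), 1.0)
    p = (counts + smoothing.alpha) / (counts.sum() + smoothing.alpha * counts.size)
    py = p.sum(axis=(1, 2), keepdims=True)
    pa = p.sum(axis=2, keepdims=True)  # P(B_i, Y)
    pb = p.sum(axis=1, keepdims=True)  # P(B_j, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log(p * py) - np.log(pa * pb)
    # cells with zero probability contribute nothing (and log there is -inf)
    value = float(np.sum(p * np.where(p > 0, logratio, 0.0)))
    return max(value, 0.0)


@dataclass(frozen=True)
class TanStructure:
    """Class node + feature spanning tree with a chosen orientation root.

    ``parents`` maps each behavior to its tree parent (``None`` for the
    orientation root); every behavior additionally has the class node as a
    parent, implicitly.
    """

    class_states: tuple[str, ...]
    features: tuple[str, ...]
    parents: Mapping[str, str | None]
    root: str
    edge_weights: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.parents) != set(self.features):
            raise ValueError("parent map must cover exactly the features")
        roots = [f for f, p in self.parents.items() if p is None]
        if roots != [self.root]:
            raise ValueError("exactly one feature (the root) may lack a tree parent")
        # acyclicity: walking up from every node must terminate at the root
        for f in self.features:
            seen = set()
            node: str | None = f
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in feature tree through {node}")
                seen.add(node)
                node = self.parents[node]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """Undirected tree edges as (parent, child) pairs in the orientation."""
        return tuple((p, f) for f, p in self.parents.items() if p is not None)

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {f: [] for f in self.features}
        for f, p in self.parents.items():
            if p is not None:
                out[p].append(f)
        return out


@dataclass(frozen=True)
class Cpt:
    """One node's conditional probability table.

    ``parents`` lists the conditioning variables in table axis order after
    the child axis; see the module docstring for shapes.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "table", np.asarray(self.table, dtype=float))
        sums = self.table.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"CPT for {self.child}: columns must sum to 1")
        if np.any(self.table < 0):
            raise ValueError(f"CPT for {self.child}: negative entries")


@dataclass(frozen=True)
class TanModel:
    """A fitted (or constructed) tree-augmented naive Bayes model."""

    structure: TanStructure
    cpts: Mapping[str, Cpt]
    smoothing: SmoothingPolicy
    training_summary: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(self.structure.features) | {CLASS_NODE}
        if set(self.cpts) != expected:
            raise ValueError("model needs one CPT per feature plus the class prior")

    @property
    def class_states(self) -> tuple[str, ...]:
        return self.structure.class_states

    @property
    def features(self) -> tuple[str, ...]:
        return self.structure.features

    @property
    def class_prior(self) -> np.ndarray:
        return self.cpts[CLASS_NODE].table

    def class_index(self, state: str) -> int:
        try:
            return self.class_states.index(state)
        except ValueError:
            raise KeyError(f"unknown accident type {state!r}") from None

    def feature_marginals(self) -> dict[str, np.ndarray]:
        """Per-class behavior marginals P(B | Y) as (K, 2) arrays."""
        order = _topological_order(self.structure)
        out: dict[str, np.ndarray] = {}
        for f in order:
            cpt = self.cpts[f]
            parent = self.structure.parents[f]
            if parent is None:
                out[f] = cpt.table.T  # (K, 2)
            else:
                # P(b|y) = sum_ps P(ps|y) P(b|y,ps)
                out[f] = np.einsum("kp,bkp->kb", out[parent], cpt.table)
        return out

    def joint_probability(self, assignment: Mapping[str, object]) -> float:
        """Product of CPT entries for a full assignment of class + behaviors."""
        return joint_probability(self, assignment)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "class_node": CLASS_NODE,
            "structure": {
                "class_states": list(self.class_states),
                "features": list(self.features),
                "parents": {f: self.structure.parents[f] for f in self.features},
                "root": self.structure.root,
                "edge_weights": [
                    [u, v, w] for (u, v), w in self.structure.edge_weights.items()
                ],
            },
            "cpts": {
                node: {
                    "parents": list(cpt.parents),
                    "table": cpt.table.tolist(),
                }
                for node, cpt in self.cpts.items()
            },
            "smoothing": {"alpha": self.smoothing.alpha},
            "training_summary": dict(self.training_summary),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TanModel":
        doc = json.loads(text)
        s = doc["structure"]
        structure = TanStructure(
            class_states=tuple(s["class_states"]),
            features=tuple(s["features"]),
            parents=dict(s["parents"]),
            root=s["root"],
            edge_weights={(u, v): w for u, v, w in s.get("edge_weights", [])},
        )
        cpts = {
            node: Cpt(node, tuple(spec["parents"]), np.array(spec["table"]))
            for node, spec in doc["cpts"].items()
        }
        return cls(
            structure=structure,
            cpts=cpts,
            smoothing=SmoothingPolicy(**doc["smoothing"]),
            training_summary=doc.get("training_summary", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TanModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _topological_order(structure: TanStructure) -> list[str]:
    """Features in root-first order along the tree orientation."""
    children = structure.children()
    order: list[str] = []
    stack = [structure.root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    return order


def learn_tan_structure(
    matrix: CaseMatrix,
    smoothing: SmoothingPolicy = SmoothingPolicy(),
    orientation_root: str = "auto",
) -> TanStructure:
    """Learn the behavior spanning tree by conditional mutual information.

    All behavior pairs are scored with I(B_i; B_j | Y); a maximum-weight
    spanning tree is built by Kruskal's algorithm with deterministic
    tie-breaking (higher weight first, then lower behavior-code indices),
    then oriented away from *orientation_root* (``"auto"`` picks the
    lowest-numbered behavior).
    """
    features = matrix.behaviors
    if len(features) < 2:
        raise ValueError("need at least 2 behaviors to build a feature tree")
    class_states = _observed_classes(matrix)
    if not class_states:
        raise ValueError("matrix has no cases")

    idx = {f: behavior_index(f) for f in features}
    scored = []
    for a_pos, fi in enumerate(features):
        for fj in features[a_pos + 1 :]:
            u, v = sorted((fi, fj), key=idx.get)
            w = conditional_mutual_information(matrix, u, v, smoothing)
            scored.append((u, v, w))
    scored.sort(key=lambda e: (-e[2], idx[e[0]], idx[e[1]]))

    # Kruskal with union-find; the complete graph guarantees a spanning tree.
    leader = {f: f for f in features}

    def find(f: str) -> str:
        while leader[f] != f:
            leader[f] = leader[leader[f]]
            f = leader[f]
        return f

    tree_edges: dict[tuple[str, str], float] = {}
    for u, v, w in scored:
        ru, rv = find(u), find(v)
        if ru != rv:
            leader[ru] = rv
            tree_edges[(u, v)] = w
            if len(tree_edges) == len(features) - 1:
                break

    if orientation_root == "auto":
        orientation_root = min(features, key=idx.get)
    elif orientation_root not in features:
        raise KeyError(f"orientation root {orientation_root} not among behaviors")

    adjacency: dict[str, list[str]] = {f: [] for f in features}
    for u, v in tree_edges:
        adjacency[u].append(v)
        adjacency[v].append(u)
    parents: dict[str, str | None] = {orientation_root: None}
    stack = [orientation_root]
    while stack:
        node = stack.pop()
        for nb in sorted(adjacency[node], key=idx.get):
            if nb not in parents:
                parents[nb] = node
                stack.append(nb)

    return TanStructure(
        class_states=class_states,
        features=features,
        parents=parents,
        root=orientation_root,
        edge_weights=tree_edges,
    )


def estimate_cpts(
    matrix: CaseMatrix,
    structure: TanStructure,
    smoothing: SmoothingPolicy = SmoothingPolicy(),
) -> TanModel:
    """Estimate all CPTs from counts with the pseudocount adjustment.

    Every cell is ``(count + alpha) / (sum of child counts + alpha * 2)``
    (``* K`` for the class prior), so any ``alpha > 0`` keeps all cells
    strictly inside (0, 1).
    """
    missing = set(structure.features) - set(matrix.behaviors)
    if missing:
        raise ValueError(f"matrix lacks behavior column(s): {sorted(missing)}")
    alpha = smoothing.alpha
    K = len(structure.class_states)
    y = _class_indices(matrix, structure.class_states)
    n = matrix.n_cases

    class_counts = np.bincount(y, minlength=K).astype(float)
    prior = (class_counts + alpha) / (n + alpha * K)
    cpts: dict[str, Cpt] = {CLASS_NODE: Cpt(CLASS_NODE, (), prior)}

    def smoothed(counts: np.ndarray) -> np.ndarray:
        denom = counts.sum(axis=0, keepdims=True) + 2 * alpha
        # a parent configuration never observed at alpha=0 gets a uniform cell
        with np.errstate(invalid="ignore", divide="ignore"):
            table = (counts + alpha) / denom
        return np.where(denom > 0, table, 0.5)

    cols = {f: matrix.data[f].to_numpy(dtype=int) for f in structure.features}
    for f in structure.features:
        parent = structure.parents[f]
        if parent is None:
            counts = np.zeros((2, K))
            np.add.at(counts, (cols[f], y), 1.0)
            cpts[f] = Cpt(f, (CLASS_NODE,), smoothed(counts))
        else:
            counts = np.zeros((2, K, 2))
            np.add.at(counts, (cols[f], y, cols[parent]), 1.0)
            cpts[f] = Cpt(f, (CLASS_NODE, parent), smoothed(counts))

    summary = {
        "n_cases": n,
        "class_counts": {s: int(c) for s, c in zip(structure.class_states, class_counts)},
    }
    return TanModel(structure, cpts, smoothing, summary)


def fit_tan(
    matrix: CaseMatrix,
    smoothing: SmoothingPolicy = SmoothingPolicy(),
    orientation_root: str = "auto",
) -> TanModel:
    """Convenience: learn the structure and estimate its CPTs in one call."""
    structure = learn_tan_structure(matrix, smoothing, orientation_root)
    return estimate_cpts(matrix, structure, smoothing)


def joint_probability(model: TanModel, assignment: Mapping[str, object]) -> float:
    """P(class state, all behavior states): product of the relevant CPT entries."""
    missing = ({CLASS_NODE} | set(model.features)) - set(assignment)
    if missing:
        raise KeyError(f"assignment missing variable(s): {sorted(missing)}")
    k = model.class_index(str(assignment[CLASS_NODE]))
    prob = float(model.class_prior[k])
    for f in model.features:
        s = _state01(assignment[f])
        parent = model.structure.parents[f]
        if parent is None:
            prob *= float(model.cpts[f].table[s, k])
        else:
            ps = _state01(assignment[parent])
            prob *= float(model.cpts[f].table[s, k, ps])
    return prob


@dataclass(frozen=True)
class RootedView:
    """The same joint distribution redrawn with a different behavior as root.

    ``class_given_root`` is the properly normalized conditional distribution
    of the accident type given the root behavior's state (rows Yes/No sum
    to 1); ``model`` carries the re-derived CPTs for the new orientation.
    """

    model: TanModel
    root: str
    class_given_root: pd.DataFrame


def reroot(model: TanModel, new_root: str) -> RootedView:
    """Re-express the model with *new_root* as the feature-tree root.

    Reversed edges get their CPTs re-derived from the model's own joint
    (per-class Bayes inversion on the adjacent-pair distribution), so the
    joint over all nodes is unchanged up to floating-point rounding.
    """
    if new_root not in model.features:
        raise KeyError(f"unknown behavior code {new_root}")
    structure = model.structure
    marginals = model.feature_marginals()  # P(B|Y), (K, 2) each

    # new orientation: BFS from new_root over the undirected tree
    adjacency: dict[str, list[str]] = {f: [] for f in structure.features}
    for f, p in structure.parents.items():
        if p is not None:
            adjacency[f].append(p)
            adjacency[p].append(f)
    idx = {f: behavior_index(f) for f in structure.features}
    new_parents: dict[str, str | None] = {new_root: None}
    stack = [new_root]
    while stack:
        node = stack.pop()
        for nb in sorted(adjacency[node], key=idx.get):
            if nb not in new_parents:
                new_parents[nb] = node
                stack.append(nb)

    cpts: dict[str, Cpt] = {CLASS_NODE: model.cpts[CLASS_NODE]}
    cpts[new_root] = Cpt(new_root, (CLASS_NODE,), marginals[new_root].T)
    for f, p in new_parents.items():
        if p is None:
            continue
        if structure.parents[f] == p:
            cpts[f] = model.cpts[f]  # orientation unchanged on this edge
        else:
            # original edge was f -> p; invert per class with Bayes' rule:
            # joint[p_state, y, f_state] = P(f_state|y) * P(p_state|y,f_state)
            assert structure.parents[p] == f
            joint = model.cpts[p].table * marginals[f][None, :, :]
            flipped = np.transpose(joint, (2, 1, 0))  # (f_state, y, p_state)
            denom = flipped.sum(axis=0, keepdims=True)
            cpts[f] = Cpt(f, (CLASS_NODE, p), flipped / denom)

    new_structure = TanStructure(
        class_states=structure.class_states,
        features=structure.features,
        parents=new_parents,
        root=new_root,
        edge_weights=structure.edge_weights,
    )
    view_model = TanModel(new_structure, cpts, model.smoothing, model.training_summary)

    # P(Y | root state), normalized over classes; rows Yes then No
    prior = model.class_prior
    joint_ry = marginals[new_root] * prior[:, None]  # (K, 2): P(y, root_state)
    cond = joint_ry / joint_ry.sum(axis=0, keepdims=True)  # P(y | root_state)
    table = pd.DataFrame(
        {"Yes": cond[:, 1], "No": cond[:, 0]}, index=list(model.class_states)
    ).T
    return RootedView(model=view_model, root=new_root, class_given_root=table)
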