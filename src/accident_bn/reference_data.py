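"""Published summary tallies from the source accident study, as inputs.

The study's case-level data were never released; what it prints are summary
counts: the class tallies of the 287 retained cases and a per-type
occurrence table for eleven frequently observed behaviors.  Those tallies
are inputs to the desk-check computations (smoothed class prior, root-node
occurrence rate, diagnosis eligibility), so they live here as package data.

``counts_matrix`` rebuilds a deterministic case matrix whose per-type
marginal tallies reproduce the published table for the chosen behaviors.
Only marginals are published, so the within-row co-occurrence pattern is a
synthetic reconstruction (each type's Yes cells are packed into its leading
rows); any statistic depending on co-occurrence is NOT faithful to the
original data and must not be read off this matrix.
"""
from __future__ import annotations

import pandas as pd

from .catalog_io import ACCIDENT_TYPES, CaseMatrix

__all__ = ["CLASS_COUNTS", "OCCURRENCE_COUNTS", "occurrence_frame", "counts_matrix"]

#: Retained accident cases per type (n = 287).
CLASS_COUNTS: dict[str, int] = {"F": 191, "C": 39, "S": 33, "L": 24}

#: Per-type occurrence counts for the eleven behaviors the study tabulates.
OCCURRENCE_COUNTS: dict[str, dict[str, int]] = {
    "B12": {"F": 99, "C": 5, "S": 1, "L": 4},
    "B11": {"F": 73, "C": 2, "S": 4, "L": 1},
    "B14": {"F": 42, "C": 8, "S": 11, "L": 11},
    "B6": {"F": 13, "C": 2, "S": 10, "L": 12},
    "B24": {"F": 30, "C": 2, "S": 3, "L": 0},
    "B13": {"F": 32, "C": 2, "S": 0, "L": 0},
    "B1": {"F": 14, "C": 0, "S": 9, "L": 5},
    "B31": {"F": 22, "C": 2, "S": 3, "L": 1},
    "B9": {"F": 16, "C": 0, "S": 4, "L": 3},
    "B16": {"F": 11, "C": 9, "S": 3, "L": 0},
    "B18": {"F": 10, "C": 0, "S": 2, "L": 9},
}


def occurrence_frame() -> pd.DataFrame:
    """The occurrence table as a frame (rows = accident types, canonical order)."""
    frame = pd.DataFrame(OCCURRENCE_COUNTS)
    return frame.reindex([t for t in ACCIDENT_TYPES if t in frame.index])


def counts_matrix(behaviors: tuple[str, ...] | None = None) -> CaseMatrix:
    """Deterministic case matrix reproducing the published per-type tallies.

    Rows are grouped by accident type (class counts from ``CLASS_COUNTS``);
    for each requested behavior, the published number of Yes cells is packed
    into the leading rows of each type block.  Marginals are exact;
    co-occurrence is synthetic (see module docstring).
    """
    if behaviors is None:
        behaviors = tuple(OCCURRENCE_COUNTS)
    unknown = [b for b in behaviors if b not in OCCURRENCE_COUNTS]
    if unknown:
        raise KeyError(f"no published tallies for behavior(s): {unknown}")

    case_ids: list[str] = []
    types: list[str] = []
    cells: dict[str, list[bool]] = {b: [] for b in behaviors}
    for t in ACCIDENT_TYPES:
        n_t = CLASS_COUNTS[t]
        for i in range(n_t):
            case_ids.append(f"{t}{i + 1:03d}")
            types.append(t)
            for b in behaviors:
                cells[b].append(i < OCCURRENCE_COUNTS[b][t])

    index = pd.Index(case_ids, name="case_id")
    data = pd.DataFrame(cells, index=index)
    return CaseMatrix(data, pd.Series(types, index=index))
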