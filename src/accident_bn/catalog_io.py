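"""Behavior catalogs, accident-case files, chains and the binary case matrix.

The raw material of the analysis is a set of coded accident cases: each case
carries one accident-type label and a time-ordered sequence of unsafe-behavior
codes (``B14``, ``B11``, ...).  This module reads and writes those records,
applies the case-filtering rules (single-behavior cases and accident types
outside the four modelled ones are dropped), extracts the directed behavior
chains, and binarizes retained chains into the Yes/No case matrix the network
is learned from.

File dialects (all plain CSV):

* catalog:  ``code,label,category``
* cases:    ``case_id,accident_type,codes`` with codes semicolon-joined in
  time order, e.g. ``A1,F,B18;B14;B12``
* matrix:   ``case_id,accident_type,B1,...,Bm`` with ``Yes``/``No`` cells
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AccidentType",
    "ACCIDENT_TYPES",
    "Behavior",
    "BehaviorCatalog",
    "AccidentCase",
    "BehaviorChain",
    "CaseMatrix",
    "Exclusion",
    "CatalogError",
    "CaseFileError",
    "behavior_index",
    "default_catalog",
    "load_catalog",
    "write_catalog",
    "load_cases",
    "write_cases",
    "filter_cases",
    "extract_chains",
    "behaviors_in_use",
    "chains_to_matrix",
]

_CODE_RE = re.compile(r"^B([1-9][0-9]*)$")
_TYPE_RE = re.compile(r"^[A-Z]$")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent behavior catalogs."""


class CaseFileError(ValueError):
    """Raised for malformed accident-case records."""


class AccidentType(str, Enum):
    """The four modelled accident types: struck-by, collapse, fall, lifting."""

    STRUCK_BY = "S"
    COLLAPSE = "C"
    FALL = "F"
    LIFTING = "L"


#: Canonical reporting order for the four accident types.
ACCIDENT_TYPES: tuple[str, ...] = tuple(t.value for t in AccidentType)


def behavior_index(code: str) -> int:
    """Return the integer index of a behavior code (``"B14"`` -> ``14``)."""
    m = _CODE_RE.match(code)
    if m is None:
        raise CatalogError(f"malformed behavior code: {code!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class Behavior:
    """One catalog entry: a coded unsafe behavior with label and category."""

    code: str
    label: str
    category: str

    def __post_init__(self) -> None:
        behavior_index(self.code)  # validates the code


class BehaviorCatalog:
    """An ordered collection of unique coded unsafe behaviors."""

    def __init__(self, behaviors: Iterable[Behavior]):
        self._behaviors = list(behaviors)
        seen: set[str] = set()
        for b in self._behaviors:
            if b.code in seen:
                raise CatalogError(f"duplicate behavior code in catalog: {b.code}")
            seen.add(b.code)
        self._by_code = {b.code: b for b in self._behaviors}

    def __len__(self) -> int:
        return len(self._behaviors)

    def __iter__(self):
        return iter(self._behaviors)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def get(self, code: str) -> Behavior:
        try:
            return self._by_code[code]
        except KeyError:
            raise CatalogError(f"unknown behavior code: {code}") from None

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(b.code for b in self._behaviors)


# Labels recoverable from the source study's worked examples and corrective-
# measure table; the full published behavior list (73 behaviors across 19
# types) is not reproduced there, so the remaining labels are placeholders.
_KNOWN_LABELS: dict[int, tuple[str, str]] = {
    1: ("stay in unsafe areas", "site discipline"),
    2: ("enter into dangerous areas", "site discipline"),
    3: ("use overloaded machines", "machine operation"),
    6: ("operate machines and equipment against the guidelines", "machine operation"),
    9: ("use machines and equipment without confirming safety beforehand", "machine operation"),
    10: ("use machines and equipment without effective safety devices", "machine operation"),
    11: ("implement inadequate protection measures for holes or borders", "protection measures"),
    12: ("do not use all personal protective equipment (PPE)", "personal protection"),
    13: ("misuse PPE", "personal protection"),
    14: ("engage in specialized operation without a permit", "permits"),
    17: ("install or dismantle formwork support system against procedures", "installation procedures"),
    18: ("install or dismantle machines and equipment against procedures", "installation procedures"),
    22: ("concreting against procedures", "installation procedures"),
    24: ("do not set up safety nets as required", "protection measures"),
    27: ("issue improper commands", "supervision"),
    31: ("do not hang warning signs in dangerous areas", "protection measures"),
}


def default_catalog(n_behaviors: int = 37) -> BehaviorCatalog:
    """Reconstructed default catalog ``B1..Bn``.

    Sixteen labels are recoverable from the source study's tables; the rest
    are synthetic placeholders (the study's appendix list is unavailable).
    """
    behaviors = []
    for k in range(1, n_behaviors + 1):
        label, category = _KNOWN_LABELS.get(
            k, (f"unsafe behavior B{k} (label not recoverable)", "unspecified")
        )
        behaviors.append(Behavior(f"B{k}", label, category))
    return BehaviorCatalog(behaviors)


def load_catalog(path: str | Path) -> BehaviorCatalog:
    """Read a behavior catalog CSV (``code,label,category``)."""
    behaviors: list[Behavior] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["code", "label", "category"]:
            raise CatalogError(f"{path}: expected header 'code,label,category'")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise CatalogError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            code = row[0].strip()
            if _CODE_RE.match(code) is None:
                raise CatalogError(f"{path}:{lineno}: malformed behavior code {code!r}")
            if code in seen:
                raise CatalogError(f"{path}:{lineno}: duplicate behavior code {code}")
            seen.add(code)
            behaviors.append(Behavior(code, row[1].strip(), row[2].strip()))
    return BehaviorCatalog(behaviors)


def write_catalog(path: str | Path, catalog: BehaviorCatalog) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "label", "category"])
        for b in catalog:
            writer.writerow([b.code, b.label, b.category])


@dataclass(frozen=True)
class AccidentCase:
    """One accident case: its type symbol and time-ordered behavior codes."""

    case_id: str
    accident_type: str
    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise CaseFileError(f"case {self.case_id}: empty behavior sequence")
        if len(set(self.sequence)) != len(self.sequence):
            dups = sorted({c for c in self.sequence if self.sequence.count(c) > 1})
            raise CaseFileError(
                f"case {self.case_id}: duplicate behavior code(s) {', '.join(dups)}"
            )


@dataclass(frozen=True)
class BehaviorChain:
    """A directed chain of unsafe behaviors (arrow direction = time order)."""

    case_id: str
    accident_type: str
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codes) < 2:
            raise CaseFileError(
                f"case {self.case_id}: a chain needs at least 2 behaviors"
            )

    def __str__(self) -> str:  # e.g. "B18 -> B14 -> B12"
        return " -> ".join(self.codes)


def load_cases(path: str | Path, catalog: BehaviorCatalog) -> list[AccidentCase]:
    """Read a case file (``case_id,accident_type,codes`` with ``;``-joined codes).

    Codes are resolved against *catalog*; an unknown code or malformed
    accident-type symbol is an error.  Accident-type symbols outside the four
    modelled ones are accepted here and dropped later by :func:`filter_cases`.
    """
    cases: list[AccidentCase] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "case_id",
            "accident_type",
            "codes",
        ]:
            raise CaseFileError(f"{path}: expected header 'case_id,accident_type,codes'")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise CaseFileError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            case_id, type_symbol = row[0].strip(), row[1].strip()
            if _TYPE_RE.match(type_symbol) is None:
                raise CaseFileError(
                    f"{path}:{lineno}: unknown accident type symbol {type_symbol!r}"
                )
            codes = tuple(c.strip() for c in row[2].split(";") if c.strip())
            for code in codes:
                if code not in catalog:
                    raise CaseFileError(
                        f"{path}:{lineno}: unknown behavior code {code} in case {case_id}"
                    )
            cases.append(AccidentCase(case_id, type_symbol, codes))
    return cases


def write_cases(path: str | Path, cases: Sequence[AccidentCase]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "accident_type", "codes"])
        for case in cases:
            writer.writerow([case.case_id, case.accident_type, ";".join(case.sequence)])


@dataclass(frozen=True)
class Exclusion:
    """One excluded case and the filtering rule that removed it."""

    case_id: str
    reason: str


def filter_cases(
    cases: Sequence[AccidentCase],
    min_chain_len: int = 2,
    allowed_types: frozenset[str] | set[str] = frozenset(ACCIDENT_TYPES),
) -> tuple[list[AccidentCase], list[Exclusion]]:
    """Apply the case-filtering rules.

    Cases whose type is not modelled, or whose behavior sequence is shorter
    than *min_chain_len* (single-behavior accidents carry no chain), are
    excluded; the returned log records every exclusion with its reason.
    The two lists partition the input.
    """
    retained: list[AccidentCase] = []
    excluded: list[Exclusion] = []
    for case in cases:
        if case.accident_type not in allowed_types:
            excluded.append(Exclusion(case.case_id, "type not modelled"))
        elif len(case.sequence) < min_chain_len:
            excluded.append(Exclusion(case.case_id, "single behavior"))
        else:
            retained.append(case)
    return retained, excluded


def extract_chains(cases: Sequence[AccidentCase]) -> list[BehaviorChain]:
    """Turn filtered cases into directed behavior chains (one per case)."""
    chains: list[BehaviorChain] = []
    for case in cases:
        if len(case.sequence) < 2:
            raise CaseFileError(
                f"case {case.case_id} has a single behavior; filter cases first"
            )
        chains.append(BehaviorChain(case.case_id, case.accident_type, case.sequence))
    return chains


def behaviors_in_use(chains: Sequence[BehaviorChain]) -> tuple[str, ...]:
    """The behavior codes occurring across *chains*, ordered by code index."""
    codes = {c for chain in chains for c in chain.codes}
    return tuple(sorted(codes, key=behavior_index))


@dataclass
class CaseMatrix:
    """Binary behavior-indicator matrix with one accident-type label per case.

    ``data`` is a boolean frame (rows = cases, columns = behavior codes,
    True = the behavior occurred in the case); ``accident_types`` holds one
    type symbol per row.  Time order is deliberately absent here — it lives
    in the chain records.
    """

    data: pd.DataFrame
    accident_types: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.accident_types.index):
            raise ValueError("case matrix rows and accident-type labels misaligned")
        self.data = self.data.astype(bool)
        self.accident_types = self.accident_types.astype(str)

    @property
    def n_cases(self) -> int:
        return len(self.data)

    @property
    def behaviors(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def class_counts(self) -> dict[str, int]:
        """Case tallies per accident type, canonical types first."""
        counts = self.accident_types.value_counts()
        ordered = [t for t in ACCIDENT_TYPES if t in counts.index]
        ordered += [t for t in counts.index if t not in ACCIDENT_TYPES]
        return {t: int(counts[t]) for t in ordered}

    def frequency(self, code: str, accident_type: str | None = None) -> float:
        """Occurrence rate of a behavior, overall or within one accident type."""
        if code not in self.data.columns:
            raise KeyError(f"behavior {code} not in matrix")
        col = self.data[code]
        if accident_type is None:
            return float(col.mean())
        mask = self.accident_types == accident_type
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"no cases of accident type {accident_type}")
        return float(col[mask].mean())

    def to_csv(self, path: str | Path) -> None:
        out = self.data.replace({True: "Yes", False: "No"})
        out.insert(0, "accident_type", self.accident_types)
        out.to_csv(path, index_label="case_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CaseMatrix":
        frame = pd.read_csv(path, index_col="case_id", dtype=str)
        if "accident_type" not in frame.columns:
            raise CaseFileError(f"{path}: missing accident_type column")
        types = frame.pop("accident_type")
        bad = set(frame.to_numpy().ravel()) - {"Yes", "No"}
        if bad:
            raise CaseFileError(f"{path}: non-Yes/No cells: {sorted(bad)!r}")
        return cls(frame == "Yes", types)


def chains_to_matrix(
    chains: Sequence[BehaviorChain], behavior_subset: Sequence[str]
) -> CaseMatrix:
    """Binarize chains: cell (case, code) is True iff the code occurs in the chain.

    Every chain code must belong to *behavior_subset*; within-chain time order
    is not encoded in the matrix.
    """
    subset = tuple(behavior_subset)
    subset_set = set(subset)
    rows = {}
    types = {}
    for chain in chains:
        missing = [c for c in chain.codes if c not in subset_set]
        if missing:
            raise CaseFileError(
                f"case {chain.case_id}: code(s) {', '.join(missing)} "
                f"not in behavior subset"
            )
        present = set(chain.codes)
        rows[chain.case_id] = [code in present for code in subset]
        types[chain.case_id] = chain.accident_type
    index = pd.Index(list(rows), name="case_id")
    data = pd.DataFrame(list(rows.values()), index=index, columns=list(subset), dtype=bool)
    return CaseMatrix(data, pd.Series(types, index=index))
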