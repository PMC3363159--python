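"""Pedigree handling and the additive (numerator) relationship matrix.

The additive relationship matrix ``A`` gives, for every pair of pedigree
members, twice their coefficient of coancestry; its diagonal is ``1 + F``
where ``F`` is the inbreeding coefficient.  ``A`` is the covariance
structure of the random polygenic effect in the animal model
``y = 1mu + Za + e`` with ``a ~ N(0, A * sigma_a^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError", "read_pedigree", "write_pedigree",
           "build_A", "inbreeding"]

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for malformed pedigrees: duplicate ids, undefined parents, cycles."""


@dataclass
class Pedigree:
    """Ordered pedigree records; parents always precede their offspring.

    Attributes
    ----------
    ids : list of str
        Individual identifiers in topological order.
    sire, dam : list of str
        Parent identifiers, ``"0"`` when unknown.
    generation : np.ndarray
        0 for founders, ``1 + max(parent generations)`` otherwise.
    """

    ids: list[str]
    sire: list[str]
    dam: list[str]
    generation: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        pos: dict[str, int] = {}
        for i, ind in enumerate(self.ids):
            if ind == UNKNOWN:
                raise PedigreeError("'0' is reserved for unknown parents")
            if ind in pos:
                raise PedigreeError(f"duplicate individual id {ind!r}")
            pos[ind] = i
        gen = np.zeros(len(self.ids), dtype=np.int64)
        for i, (ind, s, d) in enumerate(zip(self.ids, self.sire, self.dam)):
            for parent in (s, d):
                if parent == UNKNOWN:
                    continue
                if parent not in pos:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind!r} has no record")
                if pos[parent] >= i:
                    raise PedigreeError(
                        f"parent {parent!r} appears at or after offspring {ind!r}")
                gen[i] = max(gen[i], gen[pos[parent]] + 1)
        self.generation = gen
        self._pos = pos

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positions of `ids` in pedigree order; raises KeyError on unknown ids."""
        try:
            return np.asarray([self._pos[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in pedigree") from None

    @property
    def n_founders(self) -> int:
        return int(np.sum([s == UNKNOWN and d == UNKNOWN
                           for s, d in zip(self.sire, self.dam)]))

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire, dam) positional indices, -1 for unknown."""
        s = np.asarray([self._pos.get(x, -1) for x in self.sire], dtype=np.intp)
        d = np.asarray([self._pos.get(x, -1) for x in self.dam], dtype=np.intp)
        return s, d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "sire": self.sire, "dam": self.dam,
             "generation": self.generation})


def _toposort(records: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """Reorder records so parents precede offspring; detect cycles."""
    by_id = {}
    for rec in records:
        if rec[0] in by_id:
            raise PedigreeError(f"duplicate individual id {rec[0]!r}")
        by_id[rec[0]] = rec
    ordered: list[tuple[str, str, str]] = []
    state: dict[str, int] = {}  # 0 in progress, 1 done

    for root in by_id:
        if state.get(root) == 1:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if state.get(node) == 1:
                continue
            if expanded:
                state[node] = 1
                ordered.append(by_id[node])
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            _, s, d = by_id[node]
            for parent in (d, s):
                if parent == UNKNOWN:
                    continue
                if parent not in by_id:
                    raise PedigreeError(
                        f"parent {parent!r} referenced but never defined")
                if parent == node:
                    raise PedigreeError(f"{node!r} is its own parent")
                if state.get(parent) != 1:
                    stack.append((parent, False))
    return ordered


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column whitespace-separated pedigree file (id sire dam, 0=unknown).

    Records are topologically re-ordered if parents appear after offspring.
    """
    records: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            records.append((parts[0], parts[1], parts[2]))
    if not records:
        raise PedigreeError(f"{path}: empty pedigree")
    ordered = _toposort(records)
    ids, sires, dams = zip(*ordered)
    return Pedigree(list(ids), list(sires), list(dams))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s, d in zip(ped.ids, ped.sire, ped.dam):
            fh.write(f"{i}\t{s}\t{d}\n")


def build_A(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the tabular (recursive) method.

    a_ii = 1 + 0.5 * a_{s(i),d(i)};  a_ij = 0.5 * (a_{j,s(i)} + a_{j,d(i)})
    for j earlier in the pedigree order; unknown parents contribute 0.
    Returns a dense symmetric (n, n) array.
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients: F_i = 0.5 * a_{sire(i),dam(i)}, 0 when a parent is unknown."""
    A = build_A(ped)
    return np.diag(A) - 1.0
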