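"""Pedigree handling and numerator-relationship-matrix algebra.

Provides topologically ordered pedigree tables, the dense relationship
matrix A (tabular method), inbreeding coefficients via the Meuwissen-Luo
recursion, and the sparse inverse of A built from Henderson's rules with
inbreeding accounted for exactly.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, self-parenthood...)."""


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree: parents always precede offspring.

    Attributes
    ----------
    ids : np.ndarray of object
        Original animal identifiers in topological order.
    sire, dam : np.ndarray of int32
        Index (into ``ids``) of each animal's parent, ``-1`` if unknown.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    id_to_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.id_to_index:
            self.id_to_index = {a: i for i, a in enumerate(self.ids)}
        self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if len(par) != n:
                raise PedigreeError(f"{name} array length {len(par)} != {n} animals")
            bad = np.where(par >= np.arange(n))[0]
            bad = bad[par[bad] != UNKNOWN]
            if bad.size:
                raise PedigreeError(
                    f"animal {self.ids[bad[0]]!r} does not follow its {name}: "
                    "pedigree is not topologically ordered"
                )
        both = (self.sire == self.dam) & (self.sire != UNKNOWN)
        if both.any():
            raise PedigreeError(
                f"animal {self.ids[np.where(both)[0][0]]!r} has sire == dam"
            )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def indices_of(self, animal_ids) -> np.ndarray:
        """Map original ids to dense indices; raises KeyError listing misses."""
        missing = [a for a in animal_ids if a not in self.id_to_index]
        if missing:
            raise KeyError(f"animals not in pedigree: {missing[:10]}")
        return np.asarray([self.id_to_index[a] for a in animal_ids], dtype=np.int64)


def from_parent_map(animals, sires, dams) -> PedigreeTable:
    """Build a :class:`PedigreeTable` from raw (animal, sire, dam) id triples.

    Ids are arbitrary hashables; ``0``, ``"0"``, ``None`` and ``""`` denote an
    unknown parent. Parents never listed as animals are appended as founders.
    Rows are reordered so every parent precedes its offspring; a cycle raises
    :class:`PedigreeError` naming one animal on it.
    """
    missing_tokens = {0, "0", None, ""}
    animals = list(animals)
    sires = list(sires)
    dams = list(dams)
    if len(set(animals)) != len(animals):
        seen, dup = set(), None
        for a in animals:
            if a in seen:
                dup = a
                break
            seen.add(a)
        raise PedigreeError(f"duplicate animal id {dup!r}")

    known = set(animals)
    parent_of: dict = {}
    for a, s, d in zip(animals, sires, dams):
        s = None if s in missing_tokens else s
        d = None if d in missing_tokens else d
        if s is not None and s == d:
            raise PedigreeError(f"animal {a!r} has sire == dam ({s!r})")
        if a in (s, d):
            raise PedigreeError(f"animal {a!r} is its own parent")
        parent_of[a] = (s, d)

    founders_added = []
    for a, (s, d) in list(parent_of.items()):
        for p in (s, d):
            if p is not None and p not in known:
                parent_of[p] = (None, None)
                known.add(p)
                founders_added.append(p)
    if founders_added:
        logger.info(
            "added %d parents without own pedigree rows as founders", len(founders_added)
        )

    # Kahn's algorithm: parents before offspring.
    children: dict = {a: [] for a in parent_of}
    n_parents = {a: 0 for a in parent_of}
    for a, (s, d) in parent_of.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                n_parents[a] += 1
    order = [a for a in parent_of if n_parents[a] == 0]
    head = 0
    while head < len(order):
        a = order[head]
        head += 1
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                order.append(c)
    if len(order) != len(parent_of):
        on_cycle = next(a for a in parent_of if n_parents[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle through animal {on_cycle!r}")

    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire_ix = np.full(n, UNKNOWN, dtype=np.int32)
    dam_ix = np.full(n, UNKNOWN, dtype=np.int32)
    for a, (s, d) in parent_of.items():
        i = idx[a]
        if s is not None:
            sire_ix[i] = idx[s]
        if d is not None:
            dam_ix[i] = idx[d]
    return PedigreeTable(
        ids=np.asarray(order, dtype=object), sire=sire_ix, dam=dam_ix, id_to_index=idx
    )


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column pedigree file (animal, sire, dam; 0 = unknown parent).

    Accepts an optional ``animal,sire,dam`` header line. Ids are read as
    strings. Output is reordered so parents precede offspring.
    """
    df = pd.read_csv(path, dtype=str, header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"expected 3 columns in {path}, got {df.shape[1]}")
    first = [str(x).strip().lower() for x in df.iloc[0, :3]]
    if first[0] in ("animal", "id", "animal_id"):
        df = df.iloc[1:]
    df = df.iloc[:, :3].apply(lambda c: c.str.strip())
    return from_parent_map(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])


def truncate_ancestors(ped: PedigreeTable, keep_ids, max_depth: int = 5) -> PedigreeTable:
    """Prune to ancestors of ``keep_ids`` within ``max_depth`` generations.

    Animals beyond the depth limit become unknown parents, mirroring the
    use of a bounded number of pedigree generations in evaluation systems.
    """
    keep_ix = ped.indices_of(keep_ids)
    depth = np.full(len(ped), -1, dtype=np.int64)
    depth[keep_ix] = 0
    frontier = list(keep_ix)
    for g in range(1, max_depth + 1):
        nxt = []
        for i in frontier:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN and depth[p] < 0:
                    depth[p] = g
                    nxt.append(p)
        frontier = nxt
    keep_set = np.where(depth >= 0)[0]
    new_ids = ped.ids[keep_set]
    remap = {old: new for new, old in enumerate(keep_set)}

    def _remap_parent(parents):
        out = np.full(len(keep_set), UNKNOWN, dtype=np.int32)
        for new, old in enumerate(keep_set):
            p = parents[old]
            if p != UNKNOWN and p in remap:
                out[new] = remap[p]
        return out

    return PedigreeTable(
        ids=new_ids, sire=_remap_parent(ped.sire), dam=_remap_parent(ped.dam)
    )


def build_A(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    A[j, j] = 1 + 0.5 * A[sire(j), dam(j)];
    A[i, j] = 0.5 * (A[i, sire(j)] + A[i, dam(j)]) for i preceding j,
    with unknown parents contributing zero. Intended for pedigrees small
    enough to hold A densely (a few thousand animals).
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for j in range(n):
        sj, dj = s[j], d[j]
        if sj != UNKNOWN and dj != UNKNOWN:
            if j:
                A[j, :j] = 0.5 * (A[sj, :j] + A[dj, :j])
            A[j, j] = 1.0 + 0.5 * A[sj, dj]
        elif sj != UNKNOWN or dj != UNKNOWN:
            p = sj if sj != UNKNOWN else dj
            if j:
                A[j, :j] = 0.5 * A[p, :j]
            A[j, j] = 1.0
        else:
            A[j, j] = 1.0
        A[:j, j] = A[j, :j]
    return A


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo recursion.

    Equals ``diag(build_A(ped)) - 1`` but runs in memory proportional to
    the pedigree, not its square.
    """
    n = len(ped)
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    # D_i = Mendelian sampling variance factor given parental inbreeding
    for i in range(n):
        si, di = s[i], d[i]
        if si == UNKNOWN or di == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate A_ii = sum over ancestors j of L_j^2 * D_j
        L = {i: 1.0}
        aii = 0.0
        # process in decreasing index order so parents are visited after children
        heap = [-i]
        in_heap = {i}
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            sj, dj = s[j], d[j]
            if sj == UNKNOWN and dj == UNKNOWN:
                dq = 1.0
            elif sj == UNKNOWN or dj == UNKNOWN:
                p = sj if sj != UNKNOWN else dj
                dq = 0.75 - 0.25 * F[p]
            else:
                dq = 0.5 - 0.25 * (F[sj] + F[dj])
            aii += lj * lj * dq
            for p in (sj, dj):
                if p != UNKNOWN:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
            in_heap.discard(j)
        F[i] = aii - 1.0
    return F


def _mendelian_d(ped: PedigreeTable, F: np.ndarray) -> np.ndarray:
    """Mendelian-sampling variance d per animal given parental inbreeding."""
    n = len(ped)
    d = np.ones(n)
    has_s = ped.sire != UNKNOWN
    has_d = ped.dam != UNKNOWN
    d[has_s] -= 0.25 * (1.0 + F[ped.sire[has_s]])
    d[has_d] -= 0.25 * (1.0 + F[ped.dam[has_d]])
    return d


def build_A_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    For each animal i with Mendelian-sampling variance
    d_i = 1 - 0.25(1+F_sire) - 0.25(1+F_dam) (terms dropped for unknown
    parents), adds 1/d_i on (i,i), -0.5/d_i on (i,parent) and symmetric,
    and 0.25/d_i among the known parents.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    d = _mendelian_d(ped, F)
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0))
        raise PedigreeError(
            f"non-positive Mendelian sampling variance for animal {ped.ids[bad]!r}"
        )
    alpha = 1.0 / d
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)

    rows.append(idx)
    cols.append(idx)
    vals.append(alpha)
    for par in (ped.sire, ped.dam):
        m = par != UNKNOWN
        rows += [idx[m], par[m], par[m]]
        cols += [par[m], idx[m], par[m]]
        vals += [-0.5 * alpha[m], -0.5 * alpha[m], 0.25 * alpha[m]]
    both = (ped.sire != UNKNOWN) & (ped.dam != UNKNOWN)
    rows += [ped.sire[both], ped.dam[both]]
    cols += [ped.dam[both], ped.sire[both]]
    vals += [0.25 * alpha[both], 0.25 * alpha[both]]

    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    Ainv.sum_duplicates()
    return Ainv


@dataclass
class RelationshipFactors:
    """Inbreeding coefficients and the sparse A-inverse for a pedigree."""

    F: np.ndarray
    A_inverse: sparse.csr_matrix
    A: np.ndarray | None = None


def relationship_factors(ped: PedigreeTable, dense: bool = False) -> RelationshipFactors:
    """Compute F and sparse A-inverse (optionally dense A for small pedigrees)."""
    F = inbreeding(ped)
    Ainv = build_A_inverse(ped, F)
    A = build_A(ped) if dense else None
    return RelationshipFactors(F=F, A_inverse=Ainv, A=A)


def write_A_inverse(Ainv: sparse.spmatrix, path) -> None:
    """Export A-inverse as whitespace coordinate triplets (1-based, like MME dumps)."""
    coo = Ainv.tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.12g}\n")
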