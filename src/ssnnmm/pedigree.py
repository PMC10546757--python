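"""Pedigree parsing, ordering, inbreeding and the numerator relationship matrix.

The numerator relationship matrix **A** holds additive genetic relationships
among all individuals in a pedigree; its diagonal is ``1 + F`` with ``F`` the
inbreeding coefficient.  ``A`` is built by the tabular (recursive) method,
``F`` by the Meuwissen–Luo ancestor recursion, and ``A^-1`` directly by
Henderson's rules with inbreeding.  Unknown parents are treated as unrelated
founders; no genetic groups are fitted.

All matrices are indexed by the pedigree's topological order (parents before
offspring); the id <-> index map is explicit (:attr:`Pedigree.ids`,
:meth:`Pedigree.index_of`) so downstream modules never rely on implicit
alignment.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

UNKNOWN = -1

__all__ = [
    "Pedigree",
    "NumeratorMatrix",
    "PedigreeError",
    "read_pedigree",
    "topological_order",
    "inbreeding_coefficients",
    "numerator_matrix",
    "numerator_inverse",
    "submatrix",
]


class PedigreeError(ValueError):
    """Invalid pedigree structure (duplicate id, cycle, unknown reference)."""


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree.

    Parameters
    ----------
    ids : list of str
        Individual identifiers, verbatim strings, in storage order.
    sire, dam : ndarray of int
        Index of each individual's sire/dam in ``ids``; ``-1`` when unknown.
    generation : ndarray of int, optional
        Discrete generation number (filled by the simulator; -1 if unknown).
    ordered : bool
        True when every parent's index precedes its offspring's index.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    ordered: bool = field(default=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise PedigreeError(f"duplicate individual id {i!r}")
                seen.add(i)
        for arr in (self.sire, self.dam):
            if arr.shape != (n,):
                raise PedigreeError("sire/dam arrays must match the id list")
            bad = (arr < -1) | (arr >= n)
            if bad.any():
                raise PedigreeError("parent index out of range")
        if np.any((self.sire == np.arange(n)) & (self.sire >= 0)) or np.any(
            (self.dam == np.arange(n)) & (self.dam >= 0)
        ):
            i = int(
                np.nonzero(
                    ((self.sire == np.arange(n)) & (self.sire >= 0))
                    | ((self.dam == np.arange(n)) & (self.dam >= 0))
                )[0][0]
            )
            raise PedigreeError(f"individual {self.ids[i]!r} is its own parent")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {iid: k for k, iid in enumerate(self.ids)}

    def index_of(self, ids) -> np.ndarray:
        """Map ids to integer positions, raising on unknown ids."""
        lookup = self.index
        try:
            return np.array([lookup[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"id {exc.args[0]!r} not in pedigree") from None

    def founders(self) -> np.ndarray:
        return np.nonzero((self.sire == UNKNOWN) & (self.dam == UNKNOWN))[0]


@dataclass
class NumeratorMatrix:
    """Additive relationship matrix with inverse and inbreeding coefficients.

    Rows/columns follow ``ids`` (the pedigree's topological order).
    """

    ids: tuple[str, ...]
    A: np.ndarray | None = None
    A_inv: np.ndarray | None = None
    F: np.ndarray | None = None


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with header ``id,sire,dam``.

    Unknown parents are coded ``0`` or ``NA`` (or left empty).  A parent that
    is referenced but never defined as an individual is implicitly added as a
    founder, with a warning.  The returned pedigree is validated but not
    reordered; call :func:`topological_order` for that.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["id", "sire", "dam"]:
        raise PedigreeError(f"expected header 'id,sire,dam', got {list(df.columns)!r}")
    df.columns = cols + list(df.columns[3:])
    return pedigree_from_frame(df)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a :class:`Pedigree` from a DataFrame with id/sire/dam columns."""
    missing_codes = {"0", "NA", "", "NAN", "."}

    def clean(v: str) -> str | None:
        v = str(v).strip()
        return None if v.upper() in missing_codes else v

    ids = [str(v).strip() for v in df["id"]]
    sires = [clean(v) for v in df["sire"]]
    dams = [clean(v) for v in df["dam"]]

    seen: set[str] = set()
    for iid in ids:
        if iid in seen:
            raise PedigreeError(f"duplicate individual id {iid!r}")
        seen.add(iid)

    # parents referenced but never defined become founders (prepended)
    extra: list[str] = []
    for p in [*sires, *dams]:
        if p is not None and p not in seen and p not in extra:
            extra.append(p)
    if extra:
        warnings.warn(
            f"{len(extra)} parent(s) not defined as individuals; "
            f"added as founders: {extra[:5]}{'...' if len(extra) > 5 else ''}",
            stacklevel=2,
        )
    all_ids = extra + ids
    lookup = {iid: k for k, iid in enumerate(all_ids)}
    n = len(all_ids)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    off = len(extra)
    for k, (s, d) in enumerate(zip(sires, dams)):
        if s is not None:
            sire[off + k] = lookup[s]
        if d is not None:
            dam[off + k] = lookup[d]

    ped = Pedigree(tuple(all_ids), sire, dam)
    _check_acyclic(ped)
    return ped


def _kahn_order(ped: Pedigree) -> np.ndarray:
    """Stable topological order: already-ordered input maps to itself."""
    n = ped.n
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                children[p].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    out = np.empty(n, dtype=np.int64)
    k = 0
    while heap:
        i = heapq.heappop(heap)
        out[k] = i
        k += 1
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if k < n:
        cycle = _find_cycle(ped, indeg)
        raise PedigreeError(
            "pedigree contains a cycle: " + " -> ".join(ped.ids[i] for i in cycle)
        )
    return out


def _find_cycle(ped: Pedigree, indeg: np.ndarray) -> list[int]:
    start = int(np.nonzero(indeg > 0)[0][0])
    seen: dict[int, int] = {}
    path: list[int] = []
    i = start
    while i not in seen:
        seen[i] = len(path)
        path.append(i)
        nxt = ped.sire[i] if (ped.sire[i] != UNKNOWN and indeg[ped.sire[i]] > 0) else ped.dam[i]
        i = int(nxt)
    return path[seen[i] :] + [i]


def _check_acyclic(ped: Pedigree) -> None:
    _kahn_order(ped)


def topological_order(ped: Pedigree) -> Pedigree:
    """Return a pedigree reordered so every parent precedes its offspring.

    The ordering is stable: an input that is already topologically ordered is
    returned in the same order (``ordered`` flag set).
    """
    perm = _kahn_order(ped)
    if np.array_equal(perm, np.arange(ped.n)):
        return replace(ped, ordered=True)
    inv = np.empty(ped.n, dtype=np.int64)
    inv[perm] = np.arange(ped.n)
    remap = lambda a: np.where(a[perm] == UNKNOWN, UNKNOWN, inv[np.clip(a[perm], 0, None)])
    return Pedigree(
        ids=tuple(ped.ids[i] for i in perm),
        sire=remap(ped.sire),
        dam=remap(ped.dam),
        generation=None if ped.generation is None else ped.generation[perm],
        ordered=True,
    )


def _require_ordered(ped: Pedigree) -> None:
    if not ped.ordered:
        raise PedigreeError("pedigree must be topologically ordered first")


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo ancestor recursion.

    ``F[i]`` is half the additive relationship of i's parents; zero when
    either parent is unknown.  Cost is O(sum of ancestor-list sizes), i.e.
    near-linear for typical livestock pedigrees, and never requires the full
    ``A`` matrix.
    """
    _require_ordered(ped)
    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    # Mendelian sampling variance of ancestor j, using parental F (computed
    # earlier thanks to topological order)
    def mendelian_var(j: int) -> float:
        v = 1.0
        if s[j] != UNKNOWN:
            v -= 0.25 * (1.0 + F[s[j]])
        if d[j] != UNKNOWN:
            v -= 0.25 * (1.0 + F[d[j]])
        return v

    for i in range(n):
        if s[i] == UNKNOWN or d[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # A_ii = sum_j v_j^2 * D_j over ancestors j, with v the i-th row of
        # the Cholesky factor of A accumulated by walking up the pedigree.
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            vj = coeff.pop(j, 0.0)
            if vj == 0.0:
                continue
            a_ii += vj * vj * mendelian_var(j)
            for p in (s[j], d[j]):
                if p != UNKNOWN:
                    if p not in coeff:
                        heapq.heappush(heap, -int(p))
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * vj
        F[i] = a_ii - 1.0
    return F


def numerator_matrix(ped: Pedigree) -> NumeratorMatrix:
    """Tabular (recursive) construction of ``A``; also fills ``F``.

    a(i,j) = ½[a(j, sire_i) + a(j, dam_i)] for j < i, and
    a(i,i) = 1 + ½ a(sire_i, dam_i); unknown parents contribute zero.
    """
    _require_ordered(ped)
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        row = np.zeros(i)
        if s[i] != UNKNOWN:
            row += 0.5 * A[s[i], :i]
        if d[i] != UNKNOWN:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s[i] != UNKNOWN and d[i] != UNKNOWN:
            aii += 0.5 * A[s[i], d[i]]
        A[i, i] = aii
    return NumeratorMatrix(ids=ped.ids, A=A, F=np.diag(A) - 1.0)


def numerator_inverse(ped: Pedigree, F: np.ndarray | None = None) -> NumeratorMatrix:
    """``A^-1`` by Henderson's rules with inbreeding.

    Per individual the Mendelian sampling variance is
    ``d_i = 1 − 0.25(1+F_sire) − 0.25(1+F_dam)`` with terms dropped for
    unknown parents; contributions ``b=1/d_i`` are scattered onto
    (individual, known parents).
    """
    _require_ordered(ped)
    if F is None:
        F = inbreeding_coefficients(ped)
    n = ped.n
    Ainv = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        dv = 1.0
        parents = []
        if s[i] != UNKNOWN:
            dv -= 0.25 * (1.0 + F[s[i]])
            parents.append(int(s[i]))
        if d[i] != UNKNOWN:
            dv -= 0.25 * (1.0 + F[d[i]])
            parents.append(int(d[i]))
        if dv <= 0:
            raise PedigreeError(f"non-positive Mendelian variance at {ped.ids[i]!r}")
        b = 1.0 / dv
        Ainv[i, i] += b
        for p in parents:
            Ainv[i, p] -= 0.5 * b
            Ainv[p, i] -= 0.5 * b
            for q in parents:
                Ainv[p, q] += 0.25 * b
    return NumeratorMatrix(ids=ped.ids, A_inv=Ainv, F=F)


def relationship(ped: Pedigree, nm: NumeratorMatrix | None = None) -> NumeratorMatrix:
    """Convenience: one NumeratorMatrix with A, A_inv and F all filled."""
    nm = numerator_matrix(ped)
    nm.A_inv = numerator_inverse(ped, nm.F).A_inv
    return nm


def submatrix(nm: NumeratorMatrix, ids) -> np.ndarray:
    """Rows/columns of ``A`` for the given ids, in the given order."""
    if nm.A is None:
        raise ValueError("NumeratorMatrix has no A computed")
    lookup = {iid: k for k, iid in enumerate(nm.ids)}
    try:
        idx = np.array([lookup[i] for i in ids], dtype=np.int64)
    except KeyError as exc:
        raise PedigreeError(f"id {exc.args[0]!r} not in relationship matrix") from None
    return nm.A[np.ix_(idx, idx)]
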