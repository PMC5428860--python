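"""Pedigrees, the numerator relationship matrix A, and its sparse inverse.

The additive-genetic covariance of a random-regression model factorizes as
var(a) = A (x) G, where A is the pedigree-derived numerator relationship
matrix.  A is built by the tabular method (which accounts for inbreeding:
diag(A) = 1 + F_i) and its inverse by Henderson's rules with the
Quaas/Meuwissen inbreeding adjustment, so both agree with dense inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "read_pedigree",
    "numerator_relationship_matrix",
    "a_inverse",
]

UNKNOWN = 0


@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents precede offspring.

    ``ids`` are the original identifiers in sorted order; ``sire`` / ``dam``
    hold 0-based positional parent indices, -1 for unknown.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positional indices of the given ids (error on unknown id)."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[v] for v in np.atleast_1d(ids)], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"id {exc.args[0]!r} not in pedigree") from None

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (id, sire, dam) triples; 0/None/NaN = unknown parent.

        Sorts topologically, and raises on duplicate ids or parent-offspring
        cycles (the cycle is named in the error).
        """
        ids, sires, dams = [], [], []
        for rid, s, d in records:
            ids.append(rid)
            sires.append(_norm_parent(s))
            dams.append(_norm_parent(d))
        if len(set(ids)) != len(ids):
            seen, dups = set(), []
            for v in ids:
                if v in seen:
                    dups.append(v)
                seen.add(v)
            raise ValueError(f"duplicated pedigree id(s): {sorted(set(dups))!r}")

        known = set(ids)
        # Individuals referenced only as parents become founders.
        extras = [p for p in sires + dams if p is not None and p not in known]
        for p in dict.fromkeys(extras):
            ids.append(p)
            sires.append(None)
            dams.append(None)
            known.add(p)

        parent_map = {i: (s, d) for i, s, d in zip(ids, sires, dams)}
        order = _toposort(ids, parent_map)
        pos = {v: k for k, v in enumerate(order)}
        sire_idx = np.array(
            [pos[parent_map[v][0]] if parent_map[v][0] is not None else -1 for v in order]
        )
        dam_idx = np.array(
            [pos[parent_map[v][1]] if parent_map[v][1] is not None else -1 for v in order]
        )
        return cls(np.asarray(order, dtype=object), sire_idx, dam_idx)


def _norm_parent(p):
    if p is None:
        return None
    if isinstance(p, float) and np.isnan(p):
        return None
    if p in (0, "0", ""):
        return None
    return p


def _toposort(ids, parent_map):
    """Kahn's algorithm over parent -> offspring edges; reports cycles."""
    children = {v: [] for v in ids}
    indeg = {v: 0 for v in ids}
    for v in ids:
        for p in parent_map[v]:
            if p is not None:
                children[p].append(v)
                indeg[v] += 1
    queue = [v for v in ids if indeg[v] == 0]
    out = []
    while queue:
        v = queue.pop(0)
        out.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != len(ids):
        cycle = sorted(v for v in ids if indeg[v] > 0)
        raise ValueError(f"pedigree contains a cycle involving: {cycle!r}")
    return out


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV/TSV with header columns id, sire, dam.

    Unknown parents are coded 0 or left empty.  The returned pedigree is
    topologically sorted.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("id", "sire", "dam") if c not in cols]
    if missing:
        raise ValueError(f"pedigree file {path} lacks column(s) {missing}")
    recs = []
    for _, row in df.iterrows():
        rid = row[cols["id"]].strip()
        s = row[cols["sire"]]
        d = row[cols["dam"]]
        s = None if pd.isna(s) or s.strip() in ("", "0") else s.strip()
        d = None if pd.isna(d) or d.strip() in ("", "0") else d.strip()
        recs.append((rid, s, d))
    return Pedigree.from_records(recs)


def numerator_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    A_ii = 1 + 0.5 A_{s(i),d(i)};  A_ij = 0.5 (A_{j,s(i)} + A_{j,d(i)})
    for j < i, with unknown parents contributing zero.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        if i:
            row = np.zeros(i)
            if s[i] >= 0:
                row += A[s[i], :i]
            if d[i] >= 0:
                row += A[d[i], :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s[i], d[i]] if s[i] >= 0 and d[i] >= 0 else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = diag(A) - 1 (tabular method)."""
    return np.diag(numerator_relationship_matrix(ped)) - 1.0


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A^{-1} by Henderson's rules with inbreeding accounted for.

    Each individual contributes alpha_i = 1 / d_i to a 3x3 (i, sire, dam)
    pattern, where d_i is the Mendelian-sampling variance
    d_i = 1 - 0.25 (1 + F_s) - 0.25 (1 + F_d) over known parents.
    Exactly inverts the tabular-method A.
    """
    n = len(ped)
    if F is None:
        F = inbreeding(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        dm = 1.0
        if s >= 0:
            dm -= 0.25 * (1.0 + F[s])
        if d >= 0:
            dm -= 0.25 * (1.0 + F[d])
        alpha = 1.0 / dm
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv
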