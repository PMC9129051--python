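"""Cheng–Church biclustering with mutually row-exclusive extraction.

A bicluster is a submatrix (row subset I, column subset J) whose entries are
coherent under an additive row+column model ``a_ij ≈ mu + r_i + c_j``.
Coherence is measured by the mean squared residue (MSR)

    H(I, J) = mean over (i, j) of (a_ij - a_iJ - a_Ij + a_IJ)^2,

which is 0 for a perfectly additive submatrix.  The algorithm greedily
deletes the worst-fitting rows/columns until H falls below a user threshold
``delta`` (default 0.2), then re-adds any row/column that fits, and repeats
to extract several biclusters.  Rows accepted into a bicluster are removed
from the candidate pool so that the returned row sets are disjoint; columns
stay available to every bicluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bicluster",
    "BiclusterSet",
    "msr",
    "anova_r2",
    "single_node_deletion",
    "multiple_node_deletion",
    "node_addition",
    "find_bicluster",
    "find_exclusive_biclusters",
]

#: default MSR acceptance threshold
DEFAULT_DELTA = 0.2
#: multiple node deletion is applied only while a dimension exceeds this size
MULTIPLE_DELETION_SIZE = 100
#: multiple node deletion removes nodes with d-score > ALPHA * H
DEFAULT_ALPHA = 1.2
#: deletion never shrinks a dimension below this floor
SIZE_FLOOR = 2


@dataclass(frozen=True)
class Bicluster:
    """A submatrix with its coherence (MSR) and additive-fit R^2.

    ``rows`` and ``cols`` are sorted tuples of integer indices into the
    matrix the bicluster was extracted from.  ``converged`` is False when
    deletion hit the 2x2 size floor without reaching the MSR threshold.
    """

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    msr: float
    r2: float
    converged: bool = True

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.cols)

    def to_dict(self) -> dict:
        return {
            "rows": list(self.rows),
            "cols": list(self.cols),
            "msr": self.msr,
            "r2": self.r2,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Bicluster":
        return cls(
            rows=tuple(d["rows"]),
            cols=tuple(d["cols"]),
            msr=float(d["msr"]),
            r2=float(d["r2"]),
            converged=bool(d.get("converged", True)),
        )


@dataclass
class BiclusterSet:
    """An ordered collection of row-disjoint biclusters plus leftovers."""

    biclusters: list[Bicluster]
    unassigned_rows: tuple[int, ...]
    delta: float
    msr_max: float
    n_rows: int
    n_cols: int
    row_ids: list = field(default_factory=list)
    col_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.biclusters)

    def membership(self) -> np.ndarray:
        """Per-row bicluster id (0-based) or -1 for unassigned."""
        out = np.full(self.n_rows, -1, dtype=int)
        for k, bc in enumerate(self.biclusters):
            out[list(bc.rows)] = k
        return out

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "msr_max": self.msr_max,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "row_ids": list(self.row_ids),
            "col_ids": list(self.col_ids),
            "unassigned_rows": list(self.unassigned_rows),
            "biclusters": [bc.to_dict() for bc in self.biclusters],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiclusterSet":
        return cls(
            biclusters=[Bicluster.from_dict(b) for b in d["biclusters"]],
            unassigned_rows=tuple(d["unassigned_rows"]),
            delta=float(d["delta"]),
            msr_max=float(d["msr_max"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            row_ids=list(d.get("row_ids", [])),
            col_ids=list(d.get("col_ids", [])),
        )


def _as_index(idx) -> np.ndarray:
    a = np.asarray(sorted(idx), dtype=int)
    return a


def msr(matrix: np.ndarray, rows, cols) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean squared residue of the submatrix (rows, cols).

    Returns ``(H, d_row, d_col)`` where ``d_row[i]`` is the mean squared
    residue of row i over the column set (and symmetrically for columns),
    so that ``H == d_row.mean() == d_col.mean()``.
    """
    rows = _as_index(rows)
    cols = _as_index(cols)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("row and column sets must be non-empty")
    sub = np.asarray(matrix, dtype=float)[np.ix_(rows, cols)]
    row_means = sub.mean(axis=1, keepdims=True)
    col_means = sub.mean(axis=0, keepdims=True)
    overall = sub.mean()
    resid = sub - row_means - col_means + overall
    sq = resid**2
    d_row = sq.mean(axis=1)
    d_col = sq.mean(axis=0)
    return float(sq.mean()), d_row, d_col


def anova_r2(matrix: np.ndarray, rows, cols) -> float:
    """Proportion of submatrix variance explained by the additive row+column fit.

    ``r2 = 1 - SSE/SST`` with ``SSE = |I||J| * H(I,J)`` and
    ``SST = sum (a_ij - a_IJ)^2``; clipped into [0, 1].
    """
    rows = _as_index(rows)
    cols = _as_index(cols)
    if rows.size < 2 or cols.size < 2:
        raise ValueError("need at least 2 rows and 2 columns for a two-way fit")
    sub = np.asarray(matrix, dtype=float)[np.ix_(rows, cols)]
    sst = float(((sub - sub.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("constant submatrix: total sum of squares is zero")
    h, _, _ = msr(matrix, rows, cols)
    sse = rows.size * cols.size * h
    return float(np.clip(1.0 - sse / sst, 0.0, 1.0))


def single_node_deletion(
    matrix: np.ndarray,
    rows,
    cols,
    delta: float,
    size_floor: int = SIZE_FLOOR,
    trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Remove the single worst row or column until H <= delta.

    At each step the row or column with the largest mean squared residue
    d-score is removed (ties: rows before columns, then lowest index).
    Returns ``(rows, cols, converged)``; ``converged`` is False when the
    size floor was reached with H still above delta.  ``trace``, if given,
    collects H after every deletion.
    """
    rows = _as_index(rows)
    cols = _as_index(cols)
    h, d_row, d_col = msr(matrix, rows, cols)
    if trace is not None:
        trace.append(h)
    while h > delta:
        if rows.size <= size_floor and cols.size <= size_floor:
            return rows, cols, False
        best_row = int(np.argmax(d_row)) if rows.size > size_floor else None
        best_col = int(np.argmax(d_col)) if cols.size > size_floor else None
        row_score = d_row[best_row] if best_row is not None else -np.inf
        col_score = d_col[best_col] if best_col is not None else -np.inf
        if row_score >= col_score:  # rows win ties
            rows = np.delete(rows, best_row)
        else:
            cols = np.delete(cols, best_col)
        h, d_row, d_col = msr(matrix, rows, cols)
        if trace is not None:
            trace.append(h)
    return rows, cols, True


def multiple_node_deletion(
    matrix: np.ndarray,
    rows,
    cols,
    delta: float,
    alpha: float = DEFAULT_ALPHA,
    size_threshold: int = MULTIPLE_DELETION_SIZE,
    size_floor: int = SIZE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-delete rows/columns with d-score > alpha*H while a dimension is large.

    This is the original algorithm's scaling device: while |I| (resp. |J|)
    exceeds ``size_threshold``, every row (column) whose d-score exceeds
    ``alpha * H`` is removed in one pass.  Stops when no pass removes
    anything or H <= delta; single-node deletion then finishes the job.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    rows = _as_index(rows)
    cols = _as_index(cols)
    h, d_row, d_col = msr(matrix, rows, cols)
    while h > delta:
        changed = False
        if rows.size > size_threshold:
            keep = d_row <= alpha * h
            # never delete below the floor
            if keep.sum() < size_floor:
                order = np.argsort(d_row)  # keep the best-fitting rows
                keep = np.zeros_like(keep)
                keep[order[:size_floor]] = True
            if not keep.all():
                rows = rows[keep]
                changed = True
                h, d_row, d_col = msr(matrix, rows, cols)
        if h <= delta:
            break
        if cols.size > size_threshold:
            keep = d_col <= alpha * h
            if keep.sum() < size_floor:
                order = np.argsort(d_col)
                keep = np.zeros_like(keep)
                keep[order[:size_floor]] = True
            if not keep.all():
                cols = cols[keep]
                changed = True
                h, d_row, d_col = msr(matrix, rows, cols)
        if not changed:
            break
    return rows, cols


def node_addition(
    matrix: np.ndarray,
    rows,
    cols,
    allow_inverse_rows: bool = False,
    row_candidates=None,
    col_candidates=None,
    trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-add every column, then every row, whose d-score is <= current H.

    Scores for candidate nodes are computed against the current submatrix
    means; passes repeat until nothing changes.  ``row_candidates`` /
    ``col_candidates`` restrict which indices may be added (used by the
    exclusive extraction loop to keep already-assigned rows off limits).
    Optionally rows whose *negation* fits the additive model can be added
    (off by default: the clinical features here have directional meaning).
    """
    X = np.asarray(matrix, dtype=float)
    rows = _as_index(rows)
    cols = _as_index(cols)
    n, p = X.shape
    row_cand = _as_index(row_candidates) if row_candidates is not None else np.arange(n)
    col_cand = _as_index(col_candidates) if col_candidates is not None else np.arange(p)
    while True:
        changed = False
        h, _, _ = msr(X, rows, cols)
        if trace is not None:
            trace.append(h)
        # columns first
        out_cols = np.setdiff1d(col_cand, cols)
        if out_cols.size:
            sub_rows = X[np.ix_(rows, cols)]
            row_means = sub_rows.mean(axis=1)
            overall = sub_rows.mean()
            cand = X[np.ix_(rows, out_cols)]
            col_means = cand.mean(axis=0)
            resid = cand - row_means[:, None] - col_means[None, :] + overall
            scores = (resid**2).mean(axis=0)
            add = out_cols[scores <= h]
            if add.size:
                cols = np.union1d(cols, add)
                changed = True
                h, _, _ = msr(X, rows, cols)
        # then rows
        out_rows = np.setdiff1d(row_cand, rows)
        if out_rows.size:
            sub = X[np.ix_(rows, cols)]
            col_means = sub.mean(axis=0)
            overall = sub.mean()
            cand = X[np.ix_(out_rows, cols)]
            row_means = cand.mean(axis=1)
            resid = cand - row_means[:, None] - col_means[None, :] + overall
            scores = (resid**2).mean(axis=1)
            add = out_rows[scores <= h]
            if allow_inverse_rows:
                resid_inv = -cand - row_means_inv(cand)[:, None] - col_means[None, :] + overall
                scores_inv = (resid_inv**2).mean(axis=1)
                add = np.union1d(add, out_rows[scores_inv <= h])
            if add.size:
                rows = np.union1d(rows, add)
                changed = True
        if not changed:
            if trace is not None:
                trace.append(msr(X, rows, cols)[0])
            return rows, cols


def row_means_inv(cand: np.ndarray) -> np.ndarray:
    return (-cand).mean(axis=1)


def find_bicluster(
    matrix: np.ndarray,
    delta: float = DEFAULT_DELTA,
    row_pool=None,
    col_pool=None,
    alpha: float = DEFAULT_ALPHA,
    size_threshold: int = MULTIPLE_DELETION_SIZE,
    allow_inverse_rows: bool = False,
) -> Bicluster:
    """Extract one bicluster: multiple deletion -> single deletion -> addition.

    Starts from the full matrix restricted to ``row_pool`` (all rows by
    default).  Node addition only considers rows inside the pool, so an
    exclusive extraction loop can keep already-used rows off limits.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("matrix must be at least 2x2")
    row_pool = _as_index(row_pool) if row_pool is not None else np.arange(n)
    col_pool = _as_index(col_pool) if col_pool is not None else np.arange(p)
    rows, cols = row_pool, col_pool

    rows, cols = multiple_node_deletion(X, rows, cols, delta, alpha=alpha, size_threshold=size_threshold)
    rows, cols, converged = single_node_deletion(X, rows, cols, delta)
    if converged:
        rows, cols = node_addition(
            X,
            rows,
            cols,
            allow_inverse_rows=allow_inverse_rows,
            row_candidates=row_pool,
            col_candidates=col_pool,
        )
    h, _, _ = msr(X, rows, cols)
    try:
        r2 = anova_r2(X, rows, cols)
    except ValueError:
        r2 = 1.0  # constant submatrix: additive model is exact
    return Bicluster(
        rows=tuple(int(r) for r in rows),
        cols=tuple(int(c) for c in cols),
        msr=float(h),
        r2=r2,
        converged=converged,
    )


def find_exclusive_biclusters(
    matrix: np.ndarray,
    delta: float = DEFAULT_DELTA,
    max_k: int = 6,
    min_rows: int = 2,
    alpha: float = DEFAULT_ALPHA,
    size_threshold: int = MULTIPLE_DELETION_SIZE,
    allow_inverse_rows: bool = False,
    row_ids=None,
    col_ids=None,
) -> BiclusterSet:
    """Iteratively extract up to ``max_k`` biclusters with disjoint row sets.

    After each accepted bicluster its rows are removed from the candidate
    pool; columns remain available to later biclusters.  Extraction stops
    at ``max_k`` biclusters, when fewer than ``min_rows`` rows remain, or
    when deletion fails to converge.  ``delta`` must lie strictly between 0
    and the whole-matrix MSR (the natural maximum of the threshold).
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    msr_max, _, _ = msr(X, np.arange(n), np.arange(p))
    if not (0.0 < delta < msr_max):
        raise ValueError(
            f"delta must be in (0, msr_max); whole-matrix MSR is {msr_max:.6g}"
        )
    pool = np.arange(n)
    found: list[Bicluster] = []
    while len(found) < max_k and pool.size >= max(min_rows, 2):
        bc = find_bicluster(
            X,
            delta=delta,
            row_pool=pool,
            alpha=alpha,
            size_threshold=size_threshold,
            allow_inverse_rows=allow_inverse_rows,
        )
        if not bc.converged or bc.n_rows < min_rows:
            break
        found.append(bc)
        pool = np.setdiff1d(pool, np.asarray(bc.rows, dtype=int))
    return BiclusterSet(
        biclusters=found,
        unassigned_rows=tuple(int(r) for r in pool),
        delta=delta,
        msr_max=float(msr_max),
        n_rows=n,
        n_cols=p,
        row_ids=list(row_ids) if row_ids is not None else list(range(n)),
        col_ids=list(col_ids) if col_ids is not None else list(range(p)),
    )
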