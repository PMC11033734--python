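"""Design of structured binary compressed-sensing measurement matrices.

A switched sensor array imposes hard constraints on which sensors can be
combined into one analog measurement: sensors come in *blocks* that share a
multiplexing switch (at most one sensor per block can be active), and blocks
are wired together in *groups* whose active signals are summed into a single
channel.  A measurement is therefore a 0/1 row vector with at most one 1 in
each block, and measurements act independently on each group, so the full
matrix is block diagonal with one group matrix per group.

Because the matrices are small and binary, asymptotic random-matrix theory
gives no useful guarantees.  Instead, matrix quality is scored by the
*s-sparse injectivity number* (SIN): the worst-case ratio
``||M(x1 - x2)|| / ||x1 - x2||`` over distinct s-sparse vectors, which equals
the minimum smallest singular value over all 2s-column submatrices of ``M``.
A strictly positive SIN certifies exact identifiability of s-sparse signals;
larger values mean more stable recovery.  Good matrices within the feasible
class are found by a seeded random search that keeps the best SIN seen.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OFF",
    "CSStructure",
    "GroupMatrix",
    "BlockDiagonalMatrix",
    "DesignResult",
    "make_cs_matrix",
    "is_feasible",
    "sample_feasible_matrix",
    "sin",
    "sparse_injectivity_number",
    "normalized_sin",
    "rip_delta",
    "best_s_term_error",
    "search_design",
    "find_nonsingular_m0",
    "assemble_block_diagonal",
    "replicate_group",
    "compression_sweep",
]

#: Selection-list entry meaning "no sensor active in this block".
OFF = 0

#: SIN values above this threshold count as nonsingular (safely above
#: accumulated SVD round-off for the submatrix sizes handled here).
NONSINGULAR_SIN = 1e-8


@dataclass(frozen=True)
class CSStructure:
    """Parameters of the feasible structured-matrix family.

    Parameters
    ----------
    m0 : int
        Number of measurements per group (rows of each group matrix).
    block_size : int
        Sensors sharing one switch; at most one of them can be active
        per measurement.  Default 4.
    blocks_per_group : int
        Blocks summed into one measurement channel.  Default 4.
    num_groups : int
        Independent groups; the assembled matrix is block diagonal with
        one group matrix per group.  Default 4.
    """

    m0: int
    block_size: int = 4
    blocks_per_group: int = 4
    num_groups: int = 4

    def __post_init__(self) -> None:
        for name in ("m0", "block_size", "blocks_per_group", "num_groups"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n0(self) -> int:
        """Sensors per group."""
        return self.block_size * self.blocks_per_group

    @property
    def n(self) -> int:
        """Total sensors."""
        return self.n0 * self.num_groups

    @property
    def m(self) -> int:
        """Total measurements."""
        return self.m0 * self.num_groups


def _as_selection_array(selection, structure: CSStructure) -> np.ndarray:
    """Validate a selection list and return it as an (m0, blocks) int array.

    Entry ``OFF`` (0) switches the block off; entries ``1..block_size`` name
    the active sensor within the block.
    """
    sel = np.asarray(selection, dtype=int)
    expected = (structure.m0, structure.blocks_per_group)
    if sel.shape != expected:
        raise ValueError(
            f"selection list must have shape {expected} "
            f"(rows x blocks), got {sel.shape}"
        )
    bad = (sel < 0) | (sel > structure.block_size)
    if bad.any():
        r, b = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid selection entry {sel[r, b]} at row {r}, block {b}: "
            f"allowed values are 0 (off) .. {structure.block_size}"
        )
    return sel


@dataclass(eq=False)
class GroupMatrix:
    """One binary m0 x n0 measurement matrix obeying the block constraint."""

    entries: np.ndarray
    structure: CSStructure

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if not is_feasible(self.entries, self.structure):
            raise ValueError("entries violate the block structure constraint")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GroupMatrix)
            and self.structure == other.structure
            and np.array_equal(self.entries, other.entries)
        )

    def selection(self) -> np.ndarray:
        """Recover the selection list (rows x blocks, 0 = off)."""
        st = self.structure
        sel = np.zeros((st.m0, st.blocks_per_group), dtype=int)
        for b in range(st.blocks_per_group):
            block = self.entries[:, b * st.block_size : (b + 1) * st.block_size]
            rows, cols = np.nonzero(block)
            sel[rows, b] = cols + 1
        return sel


@dataclass(eq=False)
class BlockDiagonalMatrix:
    """Assembled block-diagonal matrix acting on all sensor groups."""

    group_matrices: list

    def __post_init__(self) -> None:
        if not self.group_matrices:
            raise ValueError("need at least one group matrix")
        shapes = {gm.entries.shape for gm in self.group_matrices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent group matrix shapes: {shapes}")

    @property
    def structure(self) -> CSStructure:
        base = self.group_matrices[0].structure
        return CSStructure(
            m0=base.m0,
            block_size=base.block_size,
            blocks_per_group=base.blocks_per_group,
            num_groups=len(self.group_matrices),
        )

    @property
    def entries(self) -> np.ndarray:
        from scipy.linalg import block_diag

        return block_diag(*[gm.entries for gm in self.group_matrices])

    @property
    def shape(self) -> tuple[int, int]:
        m0, n0 = self.group_matrices[0].entries.shape
        g = len(self.group_matrices)
        return (g * m0, g * n0)


@dataclass
class DesignResult:
    """Outcome of the random-search matrix design."""

    best_matrix: GroupMatrix
    best_selection: np.ndarray
    best_sin: float
    iterations_run: int
    rng_seed: int | None
    trace: np.ndarray = field(repr=False, default=None)  # best SIN after each draw


def make_cs_matrix(selection, structure: CSStructure) -> GroupMatrix:
    """Build the group measurement matrix from a selection list.

    ``selection[i, b] = c`` (1-based ``c``) puts a 1 at row ``i``, column
    ``(b * block_size) + (c - 1)``; ``selection[i, b] = 0`` leaves block
    ``b`` of row ``i`` empty.
    """
    sel = _as_selection_array(selection, structure)
    M = np.zeros((structure.m0, structure.n0), dtype=np.int8)
    rows, blocks = np.nonzero(sel)
    cols = blocks * structure.block_size + sel[rows, blocks] - 1
    M[rows, cols] = 1
    return GroupMatrix(entries=M, structure=structure)


def is_feasible(M, structure: CSStructure) -> bool:
    """True iff ``M`` is binary with at most one 1 per row per block."""
    M = np.asarray(M)
    if M.shape != (structure.m0, structure.n0):
        raise ValueError(
            f"matrix shape {M.shape} does not match structure "
            f"({structure.m0}, {structure.n0})"
        )
    if not np.isin(M, (0, 1)).all():
        return False
    blocks = M.reshape(structure.m0, structure.blocks_per_group, structure.block_size)
    return bool((blocks.sum(axis=2) <= 1).all())


def sample_feasible_matrix(
    structure: CSStructure, rng: np.random.Generator
) -> tuple[np.ndarray, GroupMatrix]:
    """Draw a uniformly random feasible matrix.

    Each (row, block) cell independently takes one of the ``block_size + 1``
    values {off, sensor 1, ..., sensor block_size} with equal probability,
    so every feasible matrix (including ones with inactive blocks) has
    positive probability.
    """
    sel = rng.integers(
        0, structure.block_size + 1, size=(structure.m0, structure.blocks_per_group)
    )
    return sel, make_cs_matrix(sel, structure)


@lru_cache(maxsize=64)
def _column_subsets(n_cols: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n_cols), k)), dtype=np.intp)


def sin(M, s: int) -> float:
    """s-sparse injectivity number of ``M``.

    Minimum over all ``2s``-column subsets of the smallest singular value of
    the restricted submatrix; equivalently the largest constant ``theta``
    with ``||M(x1 - x2)|| >= theta * ||x1 - x2||`` for all s-sparse
    ``x1, x2``.  Exact shortcut: any all-zero column (or fewer than ``2s``
    nonzero columns) forces the value 0 without enumeration.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-D matrix")
    if s < 1:
        raise ValueError("sparsity level s must be >= 1")
    n_cols = M.shape[1]
    k = 2 * s
    if k > n_cols:
        raise ValueError(f"need 2*s <= {n_cols} columns, got s={s}")
    col_norms = np.linalg.norm(M, axis=0)
    if np.count_nonzero(col_norms) < k:
        return 0.0
    subsets = _column_subsets(n_cols, k)
    sub = M[:, subsets]  # (m0, K, k)
    sub = np.moveaxis(sub, 1, 0)  # (K, m0, k)
    gram = sub.transpose(0, 2, 1) @ sub
    lam = np.linalg.eigvalsh(gram)
    lam_min = lam[:, 0].min()
    # rank tolerance: eigenvalues at the round-off floor of a numerically
    # singular submatrix are reported as exactly 0 (for binary matrices the
    # smallest *true* nonzero eigenvalue is orders of magnitude larger)
    if lam_min < 1e-10 * max(lam[:, -1].max(), 1.0):
        return 0.0
    return float(np.sqrt(lam_min))


# The field name is "s-SIN"; alias for readers who prefer a full word.
sparse_injectivity_number = sin


def normalized_sin(M, s: int) -> float:
    """SIN divided by the spectral norm of ``M`` (scale-free diagnostic)."""
    M = np.asarray(M, dtype=float)
    nrm = np.linalg.norm(M, 2)
    if nrm == 0:
        return 0.0
    return sin(M, s) / nrm


def rip_delta(M, s: int) -> float:
    """Restricted-isometry constant of order ``s`` by exhaustive enumeration.

    Smallest ``delta`` with ``(1-delta)||x||^2 <= ||Mx||^2 <=
    (1+delta)||x||^2`` for all s-sparse ``x``: the max over supports of
    ``max(1 - lambda_min, lambda_max - 1)`` of the Gram matrix of the column
    submatrix.  Guarded to small matrices because the enumeration is
    combinatorial.
    """
    M = np.asarray(M, dtype=float)
    n_cols = M.shape[1]
    if s < 1 or s > n_cols:
        raise ValueError(f"need 1 <= s <= {n_cols}, got s={s}")
    if n_cols > 24:
        raise ValueError(
            f"enumeration guard: {n_cols} columns > 24; use a smaller matrix"
        )
    subsets = _column_subsets(n_cols, s)
    sub = np.moveaxis(M[:, subsets], 1, 0)
    gram = sub.transpose(0, 2, 1) @ sub
    lam = np.linalg.eigvalsh(gram)
    return float(max((1.0 - lam[:, 0]).max(), (lam[:, -1] - 1.0).max(), 0.0))


def best_s_term_error(x, s: int) -> float:
    """l1 error of the best s-term approximation of ``x``.

    Sum of the magnitudes of all but the ``s`` largest-magnitude entries.
    """
    x = np.abs(np.asarray(x, dtype=float).ravel())
    if s < 0 or s > x.size:
        raise ValueError(f"need 0 <= s <= {x.size}, got s={s}")
    if s == x.size:
        return 0.0
    return float(np.sort(x)[: x.size - s].sum())


def _has_zero_column(M: np.ndarray) -> bool:
    return bool((~M.any(axis=0)).any())


def search_design(
    structure: CSStructure,
    s: int,
    n_iter: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    early_reject: bool = True,
) -> DesignResult:
    """Random search for a feasible matrix with large s-SIN.

    Repeatedly draws feasible matrices and keeps the one with the strictly
    largest SIN seen so far, starting from the zero matrix with SIN 0.
    ``early_reject`` skips SIN enumeration for candidates with an all-zero
    column (their SIN is exactly 0), which greatly speeds up long searches.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    best_sin = 0.0
    best_sel = np.zeros((structure.m0, structure.blocks_per_group), dtype=int)
    best_mat = make_cs_matrix(best_sel, structure)
    trace = np.zeros(n_iter)
    for i in range(n_iter):
        sel, gm = sample_feasible_matrix(structure, rng)
        if early_reject and _has_zero_column(gm.entries):
            value = 0.0
        else:
            value = sin(gm.entries, s)
        if value > best_sin:  # strict improvement only; ties keep the earlier matrix
            best_sin, best_sel, best_mat = value, sel, gm
        trace[i] = best_sin
    return DesignResult(
        best_matrix=best_mat,
        best_selection=best_sel,
        best_sin=best_sin,
        iterations_run=n_iter,
        rng_seed=seed,
        trace=trace,
    )


def find_nonsingular_m0(
    structure_template: CSStructure,
    m0_values: Sequence[int],
    s: int,
    n_iter: int,
    seed: int | None = None,
    sin_threshold: float = NONSINGULAR_SIN,
) -> dict[int, float]:
    """Extended search over measurement counts; stops each search early once
    a nonsingular SIN is found.  Returns ``{m0: best SIN found}``.
    """
    results: dict[int, float] = {}
    for k, m0 in enumerate(m0_values):
        st = CSStructure(
            m0=m0,
            block_size=structure_template.block_size,
            blocks_per_group=structure_template.blocks_per_group,
            num_groups=structure_template.num_groups,
        )
        rng = np.random.default_rng(None if seed is None else seed + 1000 * k)
        best = 0.0
        for _ in range(n_iter):
            _, gm = sample_feasible_matrix(st, rng)
            if _has_zero_column(gm.entries):
                continue
            value = sin(gm.entries, s)
            if value > best:
                best = value
            if best > sin_threshold:
                break
        results[m0] = best
    return results


def assemble_block_diagonal(groups: Sequence[GroupMatrix]) -> BlockDiagonalMatrix:
    """Stack group matrices into the block-diagonal full-array matrix."""
    return BlockDiagonalMatrix(group_matrices=list(groups))


def replicate_group(gm: GroupMatrix, num_groups: int) -> BlockDiagonalMatrix:
    """Use the same group matrix for every group (the common deployment)."""
    return assemble_block_diagonal([gm] * num_groups)


def compression_sweep(
    structure_template: CSStructure,
    m0_values: Sequence[int],
    s: int,
    n_iter: int,
    seed: int | None = None,
    sin_threshold: float = 0.1,
) -> pd.DataFrame:
    """Run the design search for a range of measurement counts.

    Returns a table with one row per ``m0``: the best SIN found, the
    compression factor ``n0 / m0``, and whether the best SIN exceeds
    ``sin_threshold``.
    """
    rows = []
    for k, m0 in enumerate(m0_values):
        st = CSStructure(
            m0=m0,
            block_size=structure_template.block_size,
            blocks_per_group=structure_template.blocks_per_group,
            num_groups=structure_template.num_groups,
        )
        if not 1 <= m0 <= st.n0:
            raise ValueError(f"m0={m0} outside [1, n0={st.n0}]")
        res = search_design(st, s, n_iter, seed=None if seed is None else seed + k)
        rows.append(
            {
                "m0": m0,
                "best_sin": res.best_sin,
                "compression": st.n0 / m0,
                "flagged": res.best_sin > sin_threshold,
            }
        )
    return pd.DataFrame(rows)
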