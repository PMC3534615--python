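"""Contact-map normalization: SCN, its alternatives, filtering and transforms.

The central routine is Sequential Component Normalization (SCN): alternate
scaling of every column, then every row, to unit Euclidean norm, repeated
until the matrix is again symmetric with all marginal norms equal to one.
This is a Sinkhorn-style balancing in the L2 metric; on the positive
matrices 3C data produces it typically converges in two or three sweeps.
Two single-pass alternatives are provided for comparison: division by the
product of row/column Euclidean norms, and division by the product of
row/column sums (L1 marginals).  Intra-chromosomal maps additionally get a
genomic-distance normalization that divides each contact by the expected
count at its genomic separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .biases import DistanceExpectation

SYMMETRY_TOL = 1e-9


class ConvergenceError(RuntimeError):
    """SCN failed to balance the matrix within the iteration budget."""


class DegenerateMatrixError(ValueError):
    """A zero row/column (or an empty matrix) makes the operation undefined."""


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact matrix over retained fragments or bins.

    ``values`` is dense; ``index`` carries the fragment (or bin) identities
    of the retained rows/columns, so filtering subsets both identically.
    ``history`` records every normalization applied, in order.
    """

    values: np.ndarray
    index: np.ndarray
    scope: str = "all"
    history: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.index = np.asarray(self.index)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if len(self.index) != self.values.shape[0]:
            raise ValueError("index length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_symmetric(self, tol: float = SYMMETRY_TOL) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=tol, rtol=0))

    def _child(self, values: np.ndarray, step: str, index: np.ndarray | None = None) -> "ContactMatrix":
        return ContactMatrix(
            values,
            index=self.index.copy() if index is None else index,
            scope=self.scope,
            history=self.history + [step],
            metadata=dict(self.metadata),
        )

    # ------------------------------------------------------------------ I/O
    def to_dense_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.index, columns=self.index).to_csv(
            path, sep="\t"
        )

    def to_coo_tsv(self, path: str | Path, index_path: str | Path | None = None) -> None:
        i, j = np.nonzero(np.triu(self.values))
        pd.DataFrame(
            {"frag_i": self.index[i], "frag_j": self.index[j], "value": self.values[i, j]}
        ).to_csv(path, sep="\t", index=False)
        if index_path is not None:
            pd.DataFrame({"index": self.index}).to_csv(index_path, sep="\t", index=False)

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"scope": self.scope, "n": self.n, "history": self.history,
                 "metadata": self.metadata},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_dense_tsv(cls, path: str | Path, scope: str = "all") -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), index=df.index.to_numpy(), scope=scope)

    @classmethod
    def from_coo_tsv(cls, path: str | Path, scope: str = "all") -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = np.unique(np.concatenate([df["frag_i"], df["frag_j"]]))
        lut = {v: k for k, v in enumerate(ids)}
        values = np.zeros((len(ids), len(ids)))
        for fi, fj, v in zip(df["frag_i"], df["frag_j"], df["value"]):
            i, j = lut[fi], lut[fj]
            values[i, j] += v
            if i != j:
                values[j, i] += v
        return cls(values, index=ids, scope=scope)


# ---------------------------------------------------------------- filtering

def filter_low_norm(matrix: ContactMatrix, threshold: float = 30.0) -> ContactMatrix:
    """Drop fragments whose row Euclidean norm falls below ``threshold``.

    Poorly detected fragments would otherwise be inflated by the equal
    weight normalization gives every fragment; the default cut of 30
    removes the low-count tail of the norm distribution.
    """
    norms = np.linalg.norm(matrix.values, axis=1)
    keep = norms >= threshold
    n_removed = int((~keep).sum())
    if not keep.any():
        raise DegenerateMatrixError(
            f"low-norm filter at threshold {threshold} removed every fragment"
        )
    out = matrix._child(
        matrix.values[np.ix_(keep, keep)],
        f"filter_low_norm(threshold={threshold})",
        index=matrix.index[keep],
    )
    out.metadata["low_norm_removed"] = n_removed
    return out


# ------------------------------------------------------------ normalization

def _marginal_l2(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.linalg.norm(values, axis=0), np.linalg.norm(values, axis=1)


def scn(
    matrix: ContactMatrix, tol: float = 1e-3, max_iter: int = 200
) -> tuple[ContactMatrix, int]:
    """Sequential Component Normalization.

    One sweep = normalize every column vector to unit Euclidean norm, then
    every row vector of the result.  Sweeps repeat until every row and
    column norm is within ``tol`` of one, after which the matrix is
    symmetrized as (M + M^T)/2.  Returns the balanced matrix and the number
    of sweeps performed.  Convergence is not guaranteed for arbitrary
    matrices; failure to converge raises with diagnostics.
    """
    values = matrix.values.copy()
    col0, row0 = _marginal_l2(values)
    if np.any(col0 == 0) or np.any(row0 == 0):
        bad = int(np.flatnonzero((col0 == 0) | (row0 == 0))[0])
        raise DegenerateMatrixError(
            f"zero row/column at index {bad}; apply filter_low_norm first"
        )
    n_sweeps = 0
    for _ in range(max_iter):
        cols, rows = _marginal_l2(values)
        if max(np.abs(cols - 1).max(), np.abs(rows - 1).max()) < tol:
            break
        values /= cols[np.newaxis, :]
        values /= np.linalg.norm(values, axis=1)[:, np.newaxis]
        n_sweeps += 1
    else:
        cols, rows = _marginal_l2(values)
        worst = max(np.abs(cols - 1).max(), np.abs(rows - 1).max())
        raise ConvergenceError(
            f"SCN did not converge in {max_iter} sweeps (max |norm-1| = {worst:.3g})"
        )
    values = (values + values.T) / 2.0
    out = matrix._child(values, f"scn(tol={tol})")
    out.metadata["scn_sweeps"] = n_sweeps
    return out, n_sweeps


def norm_product(matrix: ContactMatrix) -> ContactMatrix:
    """Single-pass alternative: c*_ij = c_ij / (||row_i|| * ||col_j||).

    Faster than SCN and usually very close to it, but the result's marginal
    norms are not exactly one, which matters for rank-based downstream
    analyses such as the colocalization test.
    """
    cols, rows = _marginal_l2(matrix.values)
    if np.any(cols == 0) or np.any(rows == 0):
        raise DegenerateMatrixError("zero row/column norm")
    return matrix._child(matrix.values / np.outer(rows, cols), "norm_product")


def marginal_sum(matrix: ContactMatrix) -> ContactMatrix:
    """Alternative used elsewhere in the field: divide by products of row/column sums.

    Gives relatively more weight to fragments with few interactions and
    yields lower-contrast maps than SCN.
    """
    cols = matrix.values.sum(axis=0)
    rows = matrix.values.sum(axis=1)
    if np.any(cols == 0) or np.any(rows == 0):
        raise DegenerateMatrixError("zero row/column sum")
    return matrix._child(matrix.values / np.outer(rows, cols), "marginal_sum")


def distance_normalize(
    matrix: ContactMatrix, expectation: "DistanceExpectation", frags
) -> ContactMatrix:
    """Divide each intra-chromosomal contact by its expected count at that genomic distance.

    The expectation comes from a polynomial fit of reads-per-possible-
    interaction against genomic distance; dividing by it reveals contacts
    stronger than the polymer-distance effect alone predicts.  SCN can be
    applied afterwards.
    """
    if matrix.scope == "inter":
        raise ValueError("distance normalization applies to intra-chromosomal maps")
    sub = frags.df.set_index("fragment_id").loc[matrix.index]
    mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
    chroms = sub["chrom"].to_numpy()
    same = chroms[:, None] == chroms[None, :]
    dg = np.abs(mids[:, None] - mids[None, :])
    values = matrix.values.copy()
    if same.any():
        expected = np.ones_like(values)
        e = expectation.evaluate(dg[same])
        if np.any(e <= 0):
            raise ValueError("distance expectation non-positive; fit clamping failed")
        expected[same] = e
        values = values / expected
    values[~same] = matrix.values[~same]
    np.fill_diagonal(values, np.diag(matrix.values))
    return matrix._child(values, "distance_normalize")


# ----------------------------------------------------------- map transforms

def correlation_map(matrix: ContactMatrix) -> ContactMatrix:
    """Pearson correlation of interaction profiles: entry (i,j) = corr(row_i, row_j).

    Sharpens compartment-like structure; the diagonal is one by definition.
    Zero-variance rows produce undefined entries, reported as NaN and
    tallied in metadata.
    """
    if matrix.n < 3:
        raise ValueError("correlation map needs at least 3 retained fragments")
    values = matrix.values
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.asarray(corr)
    np.fill_diagonal(corr, 1.0)
    out = matrix._child(corr, "correlation_map")
    out.metadata["zero_variance_rows"] = int((sd == 0).sum())
    return out


def bin_matrix(matrix: ContactMatrix, b: int, chroms: np.ndarray | None = None) -> ContactMatrix:
    """Sum counts over consecutive runs of ``b`` fragments (per chromosome).

    Used for sparse maps of large genomes where per-fragment resolution is
    unreadable; the final partial bin of each chromosome is retained, and
    total mass is conserved.
    """
    if b < 1:
        raise ValueError("bin size must be >= 1")
    if b == 1:
        return matrix._child(matrix.values.copy(), "bin_matrix(b=1)")
    if chroms is None:
        chroms = np.zeros(matrix.n, dtype=int)
    assignment = np.empty(matrix.n, dtype=int)
    nb = 0
    for c in pd.unique(chroms):
        pos = np.flatnonzero(chroms == c)
        local = np.arange(len(pos)) // b
        assignment[pos] = nb + local
        nb += int(local[-1]) + 1
    agg = np.zeros((nb, matrix.n))
    agg[assignment, np.arange(matrix.n)] = 1.0
    values = agg @ matrix.values @ agg.T
    return matrix._child(
        values, f"bin_matrix(b={b})", index=np.arange(nb)
    )


_BLUR_KERNEL = np.full((3, 3), 0.05)


def blur(values: np.ndarray, reps: int = 10) -> np.ndarray:
    """Visualization blur: repeated 3x3 convolution with a uniform 0.05 kernel.

    The kernel sums to 0.45, so intensity is deliberately not preserved —
    this matches the graphic rendering convention the maps were drawn with.
    Zero padding at the edges.
    """
    from scipy.ndimage import convolve

    out = np.asarray(values, dtype=float)
    for _ in range(reps):
        out = convolve(out, _BLUR_KERNEL, mode="constant", cval=0.0)
    return out
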