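"""Sparse binned Hi-C contact matrices: construction, balancing, expected decay.

The contact matrix is stored as an upper-triangle sparse matrix over global
bin ids (see :mod:`hicrearr.genome`); symmetry is a storage convention, all
query helpers present the full symmetric view. Balancing is square-root
vanilla coverage: weight_i = 1/sqrt(marginal_i), balanced value
w_i * c_ij * w_j; bins with zero marginal have undefined (NaN) weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .genome import BinIndex

__all__ = [
    "ContactMatrix",
    "pairs_to_matrix",
    "balance_sqrt_vc",
    "expected_by_distance",
]

log = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    bins: BinIndex
    counts: sp.csr_matrix  # upper triangle (i <= j), raw counts
    uvp: int = 0
    weights: np.ndarray | None = None  # per-bin sqrt-VC weights, NaN undefined

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin index")

    # ------------------------------------------------------------------ views
    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric raw-count matrix (diagonal counted once)."""
        u = self.counts.tocsr()
        d = sp.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def marginals(self) -> np.ndarray:
        """Per-bin total coverage (row sums of the symmetric matrix)."""
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def dense(
        self,
        chrom_row: str,
        chrom_col: str | None = None,
        balanced: bool = False,
    ) -> np.ndarray:
        """Dense symmetric-view block for one chromosome pair.

        Balanced values in rows/columns of zero-coverage bins are NaN.
        """
        chrom_col = chrom_col or chrom_row
        r0, r1 = self.bins.chrom_span(chrom_row)
        c0, c1 = self.bins.chrom_span(chrom_col)
        block = np.asarray(self.symmetric()[r0:r1, c0:c1].todense(), dtype=float)
        if balanced:
            w = self.require_weights()
            block = block * w[r0:r1, None] * w[None, c0:c1]
        return block

    def require_weights(self) -> np.ndarray:
        if self.weights is None:
            raise ValueError("matrix is not balanced; call balance_sqrt_vc first")
        return self.weights

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    # ------------------------------------------------------------ operations
    def coarsen(self, factor: int) -> "ContactMatrix":
        """Sum counts into bins ``factor`` times wider (same layout)."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("factor must be a positive integer")
        coarse = BinIndex(self.bins.layout, self.bins.resolution * int(factor))
        # map fine global bin id -> coarse global bin id
        chrom, start = self.bins.bin_starts()
        mapping = coarse.offsets[chrom] + start // coarse.resolution
        coo = self.counts.tocoo()
        i = np.minimum(mapping[coo.row], mapping[coo.col])
        j = np.maximum(mapping[coo.row], mapping[coo.col])
        n = coarse.n_bins
        counts = sp.coo_matrix((coo.data, (i, j)), shape=(n, n)).tocsr()
        counts.sum_duplicates()
        return ContactMatrix(coarse, counts, uvp=self.uvp)


def pairs_to_matrix(pairs, bins: BinIndex) -> ContactMatrix:
    """Bin a stream of contact pairs into an upper-triangle count matrix.

    ``pairs`` is an iterable of (chromA, posA, chromB, posB) or a tuple of
    four parallel arrays (chrom index arrays allowed). Out-of-range records
    are rejected (counted in the log); uvp = number of accepted pairs.
    """
    if isinstance(pairs, tuple) and len(pairs) == 4:
        ca, pa, cb, pb = pairs
        ca = np.asarray(ca)
        cb = np.asarray(cb)
    else:
        rows = list(pairs)
        if not rows:
            n = bins.n_bins
            return ContactMatrix(bins, sp.csr_matrix((n, n)), uvp=0)
        ca = np.array([r[0] for r in rows])
        pa = np.array([int(r[1]) for r in rows], dtype=np.int64)
        cb = np.array([r[2] for r in rows])
        pb = np.array([int(r[3]) for r in rows], dtype=np.int64)
    if ca.dtype.kind in "UOS":
        idx = {n: i for i, n in enumerate(bins.layout.names)}
        known = np.array([c in idx for c in ca]) & np.array([c in idx for c in cb])
        ca_i = np.array([idx.get(c, -1) for c in ca], dtype=np.int64)
        cb_i = np.array([idx.get(c, -1) for c in cb], dtype=np.int64)
    else:
        ca_i = ca.astype(np.int64)
        cb_i = cb.astype(np.int64)
        nc = len(bins.layout.names)
        known = (ca_i >= 0) & (ca_i < nc) & (cb_i >= 0) & (cb_i < nc)
    pa = np.asarray(pa, dtype=np.int64)
    pb = np.asarray(pb, dtype=np.int64)
    lengths = np.asarray(bins.layout.lengths, dtype=np.int64)
    ok = known.copy()
    ok[known] &= (
        (pa[known] >= 0)
        & (pa[known] < lengths[ca_i[known]])
        & (pb[known] >= 0)
        & (pb[known] < lengths[cb_i[known]])
    )
    n_rej = int((~ok).sum())
    if n_rej:
        log.warning("pairs_to_matrix: rejected %d out-of-range record(s)", n_rej)
    ba = bins.bin_ids(ca_i[ok], pa[ok])
    bb = bins.bin_ids(cb_i[ok], pb[ok])
    i = np.minimum(ba, bb)
    j = np.maximum(ba, bb)
    n = bins.n_bins
    counts = sp.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n, n)
    ).tocsr()
    counts.sum_duplicates()
    return ContactMatrix(bins, counts, uvp=int(ok.sum()))


def balance_sqrt_vc(matrix: ContactMatrix) -> ContactMatrix:
    """Attach square-root vanilla-coverage weights (1/sqrt of bin marginal).

    Raw counts are preserved; zero-coverage bins get NaN weights. An all-zero
    matrix yields all-NaN weights, not an error.
    """
    marg = matrix.marginals()
    with np.errstate(divide="ignore"):
        w = 1.0 / np.sqrt(marg)
    w[marg <= 0] = np.nan
    return ContactMatrix(matrix.bins, matrix.counts, uvp=matrix.uvp, weights=w)


def expected_by_distance(
    matrix: ContactMatrix,
    chrom: str,
    balanced: bool = True,
    monotone: bool = False,
) -> np.ndarray:
    """Mean intra-chromosomal signal per bin distance (index d = bin offset).

    The mean at distance d runs over all n-d cells of the d-th diagonal,
    skipping NaN (unbalanced) cells. ``monotone=True`` applies isotonic
    non-increasing smoothing (pool-adjacent-violators).
    """
    block = matrix.dense(chrom, balanced=balanced)
    n = block.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(block, offset=d)
        if diag.size and np.isfinite(diag).any():
            out[d] = np.nanmean(diag)
    if monotone:
        out = _pava_nonincreasing(out)
    return out


def _pava_nonincreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-increasing fit, NaN passed through."""
    out = y.copy()
    idx = np.flatnonzero(~np.isnan(y))
    vals = y[idx]
    # fit non-increasing == fit non-decreasing on negated values
    v = -vals
    level = list(v)
    weight = [1.0] * len(v)
    i = 0
    while i < len(level) - 1:
        if level[i] > level[i + 1] + 1e-15:
            merged = (level[i] * weight[i] + level[i + 1] * weight[i + 1]) / (
                weight[i] + weight[i + 1]
            )
            weight[i] += weight[i + 1]
            level[i] = merged
            del level[i + 1], weight[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    expanded = np.concatenate(
        [np.full(int(w), -l) for l, w in zip(level, weight)]
    )
    out[idx] = expanded
    return out
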