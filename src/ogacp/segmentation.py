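"""Block segmentation of an ordered regression series.

The cutting stage partitions the time axis 1..n into p_n contiguous blocks so
that each block holds at most one change point, and rewrites the piecewise
model as a sparse high-dimensional regression on a cumulative block design:
column (l, c) of the design carries covariate c with all rows before block l
zeroed, so a coefficient change after block boundary l shows up as a nonzero
coefficient on block l's columns.

Indices are 1-based and ranges inclusive throughout, matching the time-series
convention that a change point a_j is the LAST index of the pre-change regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, InvalidBlockLengthError, OgacpError


@dataclass
class RegressionSeries:
    """An ordered response/regressor pair — the unit of all analysis.

    Attributes
    ----------
    y : ndarray, shape (n,)
        Response, ordered by time.
    X : ndarray, shape (n, q)
        Regressors, row i observed together with y[i]. No implicit
        intercept: supply a column of ones if one is wanted.
    index : ndarray of int, shape (n,)
        1-based time index, strictly increasing by 1.
    """

    y: np.ndarray
    X: np.ndarray
    index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] == 1 and self.y.size > 1:
            self.X = self.X.T
        n = self.y.size
        if self.X.shape[0] != n:
            raise OgacpError(
                f"y has {n} rows but X has {self.X.shape[0]}"
            )
        if self.index is None:
            self.index = np.arange(1, n + 1)
        else:
            self.index = np.asarray(self.index, dtype=int).ravel()
            if self.index.size != n or not np.array_equal(
                self.index, np.arange(self.index[0], self.index[0] + n)
            ):
                raise OgacpError("index must be contiguous and ordered")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise OgacpError("series contains non-finite values")
        if n <= self.q:
            raise InsufficientDataError(
                f"need more observations ({n}) than covariates ({self.q})"
            )

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def q(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SegmentationPlan:
    """Partition of {1..n} into p_n contiguous blocks.

    Every block except the first has length exactly ``m``; the first block
    absorbs the division remainder, so m <= |Q_1| < 2m.
    """

    n: int
    m: int
    p_n: int
    blocks: tuple[tuple[int, int], ...]  # 1-based inclusive (start, end)

    def block_of(self, i: int) -> int:
        """1-based block number holding time index ``i``."""
        first_end = self.blocks[0][1]
        if i <= first_end:
            return 1
        return 2 + (i - first_end - 1) // self.m


def make_plan(n: int, m: int) -> SegmentationPlan:
    """Partition 1..n into p_n = floor(n/m) blocks of length m (first longer).

    Parameters
    ----------
    n, m : int
        Series length and block length. Requires 1 <= m <= n/2 (at least
        two blocks).
    """
    if m < 1 or 2 * m > n:
        raise InvalidBlockLengthError(f"need 1 <= m <= n/2, got m={m}, n={n}")
    p_n = n // m
    first_len = n - (p_n - 1) * m
    blocks = [(1, first_len)]
    for l in range(2, p_n + 1):
        start = first_len + (l - 2) * m + 1
        blocks.append((start, start + m - 1))
    assert blocks[-1][1] == n
    return SegmentationPlan(n=n, m=m, p_n=p_n, blocks=tuple(blocks))


@dataclass(frozen=True)
class BlockDesign:
    """Cumulative block design: n x (p_n * q) matrix Z.

    Column (l, c) equals covariate c of X with all rows belonging to blocks
    1..l-1 set to zero. Block 1's columns are therefore X itself. ``colmap``
    maps each column of Z to its (block, covariate) pair, both 1-based.
    """

    Z: np.ndarray
    colmap: tuple[tuple[int, int], ...]
    plan: SegmentationPlan
    q: int


def build_block_design(series: RegressionSeries, plan: SegmentationPlan) -> BlockDesign:
    """Assemble the cumulative block design for ``series`` under ``plan``."""
    n, q = series.n, series.q
    if plan.n != n:
        raise OgacpError(f"plan built for n={plan.n}, series has n={n}")
    p = plan.p_n
    Z = np.zeros((n, p * q))
    for l, (start, _end) in enumerate(plan.blocks, start=1):
        j0 = (l - 1) * q
        Z[start - 1 :, j0 : j0 + q] = series.X[start - 1 :, :]
    colmap = tuple((l, c) for l in range(1, p + 1) for c in range(1, q + 1))
    return BlockDesign(Z=Z, colmap=colmap, plan=plan, q=q)


def lagged_design(series: np.ndarray, order: int) -> RegressionSeries:
    """Build an AR(order) lagged design from a univariate series.

    Row t of X holds (y_{t-1}, ..., y_{t-order}); the response starts at the
    (order+1)-th observation, so n shrinks by ``order``.
    """
    series = np.asarray(series, dtype=float).ravel()
    if order < 1:
        raise OgacpError("order must be >= 1")
    if series.size <= order + 2:
        raise InsufficientDataError(
            f"need more than {order + 2} observations for AR({order})"
        )
    y = series[order:]
    X = np.column_stack([series[order - k : -k] for k in range(1, order + 1)])
    return RegressionSeries(y=y, X=X)
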