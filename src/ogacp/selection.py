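"""Greedy segment selection: OGA path, HDIC stopping, trimming, block mapping.

The orthogonal greedy algorithm (OGA) is forward stepwise regression: at each
step it picks the column of the (centered) block design with the largest
normalized correlation with the current residual, orthogonalizes it against
the columns already chosen, and deflates the residual. The path is stopped by
a high-dimensional information criterion

    HDIC(J) = log(sigma^2_J) + |J| * c_n * log(r_n) / n,

with sigma^2_J the least-squares residual variance on the raw (un-
orthogonalized) columns in J, and the stopped set is trimmed: a column is
kept only if deleting it strictly worsens HDIC. Surviving columns are mapped
back to blocks; maximal runs of consecutive selected blocks (excluding block
1, which carries the baseline coefficients) identify candidate change-point
windows of width 2m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoCandidateError
from .segmentation import SegmentationPlan

_RSS_FLOOR = 1e-300


def center_columns(y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center the response and every design column.

    Returns
    -------
    yc, Zc : centered copies of ``y`` and ``Z``.
    usable : boolean mask; False flags zero-variance (constant) columns,
        which are excluded from greedy candidacy downstream.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    yc = y - y.mean()
    mu = Z.mean(axis=0)
    Zc = Z - mu
    norms = np.linalg.norm(Zc, axis=0)
    scale = np.maximum(np.abs(mu), 1.0)
    usable = norms > 1e-10 * np.sqrt(Z.shape[0]) * scale
    return yc, Zc, usable


def _subset_rss(y: np.ndarray, Z: np.ndarray, cols) -> float:
    """Residual sum of squares of least squares of y on Z[:, cols]."""
    cols = list(cols)
    if not cols:
        return float(y @ y)
    coef, _, _, _ = np.linalg.lstsq(Z[:, cols], y, rcond=None)
    r = y - Z[:, cols] @ coef
    return float(r @ r)


def hdic_value(rss: float, k: int, n: int, c_n: float, r_n: int) -> float:
    """HDIC for a subset with residual sum of squares ``rss`` and size ``k``."""
    sigma2 = rss / n
    if sigma2 <= 0:
        warnings.warn("perfect fit: clamping sigma^2 at machine floor")
        sigma2 = _RSS_FLOOR
    return float(np.log(sigma2) + k * c_n * np.log(r_n) / n)


@dataclass
class OGAPath:
    """Trace of one greedy selection run.

    ``selected`` holds the chosen column indices (0-based into Z) in pick
    order; ``resid_norms[d]`` is ||r^(d)||^2 after d picks (entry 0 is
    ||y||^2); ``hdic[d-1]`` is HDIC of the first d picks. ``d_hat`` and
    ``J_hat`` are filled by :func:`hdic_stop` and :func:`trim`.
    """

    selected: list[int]
    resid_norms: np.ndarray
    hdic: np.ndarray = field(default=None)  # type: ignore[assignment]
    d_hat: int = 0
    J_hat: list[int] = field(default_factory=list)


def oga_path(y: np.ndarray, Z: np.ndarray, D_n: int,
             usable: np.ndarray | None = None) -> OGAPath:
    """Run the greedy path for D_n steps on centered data.

    At step d the pick maximizes |z_j' r^(d)| / (n^{1/2} ||z_j||) over
    unselected usable columns (ties broken toward the lowest index); the
    residual is then deflated by the orthogonalized pick (Gram-Schmidt with
    one reorthogonalization pass for numerical stability).
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if usable is None:
        norms_all = np.linalg.norm(Z, axis=0)
        usable = norms_all > 1e-12
    norms = np.linalg.norm(Z, axis=0)
    if not usable.any():
        raise NoCandidateError("all design columns are zero or constant")
    D_n = int(min(D_n, usable.sum(), n - 1))
    if D_n < 1:
        raise NoCandidateError("no greedy steps possible")

    mask = usable.copy()
    inv_norm = np.zeros(p)
    inv_norm[mask] = 1.0 / norms[mask]
    r = y.copy()
    Q = np.empty((n, D_n))
    selected: list[int] = []
    rss = [float(r @ r)]
    sqrt_n = np.sqrt(n)
    for d in range(D_n):
        corr = np.abs(Z.T @ r) * inv_norm / sqrt_n
        corr[~mask] = -np.inf
        j = int(np.argmax(corr))
        v = Z[:, j].copy()
        if d:
            Qd = Q[:, :d]
            v -= Qd @ (Qd.T @ v)
            v -= Qd @ (Qd.T @ v)  # reorthogonalize
        nv = np.linalg.norm(v)
        if nv <= 1e-10 * norms[j]:
            # numerically in the span of the current set: drop and retry
            mask[j] = False
            if not mask.any():
                break
            continue
        qv = v / nv
        Q[:, d] = qv
        r = r - qv * (qv @ r)
        selected.append(j)
        mask[j] = False
        rss.append(float(r @ r))
    if not selected:
        raise NoCandidateError("greedy selection found no usable column")
    return OGAPath(selected=selected, resid_norms=np.asarray(rss))


def hdic_stop(path: OGAPath, y: np.ndarray, Z: np.ndarray,
              c_n: float, r_n: int) -> int:
    """Stop the path at the HDIC argmin; returns and stores 1-based d_hat.

    sigma^2 along the path comes from the orthogonalized residual norms,
    which equal the least-squares residual variance on the raw selected
    columns (the projection onto the span is the same subspace projection).
    """
    n = y.size
    D = len(path.selected)
    ks = np.arange(1, D + 1)
    sigma2 = np.maximum(path.resid_norms[1:] / n, _RSS_FLOOR)
    if (path.resid_norms[1:] <= 0).any():
        warnings.warn("perfect fit along path: clamping sigma^2 at machine floor")
    path.hdic = np.log(sigma2) + ks * c_n * np.log(r_n) / n
    path.d_hat = int(np.argmin(path.hdic)) + 1
    return path.d_hat


def trim(path: OGAPath, y: np.ndarray, Z: np.ndarray,
         c_n: float, r_n: int) -> list[int]:
    """Prune the stopped set: keep a column only if removing it worsens HDIC.

    With a single pick the set is kept as is; if every column were pruned the
    first pick is retained so the selected set is never empty.
    """
    n = y.size
    d_hat = path.d_hat
    if d_hat < 1:
        raise ValueError("run hdic_stop before trim")
    J = path.selected[:d_hat]
    if d_hat == 1:
        path.J_hat = [J[0]]
        return path.J_hat
    full = hdic_value(_subset_rss(y, Z, J), d_hat, n, c_n, r_n)
    kept = []
    for j in J:
        rest = [c for c in J if c != j]
        if hdic_value(_subset_rss(y, Z, rest), len(rest), n, c_n, r_n) > full:
            kept.append(j)
    if not kept:
        kept = [path.selected[0]]
    path.J_hat = kept
    return kept


@dataclass(frozen=True)
class SelectedSegments:
    """Candidate change-point windows derived from the surviving columns.

    ``A_hat`` — blocks with at least one surviving column; ``C_hat`` — one
    block index k_j per detected change point; ``windows`` — the associated
    2m-wide index ranges (1-based inclusive), pairwise disjoint and ordered.
    """

    A_hat: frozenset[int]
    C_hat: tuple[int, ...]
    s_hat: int
    windows: tuple[tuple[int, int], ...]


def select_segments(J_hat, colmap, plan: SegmentationPlan, q: int) -> SelectedSegments:
    """Map surviving columns to blocks and build refinement windows.

    A block enters the active set if ANY of its q columns survives the trim.
    Maximal runs of consecutive active blocks (block 1 excluded — it carries
    the baseline, not a change) each signal one change point; the window
    anchor is k_j = (last block of the run) - 1, which places the change
    point interior to the 2m window whether it falls at a block boundary
    (single-block signature) or inside a block (two-block signature).
    """
    n, m, p = plan.n, plan.m, plan.p_n
    A_hat = frozenset(colmap[j][0] for j in J_hat)
    cands = sorted(b for b in A_hat if b != 1)
    runs: list[list[int]] = []
    for b in cands:
        if runs and b == runs[-1][-1] + 1:
            runs[-1].append(b)
        else:
            runs.append([b])
    ks: list[int] = []
    for run in runs:
        k = run[-1] - 1
        if k + 1 > p:
            k = p - 1
        if k < 1:
            k = 1
        if ks and k <= ks[-1]:
            k = ks[-1] + 1  # defensive: keep anchors strictly increasing
            if k + 1 > p:
                continue
        ks.append(k)
    windows = tuple(
        (n - (p - k + 1) * m + 1, n - (p - k - 1) * m) for k in ks
    )
    return SelectedSegments(
        A_hat=A_hat, C_hat=tuple(ks), s_hat=len(ks), windows=windows
    )


def default_dn(n: int, r_n: int, scale: int = 5) -> int:
    """Greedy path cap: ceil((n / log r_n)^(1/2)) * scale, at most r_n."""
    if r_n < 2:
        return 1
    base = int(np.ceil(np.sqrt(n / np.log(r_n))))
    return int(min(r_n, base * scale))
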