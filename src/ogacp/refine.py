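"""Refinement stage: sup-Wald location scans and the full two-stage detector.

Each selected 2m window is assumed to hold exactly one change point. Within
the window {n_l..n_r} the model is y_i = x_i' beta + x_i' delta I(i > h) + e_i
and the split h is estimated by the sup-Wald argmax

    a_hat = argmax_h  delta_h' (Z_h' M Z_h) delta_h,   n_l + q < h < n_r - q,

where Z_h zeroes the rows up to h and M projects off the window regressors.
The statistic equals RSS(X) - RSS(X, Z_h) (partitioned regression), and the
augmented fit decouples into separate least squares on the pre- and post-h
rows, which is how the scan is computed (batched cumulative Gram matrices).

The block length m = ceil(c0 * sqrt(n)) is chosen by BIC over a grid of c0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .exceptions import (
    ConfigError,
    InsufficientDataError,
    InvalidBlockLengthError,
    RankDeficiencyError,
    WindowFailureError,
)
from .segmentation import (
    BlockDesign,
    RegressionSeries,
    SegmentationPlan,
    build_block_design,
    make_plan,
)
from .selection import (
    OGAPath,
    SelectedSegments,
    center_columns,
    default_dn,
    hdic_stop,
    oga_path,
    select_segments,
    trim,
)

logger = logging.getLogger(__name__)


@dataclass
class WaldScan:
    """Wald profile over candidate splits of one refinement window.

    ``h_grid`` holds absolute (1-based) candidate split indices, ``h`` being
    the last pre-change index; ``stat`` the Wald statistic at each (NaN where
    the split was numerically singular and skipped); ``argmax_h`` the
    estimated change point (ties and flat profiles resolve to the smallest h).
    """

    window: tuple[int, int]
    h_grid: np.ndarray
    stat: np.ndarray
    argmax_h: int


def _split_rss(Cxx: np.ndarray, Cxy: np.ndarray, Cyy: np.ndarray) -> np.ndarray:
    """RSS of least squares per stacked Gram system; NaN where singular."""
    out = np.full(Cyy.shape[0], np.nan)
    try:
        coef = np.linalg.solve(Cxx, Cxy[..., None])[..., 0]
        out = Cyy - np.einsum("tk,tk->t", Cxy, coef)
    except np.linalg.LinAlgError:
        for t in range(Cyy.shape[0]):
            try:
                c = np.linalg.solve(Cxx[t], Cxy[t])
                out[t] = Cyy[t] - Cxy[t] @ c
            except np.linalg.LinAlgError:
                out[t] = np.nan
    return out


def sup_wald_scan(y_w: np.ndarray, X_w: np.ndarray, q: int,
                  offset: int = 1) -> WaldScan:
    """Scan all admissible splits of a window; return the Wald profile.

    Parameters
    ----------
    y_w, X_w : window response (length w) and regressors (w x q).
    q : number of regressors.
    offset : absolute 1-based index of the window's first row, so the
        returned grid and argmax are on the global time axis.
    """
    y_w = np.asarray(y_w, dtype=float).ravel()
    X_w = np.asarray(X_w, dtype=float)
    w = y_w.size
    if w < 2 * q + 3:
        raise InsufficientDataError(f"window of {w} rows too short for q={q}")
    # local split t = number of pre-change rows; admissible t in [q+1, w-q-1]
    outer = np.einsum("ti,tj->tij", X_w, X_w)
    Cxx = np.cumsum(outer, axis=0)
    Cxy = np.cumsum(X_w * y_w[:, None], axis=0)
    Cyy = np.cumsum(y_w * y_w)
    G, b, syy = Cxx[-1], Cxy[-1], Cyy[-1]
    try:
        rss_x = float(syy - b @ np.linalg.solve(G, b))
    except np.linalg.LinAlgError as e:
        raise WindowFailureError("window regressor Gram matrix is singular") from e

    # admissible local splits: strictly more than q rows on each side
    ts = np.arange(q + 2, w - q)
    pre = _split_rss(Cxx[ts - 1], Cxy[ts - 1], Cyy[ts - 1])
    post = _split_rss(G - Cxx[ts - 1], b - Cxy[ts - 1], syy - Cyy[ts - 1])
    stat = rss_x - (pre + post)
    bad = ~np.isfinite(stat)
    if bad.all():
        raise WindowFailureError("every candidate split in window is singular")
    if bad.any():
        logger.debug("skipped %d singular splits in window at %d", bad.sum(), offset)
    stat = np.where(bad, np.nan, np.maximum(stat, 0.0))
    best = int(np.nanargmax(stat))
    h_grid = ts + offset - 1  # absolute h = last pre-change index
    return WaldScan(
        window=(offset, offset + w - 1),
        h_grid=h_grid,
        stat=stat,
        argmax_h=int(h_grid[best]),
    )


@dataclass
class ChangePointFit:
    """Result of the two-stage detection on one series.

    ``a_hat`` are the estimated change points (1-based, each the last index
    of its regime), ``k_hat`` the anchoring block indices, ``beta1_hat`` the
    first-regime coefficients and ``delta_hat`` the per-change coefficient
    increments. ``resid_centered`` has mean zero within every estimated
    segment, ready for segment-wise bootstrap resampling.
    """

    s_hat: int
    a_hat: np.ndarray
    k_hat: tuple[int, ...]
    beta1_hat: np.ndarray
    delta_hat: list[np.ndarray]
    fitted: np.ndarray
    resid_raw: np.ndarray
    resid_centered: np.ndarray
    n: int
    q: int
    m_used: Optional[int] = None
    c0_used: Optional[float] = None
    bic_value: Optional[float] = None
    scans: Optional[list[WaldScan]] = None
    path: Optional[OGAPath] = None
    segments: Optional[SelectedSegments] = None

    def segment_bounds(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each estimated segment."""
        edges = [0, *self.a_hat.tolist(), self.n]
        return [(edges[j] + 1, edges[j + 1]) for j in range(len(edges) - 1)]

    def segment_coefficients(self) -> list[np.ndarray]:
        """Cumulative regression coefficients, one q-vector per segment."""
        out = [self.beta1_hat.copy()]
        for d in self.delta_hat:
            out.append(out[-1] + d)
        return out


def piecewise_design(X: np.ndarray, a_hat: Sequence[int]) -> np.ndarray:
    """Stack [X, X*I(i > a_1), ..., X*I(i > a_s)] for 1-based change points."""
    n = X.shape[0]
    idx = np.arange(1, n + 1)
    parts = [X] + [X * (idx > a)[:, None] for a in a_hat]
    return np.hstack(parts)


def fit_piecewise(series: RegressionSeries, a_hat: Sequence[int],
                  k_hat: Sequence[int] = ()) -> ChangePointFit:
    """Least-squares fit of the piecewise model at fixed change points.

    Residuals are centered within each estimated segment {a_{j-1}+1..a_j}
    (with a_0 = 0 and a_{s+1} = n), the construction the residual bootstrap
    resamples from.
    """
    a_hat = sorted(int(a) for a in a_hat)
    n, q = series.n, series.q
    for a in a_hat:
        if not 1 <= a < n:
            raise ConfigError(f"change point {a} outside 1..{n - 1}")
    if len(set(a_hat)) != len(a_hat):
        raise ConfigError("change points must be distinct")
    D = piecewise_design(series.X, a_hat)
    coef, _, rank, _ = np.linalg.lstsq(D, series.y, rcond=None)
    if rank < D.shape[1]:
        edges = [0, *a_hat, n]
        for j in range(len(edges) - 1):
            seg = series.X[edges[j] : edges[j + 1]]
            if np.linalg.matrix_rank(seg) < q:
                raise RankDeficiencyError(
                    f"segment {j + 1} ({edges[j] + 1}..{edges[j + 1]}) is rank deficient"
                )
        raise RankDeficiencyError("piecewise design is rank deficient")
    fitted = D @ coef
    resid = series.y - fitted
    centered = resid.copy()
    edges = [0, *a_hat, n]
    for j in range(len(edges) - 1):
        sl = slice(edges[j], edges[j + 1])
        centered[sl] -= centered[sl].mean()
    s = len(a_hat)
    return ChangePointFit(
        s_hat=s,
        a_hat=np.asarray(a_hat, dtype=int),
        k_hat=tuple(k_hat),
        beta1_hat=coef[:q].copy(),
        delta_hat=[coef[q * (j + 1) : q * (j + 2)].copy() for j in range(s)],
        fitted=fitted,
        resid_raw=resid,
        resid_centered=centered,
        n=n,
        q=q,
    )


class PipelineState:
    """Precomputed segmentation and centered design for one (series, m) pair.

    The block design depends only on X and m, so the bootstrap — which fixes
    the segmentation and reruns selection + refinement on resampled
    responses — reuses one state across all replicates.
    """

    def __init__(self, series: RegressionSeries, m: int, config: RunConfig):
        n, q = series.n, series.q
        if m < 2 * q + 3:
            raise InvalidBlockLengthError(
                f"refinement needs m >= 2q+3 = {2 * q + 3}, got m={m}"
            )
        self.series = series
        self.config = config
        self.plan: SegmentationPlan = make_plan(n, m)
        self.design: BlockDesign = build_block_design(series, self.plan)
        _, self.Zc, self.usable = center_columns(series.y, self.design.Z)
        self.r_n = self.design.Z.shape[1]
        self.D_n = default_dn(n, self.r_n, config.dn_scale)

    def select(self, y: np.ndarray) -> tuple[SelectedSegments, OGAPath]:
        """OGA + HDIC + Trim + block mapping for one response vector."""
        yc = y - y.mean()
        path = oga_path(yc, self.Zc, self.D_n, self.usable)
        hdic_stop(path, yc, self.Zc, self.config.cn, self.r_n)
        trim(path, yc, self.Zc, self.config.cn, self.r_n)
        seg = select_segments(path.J_hat, self.design.colmap, self.plan,
                              self.series.q)
        return seg, path

    def locate(self, y: np.ndarray, windows) -> tuple[list[int], list[WaldScan]]:
        """Sup-Wald argmax within each window, on the given response."""
        a_hats, scans = [], []
        for lo, hi in windows:
            scan = sup_wald_scan(y[lo - 1 : hi], self.series.X[lo - 1 : hi],
                                 self.series.q, offset=lo)
            a_hats.append(scan.argmax_h)
            scans.append(scan)
        return a_hats, scans


def _bic(rss: float, n: int, s: int, q: int, variant: str) -> float:
    rss = max(rss, 1e-300)
    if variant == "unscaled":
        return float(np.log(rss) + s * q * np.log(n))
    return float(n * np.log(rss / n) + s * q * np.log(n))


def detect_with_m(series: RegressionSeries, m: int,
                  config: Optional[RunConfig] = None) -> ChangePointFit:
    """Run the two-stage detector at a fixed block length m."""
    config = config or RunConfig()
    n, q = series.n, series.q
    if n < 4 * q + 4:
        raise InsufficientDataError(f"need n >= 4q+4 = {4 * q + 4}, got {n}")
    state = PipelineState(series, m, config)
    seg, path = state.select(series.y)
    a_hats, scans = state.locate(series.y, seg.windows)
    fit = fit_piecewise(series, a_hats, k_hat=seg.C_hat)
    fit.m_used = m
    fit.bic_value = _bic(float(fit.resid_raw @ fit.resid_raw), n, fit.s_hat, q,
                         config.bic_variant)
    fit.segments = seg
    if config.trace:
        fit.scans = scans
        fit.path = path
    return fit


def candidate_block_lengths(n: int, q: int, c0_values: np.ndarray) -> list[tuple[float, int]]:
    """Admissible (c0, m) pairs: m = ceil(c0 sqrt(n)), deduplicated, valid."""
    out: list[tuple[float, int]] = []
    seen: set[int] = set()
    for c0 in np.sort(np.asarray(c0_values, dtype=float)):
        m = int(np.ceil(c0 * np.sqrt(n)))
        if m in seen:
            continue
        if m < 2 * q + 3 or 2 * m >= n:
            continue
        seen.add(m)
        out.append((float(c0), m))
    return out


def select_m(series: RegressionSeries, c0_grid: np.ndarray,
             config: Optional[RunConfig] = None) -> ChangePointFit:
    """Pick the block length by BIC over the c0 grid; return the best fit.

    Ties resolve to the smallest m. Grid points whose implied m is
    inadmissible for this (n, q) are skipped; if every point fails the last
    error is raised.
    """
    config = config or RunConfig()
    c0_grid = np.asarray(c0_grid, dtype=float)
    if c0_grid.size == 0:
        raise ConfigError("empty c0 grid")
    cands = candidate_block_lengths(series.n, series.q, c0_grid)
    if not cands:
        raise ConfigError(
            f"no admissible block length for n={series.n}, q={series.q}"
        )
    best: Optional[ChangePointFit] = None
    last_err: Optional[Exception] = None
    for c0, m in cands:
        try:
            fit = detect_with_m(series, m, config)
        except (WindowFailureError, RankDeficiencyError) as e:
            logger.debug("c0=%.2f (m=%d) failed: %s", c0, m, e)
            last_err = e
            continue
        fit.c0_used = c0
        if best is None or fit.bic_value < best.bic_value:
            best = fit
    if best is None:
        assert last_err is not None
        raise last_err
    return best


def detect(series: RegressionSeries,
           config: Optional[RunConfig] = None) -> ChangePointFit:
    """Full two-stage change-point detection.

    Cut the series into blocks, select change-bearing blocks by
    OGA + HDIC + Trim on the cumulative block design, refine each selected
    2m window by the sup-Wald argmax, and fit the final piecewise model.
    The block length is fixed by ``config.m`` when given, otherwise chosen
    by BIC over the c0 grid. A fit with no change points (s_hat = 0) is a
    valid outcome.
    """
    config = config or RunConfig()
    if series.n < 4 * series.q + 4:
        raise InsufficientDataError(
            f"need n >= 4q+4 = {4 * series.q + 4}, got {series.n}"
        )
    if config.m is not None:
        return detect_with_m(series, config.m, config)
    return select_m(series, config.c0_values(), config)
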