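"""Segment-wise centered residual bootstrap for change-point locations.

Responses are regenerated as y*_i = fitted_i + e*_i, where e*_i is drawn
i.i.d. with replacement from the centered residuals OF THE ESTIMATED SEGMENT
containing i (conditional mean zero by construction). The two-stage detector
is rerun on each y* with the segmentation (block length m) held fixed; a
bootstrap change point is matched to an original one when it anchors to the
same block, and the empirical quantiles of the matched location differences
a*_j - a_hat_j give percentile confidence intervals. Joint (simultaneous)
intervals use a Bonferroni split of the level across the detected points.

The design rows x_i are kept as observed even when a column is a lagged
response (fixed-design bootstrap); ``recursive=True`` re-propagates lagged
columns from the regenerated responses for AR designs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .exceptions import (
    DegenerateSegmentError,
    NothingToBootstrapError,
    WindowFailureError,
)
from .refine import ChangePointFit, PipelineState
from .segmentation import RegressionSeries

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Matched bootstrap locations and the intervals built from them.

    ``diffs[j]`` holds a*_j - a_hat_j over the replicates in which change
    point j had a matched bootstrap counterpart; ``B_star[j]`` is that
    effective count. ``ci[j]`` is the integer interval at the working level
    (alpha, or alpha/s_hat under Bonferroni), or None when no replicate
    matched.
    """

    B: int
    alpha: float
    bonferroni: bool
    a_hat: np.ndarray
    diffs: list[np.ndarray]
    B_star: list[int]
    ci: list[Optional[tuple[int, int]]]
    level_per_point: float

    def intervals_at(self, alpha: float, n: Optional[int] = None,
                     bonferroni: bool = False) -> list[Optional[tuple[int, int]]]:
        """Rebuild per-point intervals at another level from the same diffs."""
        lvl = alpha / len(self.a_hat) if bonferroni and len(self.a_hat) else alpha
        return [
            build_ci(int(a), d, lvl, n=n) if d.size else None
            for a, d in zip(self.a_hat, self.diffs)
        ]


def make_bootstrap_sample(fit: ChangePointFit, series: RegressionSeries,
                          rng: np.random.Generator,
                          recursive: bool = False,
                          lagged_cols: Optional[dict[int, int]] = None) -> np.ndarray:
    """Draw one bootstrap response vector from the fitted piecewise model.

    Within each estimated segment, residuals are resampled with replacement
    from that segment's centered residuals; the fitted mean keeps x_i as
    observed. With ``recursive`` and a ``lagged_cols`` map {column: lag},
    lagged-response columns are instead rebuilt from the regenerated y*.
    """
    eps_star = np.empty(fit.n)
    for lo, hi in fit.segment_bounds():
        seg = fit.resid_centered[lo - 1 : hi]
        if seg.size < 2:
            raise DegenerateSegmentError(
                f"segment {lo}..{hi} has {seg.size} residual(s); cannot resample"
            )
        eps_star[lo - 1 : hi] = rng.choice(seg, size=seg.size, replace=True)
    if not recursive:
        return fit.fitted + eps_star
    if not lagged_cols:
        raise ValueError("recursive regeneration requires lagged_cols")
    # re-propagate the recursion: y*_t depends on regenerated lagged values
    coefs = fit.segment_coefficients()
    edges = [0, *fit.a_hat.tolist(), fit.n]
    y_star = np.empty(fit.n)
    x = series.X.copy()
    seg_idx = 0
    for t in range(fit.n):
        while t + 1 > edges[seg_idx + 1]:
            seg_idx += 1
        for c, lag in lagged_cols.items():
            if t - lag >= 0:
                x[t, c] = y_star[t - lag]
        y_star[t] = x[t] @ coefs[seg_idx] + eps_star[t]
    return y_star


def bootstrap_replicate(y_star: np.ndarray, series: RegressionSeries,
                        fit: ChangePointFit,
                        config: Optional[RunConfig] = None,
                        state: Optional[PipelineState] = None,
                        match_slack: int = 0) -> list[Optional[int]]:
    """Rerun selection + refinement on one bootstrap response.

    The segmentation is kept at the original block length. Each original
    change point j is matched to the bootstrap detection anchored at the
    same block index (``match_slack`` allows near-miss anchors within that
    many blocks; default exact); the refined location a*_j is returned per
    j, or None when no anchoring block was selected in this replicate.
    """
    config = config or RunConfig()
    if state is None:
        state = PipelineState(series, int(fit.m_used), config)
    out: list[Optional[int]] = [None] * fit.s_hat
    try:
        seg, _ = state.select(np.asarray(y_star, dtype=float))
    except Exception as e:  # failed replicates count as unmatched
        logger.debug("bootstrap replicate selection failed: %s", e)
        return out
    boot_by_block = dict(zip(seg.C_hat, seg.windows))
    for j, k in enumerate(fit.k_hat):
        win = boot_by_block.get(k)
        if win is None and match_slack:
            near = [kk for kk in boot_by_block if abs(kk - k) <= match_slack]
            if near:
                win = boot_by_block[min(near, key=lambda kk: abs(kk - k))]
        if win is None:
            continue
        try:
            a_list, _ = state.locate(np.asarray(y_star, dtype=float), [win])
        except WindowFailureError:
            continue
        out[j] = a_list[0]
    return out


def _empirical_quantile(diffs: np.ndarray, p: float) -> float:
    # inverse-ECDF (order statistic) quantile: attained sample values only
    return float(np.quantile(diffs, p, method="inverted_cdf"))


def build_ci(a_hat_j: int, diffs: Sequence[int], alpha: float,
             n: Optional[int] = None) -> tuple[int, int]:
    """Percentile interval for one change point from matched differences.

    [a_hat + Q_{alpha/2}(diffs), a_hat + Q_{1-alpha/2}(diffs)], endpoints
    rounded outward to integers and clipped to [1, n] when n is given.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise NothingToBootstrapError("no matched replicates for this change point")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lo = a_hat_j + _empirical_quantile(diffs, alpha / 2)
    hi = a_hat_j + _empirical_quantile(diffs, 1 - alpha / 2)
    lo_i, hi_i = math.floor(lo), math.ceil(hi)
    if n is not None:
        lo_i = max(1, min(lo_i, n))
        hi_i = max(1, min(hi_i, n))
    return lo_i, hi_i


def bootstrap_cis(series: RegressionSeries, fit: ChangePointFit,
                  B: int = 500, alpha: float = 0.05,
                  bonferroni: bool = False,
                  rng: Optional[np.random.Generator] = None,
                  config: Optional[RunConfig] = None,
                  match_slack: int = 0,
                  recursive: bool = False,
                  lagged_cols: Optional[dict[int, int]] = None
                  ) -> BootstrapResult:
    """B-replicate residual bootstrap and percentile intervals per point.

    Replicate b uses a generator seeded from a deterministic substream of
    ``rng``, so results do not depend on execution order or worker count.
    With ``recursive`` and a ``lagged_cols`` map, lagged-response columns
    are re-propagated from each regenerated response (AR designs).
    """
    if fit.s_hat < 1:
        raise NothingToBootstrapError("fit has no change points to bootstrap")
    config = config or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state = PipelineState(series, int(fit.m_used), config)
    child_seeds = rng.integers(0, 2**31 - 1, size=B)
    diffs: list[list[int]] = [[] for _ in range(fit.s_hat)]
    for b in range(B):
        sub = np.random.default_rng(int(child_seeds[b]))
        y_star = make_bootstrap_sample(fit, series, sub, recursive=recursive,
                                       lagged_cols=lagged_cols)
        rep_state = state
        rep_series = series
        if recursive:
            # the replicate's lagged columns must reflect the regenerated y*
            X_star = series.X.copy()
            for c, lag in (lagged_cols or {}).items():
                X_star[lag:, c] = y_star[:-lag]
            rep_series = RegressionSeries(y=y_star, X=X_star)
            rep_state = PipelineState(rep_series, int(fit.m_used), config)
        matched = bootstrap_replicate(y_star, rep_series, fit, config,
                                      state=rep_state, match_slack=match_slack)
        for j, a_star in enumerate(matched):
            if a_star is not None:
                diffs[j].append(a_star - int(fit.a_hat[j]))
    level = alpha / fit.s_hat if bonferroni else alpha
    diff_arrays = [np.asarray(d, dtype=int) for d in diffs]
    cis: list[Optional[tuple[int, int]]] = []
    for j in range(fit.s_hat):
        if diff_arrays[j].size == 0:
            logger.warning("change point %d: no matched bootstrap replicates", j + 1)
            cis.append(None)
        else:
            cis.append(build_ci(int(fit.a_hat[j]), diff_arrays[j], level, n=fit.n))
    return BootstrapResult(
        B=B,
        alpha=alpha,
        bonferroni=bonferroni,
        a_hat=fit.a_hat.copy(),
        diffs=diff_arrays,
        B_star=[int(d.size) for d in diff_arrays],
        ci=cis,
        level_per_point=level,
    )
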