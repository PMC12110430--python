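"""Run configuration shared by the detection, bootstrap and simulation drivers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .exceptions import ConfigError


@dataclass
class RunConfig:
    """Tuning parameters of the two-stage detector and its bootstrap.

    Parameters
    ----------
    cn : float
        Penalty multiplier c_n of the high-dimensional information criterion
        HDIC(J) = log sigma^2_J + |J| c_n log(r_n)/n. Default 2 (AIC-like).
    dn_scale : int
        The greedy path is capped at D_n = min(#usable columns,
        ceil((n / log r_n)^(1/2)) * dn_scale).
    c0_grid : tuple of float
        (start, stop, step) for the block-length constant c0; candidate block
        lengths are m = ceil(c0 * sqrt(n)). Grid must lie within [0.1, 1.5].
    bic_variant : str
        "scaled" uses n*log(RSS/n) + s*q*log(n) to pick m; "unscaled" uses
        log(RSS) + s*q*log(n).
    m : int, optional
        Fixed block length; when set, the c0 grid is bypassed.
    B : int
        Bootstrap replicate count.
    alpha : float
        Confidence level complement for bootstrap intervals.
    bonferroni : bool
        Build joint intervals at level alpha / s_hat per change point.
    seed : int, optional
        Seed for stochastic commands.
    ar_order : int, optional
        Build a lagged autoregressive design of this order from a univariate
        series.
    trace : bool
        Retain per-window Wald profiles and the greedy path for debugging.
    """

    cn: float = 2.0
    dn_scale: int = 5
    c0_grid: tuple[float, float, float] = (0.1, 1.5, 0.1)
    bic_variant: str = "scaled"
    m: Optional[int] = None
    B: int = 500
    alpha: float = 0.05
    bonferroni: bool = False
    seed: Optional[int] = None
    ar_order: Optional[int] = None
    trace: bool = False

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ConfigError("cn must be nonnegative")
        if self.dn_scale < 1:
            raise ConfigError("dn_scale must be a positive integer")
        if self.bic_variant not in ("scaled", "unscaled"):
            raise ConfigError("bic_variant must be 'scaled' or 'unscaled'")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.B < 1:
            raise ConfigError("B must be positive")
        start, stop, step = self.c0_grid
        if step <= 0 or stop < start:
            raise ConfigError("c0_grid must be (start, stop, step) with step > 0")
        if start < 0.1 - 1e-12 or stop > 1.5 + 1e-12:
            raise ConfigError("c0 grid must lie within [0.1, 1.5]")

    def c0_values(self) -> np.ndarray:
        """Expand the (start, stop, step) triple into grid points (inclusive)."""
        start, stop, step = self.c0_grid
        k = int(round((stop - start) / step))
        vals = start + step * np.arange(k + 1)
        vals = vals[vals <= stop + 1e-9]
        if vals.size == 0:
            raise ConfigError("empty c0 grid")
        return np.round(vals, 10)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c0_grid"] = list(self.c0_grid)
        return d
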