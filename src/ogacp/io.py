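"""CSV reading and JSON result writing."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapResult
from .config import RunConfig
from .exceptions import ParseError
from .refine import ChangePointFit
from .segmentation import RegressionSeries, lagged_design

RESULTS_SCHEMA_VERSION = 1


def read_series(path, ar_order: Optional[int] = None) -> RegressionSeries:
    """Read an ordered regression series from CSV.

    Expected layout: header row with columns ``t, y, x1..xq``; or a
    single-column ``y`` series (optionally with ``t``) together with
    ``ar_order``, in which case an AR(ar_order) lagged design is built.
    Rows are sorted by ``t``; duplicated or gapped ``t`` is rejected.
    """
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"cannot read {path}: {e}") from e
    cols = list(df.columns)
    if "y" not in cols:
        raise ParseError(f"{path}: missing required column 'y'")
    for c in df.columns:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any() or df[c].isna().any():
            row = int(np.argmax((bad | df[c].isna()).to_numpy())) + 2  # +header
            raise ParseError(f"{path}: non-numeric or missing value in "
                             f"column {c!r} at row {row}")
    if "t" in cols:
        df = df.sort_values("t", kind="stable").reset_index(drop=True)
        t = df["t"].to_numpy()
        if np.any(np.diff(t) == 0):
            row = int(np.argmax(np.diff(t) == 0)) + 2
            raise ParseError(f"{path}: duplicated t at row {row}")
        if np.any(np.diff(t) != 1):
            row = int(np.argmax(np.diff(t) != 1)) + 2
            raise ParseError(f"{path}: gapped t index at row {row}")
    y = df["y"].to_numpy(dtype=float)
    xcols = [c for c in cols if c not in ("t", "y")]
    if ar_order is not None:
        if xcols:
            raise ParseError(
                f"{path}: AR design requested but regressor columns present"
            )
        return lagged_design(y, ar_order)
    if not xcols:
        raise ParseError(f"{path}: no regressor columns x1..xq and no AR order")
    expected = [f"x{i}" for i in range(1, len(xcols) + 1)]
    if xcols != expected:
        raise ParseError(f"{path}: regressors must be named {expected}, got {xcols}")
    X = df[xcols].to_numpy(dtype=float)
    return RegressionSeries(y=y, X=X)


def write_series(series: RegressionSeries, path) -> None:
    """Write a series as CSV with columns t, y, x1..xq."""
    df = pd.DataFrame({"t": series.index, "y": series.y})
    for c in range(series.q):
        df[f"x{c + 1}"] = series.X[:, c]
    df.to_csv(path, index=False)


def results_dict(fit: ChangePointFit, boot: Optional[BootstrapResult],
                 config: Optional[RunConfig]) -> dict:
    ci90 = boot.intervals_at(0.10, n=fit.n) if boot is not None else [None] * fit.s_hat
    ci95 = boot.intervals_at(0.05, n=fit.n) if boot is not None else [None] * fit.s_hat
    k_hat = list(fit.k_hat) if fit.k_hat else [None] * fit.s_hat
    change_points = [
        {
            "a_hat": int(fit.a_hat[j]),
            "block": int(k_hat[j]) if k_hat[j] is not None else None,
            "ci_90": list(ci90[j]) if ci90[j] is not None else None,
            "ci_95": list(ci95[j]) if ci95[j] is not None else None,
        }
        for j in range(fit.s_hat)
    ]
    trace = None
    if fit.scans is not None or fit.path is not None:
        trace = {}
        if fit.path is not None:
            trace["selected_columns"] = [int(j) for j in fit.path.selected]
            trace["hdic"] = [float(v) for v in np.asarray(fit.path.hdic)]
            trace["trimmed"] = [int(j) for j in fit.path.J_hat]
        if fit.scans is not None:
            trace["windows"] = [
                {
                    "window": list(sc.window),
                    "h": sc.h_grid.tolist(),
                    "stat": [None if not np.isfinite(v) else float(v)
                             for v in sc.stat],
                }
                for sc in fit.scans
            ]
    return {
        "version": RESULTS_SCHEMA_VERSION,
        "trace": trace,
        "package_version": __version__,
        "n": fit.n,
        "q": fit.q,
        "m_used": fit.m_used,
        "c0_used": fit.c0_used,
        "s_hat": fit.s_hat,
        "bic": fit.bic_value,
        "change_points": change_points,
        "B_star": boot.B_star if boot is not None else None,
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
    }


def write_results(fit: ChangePointFit, boot: Optional[BootstrapResult],
                  path, config: Optional[RunConfig] = None) -> None:
    """Write detection (and optional bootstrap) results as versioned JSON."""
    payload = results_dict(fit, boot, config)
    text = json.dumps(payload, indent=2, sort_keys=True)
    Path(path).write_text(text + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
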