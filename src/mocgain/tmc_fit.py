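"""Least-squares estimation of cochlear IO-model parameters from TMCs.

The six without-elicitor parameters (G_max, c, BP_ctr, k, mu, P) are
estimated by minimizing the sum of squared differences between observed and
predicted on- and off-frequency masking thresholds (bounded nonlinear least
squares with a fixed multistart lattice).  The with-elicitor data are then
fitted by varying a single additional parameter, the gain reduction dG
(sign-unconstrained), with all other parameters — including the break
points — carried over from the baseline fit; the with-elicitor compression
exponent c_tilde follows from the fixed-break-point constraint.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_model import (
    CochlearIOParams,
    ElicitorEffect,
    MaskingContext,
    predict_tmc,
)

__all__ = [
    "TMC_COLUMNS",
    "FitResult",
    "validate_tmc_table",
    "fit_baseline",
    "fit_elicitor",
    "fit_subject",
    "rmsd",
    "predict_missing_off_tmc",
    "read_tmc_table",
    "write_tmc_table",
    "fit_report",
]

TMC_COLUMNS = [
    "subject_id",
    "gap_ms",
    "masker",
    "elicitor",
    "threshold_db_spl",
    "signal_level_db_spl",
]

# parameter bounds: generous supersets of values reported for
# normal-hearing listeners
BOUNDS_LO = np.array([0.0, 1e-3, 10.0, 0.05, 0.01, -20.0])
BOUNDS_HI = np.array([60.0, 0.999, 90.0, 20.0, 3.0, 60.0])
DELTA_G_BOUNDS = (-30.0, 60.0)

# fixed multistart lattice: 3 levels each of (G_max, c, BP_ctr) crossed
# with central (k, mu, P); ties broken by lattice order
_START_G_MAX = (10.0, 25.0, 40.0)
_START_C = (0.1, 0.3, 0.6)
_START_BP_CTR = (30.0, 45.0, 60.0)
_START_K, _START_MU, _START_P = 1.5, 0.5, 20.0
_DELTA_G_STARTS = (-5.0, 0.0, 5.0, 15.0, 30.0)

FTOL = XTOL = GTOL = 1e-10
MAX_NFEV = 2000

#: P used when no off-frequency rows identify the passive attenuation.
DEFAULT_FIXED_P = 20.0


@dataclass
class FitResult:
    """Best-fitting model for one subject and condition set."""

    params: CochlearIOParams
    ctx: MaskingContext
    effect: Optional[ElicitorEffect]
    rmsd_db: float
    sse: float
    n_points: int
    converged: bool
    n_starts_used: int
    p_fixed: bool = False

    @property
    def record(self) -> dict:
        """Parameter-table row (reference-table column names)."""
        rec = {
            "G_max": self.params.g_max,
            "c": self.params.c,
            "BP_ctr": self.params.bp_ctr,
            "k": self.ctx.k,
            "mu": self.ctx.mu,
            "P": self.params.p,
            "dG": self.effect.delta_g if self.effect else np.nan,
            "c_tilde": self.effect.c_tilde if self.effect else np.nan,
            "rmsd_dB": self.rmsd_db,
            "converged": self.converged,
        }
        return rec


def validate_tmc_table(df: pd.DataFrame) -> None:
    """Check schema and uniqueness of gaps within each condition cell."""
    missing = [c for c in TMC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TMC table missing columns: {missing}")
    if not df["masker"].isin(["on", "off"]).all():
        raise ValueError("masker must be 'on' or 'off'")
    if not df["elicitor"].isin(["with", "without"]).all():
        raise ValueError("elicitor must be 'with' or 'without'")
    for key, cell in df.groupby(["subject_id", "masker", "elicitor"]):
        if cell["gap_ms"].duplicated().any():
            raise ValueError(f"duplicate gaps in cell {key}")


def rmsd(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square deviation between aligned threshold sequences (dB)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("sequences must be aligned and non-empty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _multistart(residuals, starts, bounds):
    """Bounded least squares from each start; best SSE wins.

    The piecewise-linear model gives non-smooth residuals, so a start can
    crawl along a kink until the evaluation budget runs out while sitting
    at the minimum.  The fit is reported as converged when the best SSE is
    corroborated (within 1 % relative) by a start that terminated on a
    tolerance criterion.
    """
    best = None
    results = []
    n_starts = 0
    for x0 in starts:
        sol = least_squares(
            residuals,
            np.asarray(x0, dtype=float),
            bounds=bounds,
            ftol=FTOL,
            xtol=XTOL,
            gtol=GTOL,
            max_nfev=MAX_NFEV,
        )
        n_starts += 1
        sse = float(2.0 * sol.cost)
        results.append((sse, sol.status))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol)
        if best[0] < 1e-16:  # exact fit; later starts cannot improve
            break
    sse, sol = best
    converged = any(
        status > 0 and s <= sse * 1.01 + 1e-12 for s, status in results
    )
    return sse, sol, converged, n_starts


def _signal_level(df: pd.DataFrame) -> float:
    levels = df["signal_level_db_spl"].unique()
    if len(levels) != 1:
        raise ValueError("signal level must be constant within a fit")
    return float(levels[0])


def _split_cells(df: pd.DataFrame):
    on = df[df["masker"] == "on"]
    off = df[df["masker"] == "off"]
    return (
        on["gap_ms"].to_numpy(float),
        on["threshold_db_spl"].to_numpy(float),
        off["gap_ms"].to_numpy(float),
        off["threshold_db_spl"].to_numpy(float),
    )


def fit_baseline(
    data: pd.DataFrame, fixed_p: float = DEFAULT_FIXED_P
) -> FitResult:
    """Fit the six baseline parameters to without-elicitor thresholds.

    ``data`` holds one subject's without-elicitor rows (on-frequency
    required, off-frequency optional).  Without off-frequency rows the
    passive attenuation P is unidentifiable; it is then held at ``fixed_p``
    and the result flagged (``p_fixed``).
    """
    validate_tmc_table(data)
    if (data["elicitor"] == "with").any():
        raise ValueError("fit_baseline expects without-elicitor rows only")
    l_s = _signal_level(data)
    on_g, on_t, off_g, off_t = _split_cells(data)
    if on_g.size < 3:
        raise ValueError("need at least 3 on-frequency rows")
    if 0 < off_g.size < 2:
        raise ValueError("need at least 2 off-frequency rows when present")
    p_fixed = off_g.size == 0

    def residuals(theta: np.ndarray) -> np.ndarray:
        g_max, c, bp_ctr, k, mu, p = theta
        params = CochlearIOParams.from_bp_ctr(g_max, min(c, 0.999), bp_ctr, p)
        ctx = MaskingContext(l_s=l_s, k=k, mu=mu)
        res = [predict_tmc(params, ctx, on_g, "on") - on_t]
        if off_g.size:
            res.append(predict_tmc(params, ctx, off_g, "off") - off_t)
        return np.concatenate(res)

    lo, hi = BOUNDS_LO.copy(), BOUNDS_HI.copy()
    starts = []
    for g0, c0, b0 in itertools.product(_START_G_MAX, _START_C, _START_BP_CTR):
        x0 = np.array([g0, c0, b0, _START_K, _START_MU, _START_P])
        if p_fixed:
            x0[5] = fixed_p
            lo[5] = fixed_p - 1e-12
            hi[5] = fixed_p + 1e-12
        starts.append(x0)
    sse, sol, converged, n_starts = _multistart(
        residuals, starts, (lo, hi)
    )
    g_max, c, bp_ctr, k, mu, p = sol.x
    params = CochlearIOParams.from_bp_ctr(g_max, min(c, 0.999), bp_ctr, p)
    ctx = MaskingContext(l_s=l_s, k=k, mu=mu)
    n_points = on_g.size + off_g.size
    return FitResult(
        params=params,
        ctx=ctx,
        effect=None,
        rmsd_db=math.sqrt(sse / n_points),
        sse=sse,
        n_points=n_points,
        converged=converged,
        n_starts_used=n_starts,
        p_fixed=p_fixed,
    )


def fit_elicitor(data: pd.DataFrame, baseline: FitResult) -> FitResult:
    """Fit the gain reduction dG to with-elicitor thresholds.

    All baseline parameters are carried over; only dG varies
    (sign-unconstrained).  Works with on-frequency rows alone: the
    off-frequency elicitor effect is a uniform dG shift, so omitting off
    rows leaves the estimate unchanged on noise-free data.
    """
    validate_tmc_table(data)
    if (data["elicitor"] == "without").any():
        raise ValueError("fit_elicitor expects with-elicitor rows only")
    if not baseline.converged:
        raise ValueError("baseline fit did not converge")
    if len(data) == 0:
        raise ValueError("no with-elicitor rows")
    on_g, on_t, off_g, off_t = _split_cells(data)
    params, ctx = baseline.params, baseline.ctx

    def residuals(theta: np.ndarray) -> np.ndarray:
        effect = ElicitorEffect.from_params(params, float(theta[0]))
        res = []
        if on_g.size:
            res.append(predict_tmc(params, ctx, on_g, "on", effect) - on_t)
        if off_g.size:
            res.append(predict_tmc(params, ctx, off_g, "off", effect) - off_t)
        return np.concatenate(res)

    sse, sol, converged, n_starts = _multistart(
        residuals,
        [np.array([dg0]) for dg0 in _DELTA_G_STARTS],
        ([DELTA_G_BOUNDS[0]], [DELTA_G_BOUNDS[1]]),
    )
    effect = ElicitorEffect.from_params(params, float(sol.x[0]))
    n_points = on_g.size + off_g.size
    return FitResult(
        params=params,
        ctx=ctx,
        effect=effect,
        rmsd_db=math.sqrt(sse / n_points),
        sse=sse,
        n_points=n_points,
        converged=converged,
        n_starts_used=n_starts,
        p_fixed=baseline.p_fixed,
    )


def fit_subject(
    data: pd.DataFrame, fixed_p: float = DEFAULT_FIXED_P
) -> FitResult:
    """Baseline + elicitor fit for one subject's full TMC table."""
    without = data[data["elicitor"] == "without"]
    baseline = fit_baseline(without, fixed_p=fixed_p)
    with_rows = data[data["elicitor"] == "with"]
    if len(with_rows) == 0:
        return baseline
    elicitor = fit_elicitor(with_rows, baseline)
    # combined goodness of fit over all rows
    sse = baseline.sse + elicitor.sse
    n = baseline.n_points + elicitor.n_points
    return FitResult(
        params=baseline.params,
        ctx=baseline.ctx,
        effect=elicitor.effect,
        rmsd_db=math.sqrt(sse / n),
        sse=sse,
        n_points=n,
        converged=baseline.converged and elicitor.converged,
        n_starts_used=baseline.n_starts_used + elicitor.n_starts_used,
        p_fixed=baseline.p_fixed,
    )


def predict_missing_off_tmc(
    baseline: FitResult,
    gaps_ms: Sequence[float],
    effect: Optional[ElicitorEffect] = None,
) -> np.ndarray:
    """Model-predicted off-frequency TMC for an unmeasured condition.

    Used for reduced designs that omit the with-elicitor off-frequency
    cell: the inferred with-elicitor IO function is then constructed from
    the model's predicted (linear, slope-mu) off-frequency curve.
    """
    if not baseline.converged:
        raise ValueError("baseline fit did not converge")
    return predict_tmc(baseline.params, baseline.ctx, gaps_ms, "off", effect)


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_tmc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_tmc_table(df)
    return df


def write_tmc_table(df: pd.DataFrame, path, header_comment: str = "") -> None:
    validate_tmc_table(df)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def fit_report(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Parameter table (one row per subject) plus an appended median row."""
    rows = []
    for subject_id, fit in fits.items():
        rows.append({"subject_id": subject_id, **fit.record})
    df = pd.DataFrame(rows)
    if len(df):
        med = df.drop(columns=["subject_id", "converged"]).median(
            numeric_only=True
        )
        df = pd.concat(
            [df, pd.DataFrame([{"subject_id": "median", **med.to_dict()}])],
            ignore_index=True,
        )
    return df
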