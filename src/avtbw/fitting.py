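"""Psychometric fits for simultaneity-judgement curves.

Two models are fitted per subject and condition, by bounded nonlinear least
squares on the proportion-synchronous curve:

* Gaussian  ``y = a * exp(-((x - b) / c)**2)`` over the full SOA range.
  ``b`` is the point of subjective simultaneity (PSS); ``c`` is the curve
  width reported as the temporal binding window (TBW). The amplitude is
  bounded above at 1 (a proportion cannot exceed it); ``b`` and ``c`` are
  otherwise free. Note the exponent carries no factor of 2, so ``c`` is the
  1/e half-width of the curve, not a standard deviation in the conventional
  parameterization; it is reported as the TBW exactly as fitted.

* Logistic  ``y = 1 / (1 + exp(b * (t - x)))`` fitted separately on the
  auditory-leading half (SOAs -500..0 ms) and the visual-leading half
  (0..+500 ms), with SOA 0 in both. The slope ``b`` is sign-bounded per
  side (AL: b >= 0, VL: b <= 0) and ``t`` is unconstrained; slopes and
  thresholds are reported as absolute values. ``t`` is the inflection point
  of the curve (the model value there is 0.5 for any slope).

Goodness of fit uses the Wherry adjusted R-squared; subjects are excluded
from downstream summaries when adjusted R-squared falls below .5 (Gaussian)
or below .3 on either logistic side. Both thresholds are strict: a subject
sitting exactly on the threshold is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .coding import SJCurve
from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "GaussianFit",
    "LogisticFit",
    "GAUSSIAN_BOUNDS",
    "gaussian_model",
    "logistic_model",
    "adjusted_r2",
    "fit_gaussian",
    "fit_logistic",
    "fit_subject",
    "apply_exclusion",
    "summarize_by_condition",
]

GAUSS_R2_THRESHOLD = 0.5
LOGISTIC_R2_THRESHOLD = 0.3

# (lower, upper) per parameter; lower bounds on a and c avoid degenerate
# zero-amplitude or spike solutions and are artifact choices.
GAUSSIAN_BOUNDS = {"a": (0.01, 1.0), "b": (-1000.0, 1000.0), "c": (1.0, 2000.0)}
LOGISTIC_T_BOUNDS = (-1000.0, 1000.0)
_GAUSS_C_STARTS = (150.0, 300.0, 450.0)
_LOGISTIC_B_STARTS = (0.002, 0.01, 0.05, 0.3)
_LOGISTIC_T_EXTRA_STARTS = (-250.0, 0.0, 250.0)


def gaussian_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-(((np.asarray(x, dtype=float) - b) / c) ** 2))


def logistic_model(x: np.ndarray, b: float, t: float) -> np.ndarray:
    z = np.clip(b * (t - np.asarray(x, dtype=float)), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


def adjusted_r2(observed: Sequence[float], fitted: Sequence[float], n_params: int) -> float:
    """Wherry adjusted R^2: 1 - (1 - R^2) (n - 1) / (n - p - 1).

    Returns NaN (flagged, treated as failing any threshold) when the
    observed values have zero variance.
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(fitted, dtype=float)
    n = y.size
    if n < n_params + 2:
        raise InsufficientDataError(f"need >= {n_params + 2} points, got {n}")
    ss_res = float(np.sum((y - f) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


@dataclass(frozen=True)
class GaussianFit:
    condition_label: str
    a_peak: float
    b_pss: float  # ms
    c_tbw: float  # ms
    sse: float
    r2: float
    adj_r2: float
    converged: bool
    n_points: int

    @property
    def kept(self) -> bool:
        return self.converged and np.isfinite(self.adj_r2) and self.adj_r2 >= GAUSS_R2_THRESHOLD


@dataclass(frozen=True)
class LogisticFit:
    condition_label: str
    side: str  # "AL" | "VL"
    b_slope_raw: float  # signed, per ms
    t_raw: float  # ms
    sse: float
    r2: float
    adj_r2: float
    converged: bool
    n_points: int

    @property
    def b_slope(self) -> float:
        return abs(self.b_slope_raw)

    @property
    def t_threshold(self) -> float:
        return abs(self.t_raw)


def _r2_pair(y: np.ndarray, f: np.ndarray, n_params: int) -> tuple[float, float]:
    ss_res = float(np.sum((y - f) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, adjusted_r2(y, f, n_params)


def fit_gaussian(curve: SJCurve) -> GaussianFit:
    """Bounded least-squares Gaussian fit with multi-start initialization.

    Starts: a0 = max observed proportion, b0 = SOA at the maximum,
    c0 in {150, 300, 450} ms; the start reaching the lowest sum of squared
    residuals wins (ties to the first). An optimizer failure from every
    start is recorded as converged=False, never raised, so cohort runs
    survive individual bad subjects.
    """
    x, y = curve.defined()
    if x.size < 4:
        raise InsufficientDataError(f"Gaussian fit needs >= 4 defined points, got {x.size}")
    lo = [GAUSSIAN_BOUNDS["a"][0], GAUSSIAN_BOUNDS["b"][0], GAUSSIAN_BOUNDS["c"][0]]
    hi = [GAUSSIAN_BOUNDS["a"][1], GAUSSIAN_BOUNDS["b"][1], GAUSSIAN_BOUNDS["c"][1]]
    a0 = float(np.clip(y.max(), lo[0] + 1e-6, hi[0]))
    b0 = float(np.clip(x[int(np.argmax(y))], lo[1], hi[1]))

    best = None
    converged = False
    for c0 in _GAUSS_C_STARTS:
        res = least_squares(
            lambda p: gaussian_model(x, *p) - y,
            x0=[a0, b0, c0],
            bounds=(lo, hi),
            method="trf",
        )
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, res)
            converged = bool(res.success)
    sse, res = best
    a, b, c = res.x
    r2, adj = _r2_pair(y, gaussian_model(x, a, b, c), 3)
    return GaussianFit(curve.condition_label, float(a), float(b), float(c),
                       sse, r2, adj, converged, int(x.size))


def fit_logistic(curve: SJCurve, side: str) -> LogisticFit:
    """Bounded least-squares logistic fit on one leading-sense half.

    AL uses SOAs in [-500, 0], VL in [0, +500]; SOA 0 belongs to both.
    The slope is bounded to [0, 1] (AL) or [-1, 0] (VL). Starts cross four
    slope magnitudes with the SOA nearest half-maximum plus fixed threshold
    fallbacks; the flat tails of the logistic make single-start descent
    prone to plateaus.
    """
    if side not in ("AL", "VL"):
        raise InvalidArgumentError(f"side must be 'AL' or 'VL', got {side!r}")
    x_all, y_all = curve.defined()
    mask = x_all <= 0 if side == "AL" else x_all >= 0
    x, y = x_all[mask], y_all[mask]
    if x.size < 3:
        raise InsufficientDataError(
            f"logistic fit ({side}) needs >= 3 defined points, got {x.size}"
        )
    if side == "AL":
        b_lo, b_hi = 0.0, 1.0
        b_starts = _LOGISTIC_B_STARTS
    else:
        b_lo, b_hi = -1.0, 0.0
        b_starts = tuple(-b for b in _LOGISTIC_B_STARTS)
    t_half = float(x[int(np.argmin(np.abs(y - 0.5)))])
    t_starts = (t_half,) + tuple(t for t in _LOGISTIC_T_EXTRA_STARTS if t != t_half)

    best = None
    converged = False
    for b0 in b_starts:
        for t0 in t_starts:
            res = least_squares(
                lambda p: logistic_model(x, *p) - y,
                x0=[b0, t0],
                bounds=([b_lo, LOGISTIC_T_BOUNDS[0]], [b_hi, LOGISTIC_T_BOUNDS[1]]),
                method="trf",
            )
            sse = float(np.sum(res.fun ** 2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, res)
                converged = bool(res.success)
    sse, res = best
    b, t = res.x
    r2, adj = _r2_pair(y, logistic_model(x, b, t), 2)
    return LogisticFit(curve.condition_label, side, float(b), float(t),
                       sse, r2, adj, converged, int(x.size))


def fit_subject(curves: Iterable[SJCurve], subject_id: str) -> pd.DataFrame:
    """All fits for one subject: one row per condition with Gaussian and
    both logistic parameter sets plus per-row kept flags."""
    rows = []
    for curve in curves:
        record: dict = {"subject_id": subject_id, "condition_label": curve.condition_label}
        try:
            g = fit_gaussian(curve)
            record.update(
                a=g.a_peak, pss_ms=g.b_pss, tbw_ms=g.c_tbw,
                adj_r2_gauss=g.adj_r2, gauss_converged=g.converged,
            )
        except InsufficientDataError:
            record.update(a=np.nan, pss_ms=np.nan, tbw_ms=np.nan,
                          adj_r2_gauss=np.nan, gauss_converged=False)
        for side in ("AL", "VL"):
            key = side.lower()
            try:
                f = fit_logistic(curve, side)
                record.update({
                    f"slope_{key}": f.b_slope,
                    f"thr_{key}_ms": f.t_threshold,
                    f"slope_{key}_raw": f.b_slope_raw,
                    f"thr_{key}_raw": f.t_raw,
                    f"adj_r2_{key}": f.adj_r2,
                    f"{key}_converged": f.converged,
                })
            except InsufficientDataError:
                record.update({
                    f"slope_{key}": np.nan, f"thr_{key}_ms": np.nan,
                    f"slope_{key}_raw": np.nan, f"thr_{key}_raw": np.nan,
                    f"adj_r2_{key}": np.nan, f"{key}_converged": False,
                })
        rows.append(record)
    return pd.DataFrame(rows)


def _passes(value: float, threshold: float) -> bool:
    return bool(np.isfinite(value) and value >= threshold)


def apply_exclusion(
    fits: pd.DataFrame,
    gauss_threshold: float = GAUSS_R2_THRESHOLD,
    logistic_threshold: float = LOGISTIC_R2_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Subject-level kept/excluded rosters under the strict R^2 rules.

    A subject is dropped from the Gaussian roster if any condition's
    Gaussian fit failed to converge or has adjusted R^2 < ``gauss_threshold``;
    from the logistic roster if either leading-sense side of any condition
    fails convergence or sits below ``logistic_threshold``. Returns the fits
    table with ``kept_gauss`` / ``kept_logistic`` columns plus a log of
    exclusion reasons (one line each; nothing is dropped silently).
    """
    fits = fits.copy()
    reasons: list[str] = []
    kept_g, kept_l = {}, {}
    for subject_id, sub in fits.groupby("subject_id", sort=True):
        g_ok, l_ok = True, True
        for _, row in sub.iterrows():
            cond = row["condition_label"]
            if not (row["gauss_converged"] and _passes(row["adj_r2_gauss"], gauss_threshold)):
                g_ok = False
                reasons.append(
                    f"{subject_id}: Gaussian adjusted R^2 {row['adj_r2_gauss']:.3f} "
                    f"< {gauss_threshold} (condition {cond})"
                    if row["gauss_converged"]
                    else f"{subject_id}: Gaussian fit did not converge (condition {cond})"
                )
            for side in ("al", "vl"):
                if not (row[f"{side}_converged"] and _passes(row[f"adj_r2_{side}"], logistic_threshold)):
                    l_ok = False
                    reasons.append(
                        f"{subject_id}: logistic ({side.upper()}) adjusted R^2 "
                        f"{row[f'adj_r2_{side}']:.3f} < {logistic_threshold} (condition {cond})"
                        if row[f"{side}_converged"]
                        else f"{subject_id}: logistic ({side.upper()}) fit did not converge "
                             f"(condition {cond})"
                    )
        kept_g[subject_id] = g_ok
        kept_l[subject_id] = l_ok
    fits["kept_gauss"] = fits["subject_id"].map(kept_g)
    fits["kept_logistic"] = fits["subject_id"].map(kept_l)
    return fits, reasons


def summarize_by_condition(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and standard error of the kept subjects' measures.

    TBW and PSS are summarized over the Gaussian roster; |slope| and
    |threshold| per leading sense over the logistic roster. SE is the
    sample standard deviation / sqrt(n); single-subject cells report n but
    no SE.
    """
    measures = [
        ("tbw_ms", "kept_gauss"), ("pss_ms", "kept_gauss"),
        ("slope_al", "kept_logistic"), ("slope_vl", "kept_logistic"),
        ("thr_al_ms", "kept_logistic"), ("thr_vl_ms", "kept_logistic"),
    ]
    rows = []
    for label, group in fits.groupby("condition_label", sort=True):
        for measure, roster in measures:
            vals = group.loc[group[roster], measure].dropna()
            n = int(vals.size)
            if n == 0:
                continue
            rows.append({
                "condition_label": label,
                "measure": measure,
                "n": n,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
            })
    return pd.DataFrame(rows)
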