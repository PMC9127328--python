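"""FRAP trace normalization, quality control, and hyperbolic recovery fitting.

A recording consists of three prebleach frames followed by postbleach frames
(117 in the reference protocol, 1.77 Hz).  Per frame the bleach-ROI
intensity is background corrected and normalized to the mean of the
corrected prebleach values, so the prebleach level is 1 by construction.
Recordings whose non-bleached reference ROI varies by more than 15%
(range/mean over the recording, strict inequality) are excluded as focal
drift.  Averaged recovery traces are fit with the hyperbola

    y(t) = offset + R * t / (t + t_half)

where ``offset`` is the bleach floor, ``R`` the maximal recovery above the
floor, and ``t_half`` the half-time of recovery (the fitted curve at
``t = t_half`` equals ``offset + R/2``).  Time is measured from the bleach
event: the first postbleach frame sits at t = 1/rate, so the model's
``y(0) = offset`` coincides with the bleach floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class FrapTrace:
    """One FRAP recording: raw ROI intensities plus the normalized recovery."""

    times_s: np.ndarray  # postbleach times, measured from the bleach event
    bleach: np.ndarray  # bleach-ROI mean intensity per frame (pre + post)
    background: np.ndarray
    reference: np.ndarray
    n_prebleach: int = 3
    normalized: np.ndarray | None = None  # postbleach values, prebleach mean = 1
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        n_total = self.n_prebleach + len(t)
        for name in ("bleach", "background", "reference"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n_total:
                raise ValueError(
                    f"{name} has {len(arr)} frames, expected "
                    f"{self.n_prebleach} prebleach + {len(t)} postbleach"
                )
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "times_s", t)


@dataclass(frozen=True)
class FrapFit:
    """Hyperbolic recovery fit parameters."""

    offset: float
    maximal_recovery: float
    t_half_s: float
    fit_r2: float
    converged: bool = True
    flag: str | None = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.maximal_recovery * t / (t + self.t_half_s)


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Background-correct and normalize a trace to its prebleach mean.

    Per frame ``bleach - background`` is computed; the postbleach values are
    divided by the mean of the corrected prebleach frames.  A non-positive
    prebleach mean (e.g. background equal to the signal) makes the
    normalization undefined and raises ``ValueError``.
    """
    corrected = trace.bleach - trace.background
    pre = corrected[: trace.n_prebleach]
    pre_mean = pre.mean()
    if pre_mean <= 0:
        raise ValueError(
            f"prebleach corrected mean {pre_mean} <= 0: normalization undefined"
        )
    normalized = corrected[trace.n_prebleach :] / pre_mean
    return replace(trace, normalized=normalized)


def qc_exclude(trace: FrapTrace, max_variation: float = 0.15) -> FrapTrace:
    """Flag recordings with reference-ROI intensity variation above 15%.

    Variation is (max - min) / mean of the reference ROI over the whole
    recording; exactly 15% is retained (the rule is a strict inequality).
    """
    ref = trace.reference
    mean = ref.mean()
    if mean <= 0:
        return replace(trace, excluded=True, exclusion_reason="nonpositive reference mean")
    variation = (ref.max() - ref.min()) / mean
    if variation > max_variation:
        return replace(
            trace,
            excluded=True,
            exclusion_reason=f"reference variation {variation:.3f} > {max_variation}",
        )
    return replace(trace, excluded=False, exclusion_reason=None)


def average_traces(traces: list[FrapTrace]) -> FrapTrace:
    """Average the normalized recovery of retained traces on a common time base."""
    kept = [t for t in traces if not t.excluded]
    if not kept:
        raise ValueError("no retained traces to average")
    base = kept[0].times_s
    for t in kept[1:]:
        if len(t.times_s) != len(base) or not np.allclose(t.times_s, base):
            raise ValueError("traces must share a common time base for averaging")
    norms = []
    for t in kept:
        if t.normalized is None:
            t = normalize_trace(t)
        norms.append(t.normalized)
    mean_norm = np.mean(norms, axis=0)
    proto = kept[0]
    return replace(proto, normalized=mean_norm)


def _hyperbola(t: np.ndarray, offset: float, recovery: float, t_half: float) -> np.ndarray:
    return offset + recovery * t / (t + t_half)


def fit_recovery(trace: FrapTrace, min_points: int = 10) -> FrapFit:
    """Least-squares hyperbolic fit to the normalized postbleach recovery.

    Bounds: offset and R in [0, 1.5], t_half in (0, 10 x recording length].
    Three multistart t_half seeds guard against local minima; a fit pinned
    at a bound or a flat trace (R ~ 0, t_half unidentifiable) is flagged.
    """
    if trace.normalized is None:
        trace = normalize_trace(trace)
    t = trace.times_s
    y = trace.normalized
    if len(t) < min_points:
        raise ValueError(f"need >= {min_points} postbleach points, got {len(t)}")
    t_max = float(t[-1])
    bounds = ([0.0, 0.0, 1e-9], [1.5, 1.5, 10.0 * t_max])
    y_span = float(y.max() - y.min())
    best = None
    for t_half0 in (0.1 * t_max, 0.5 * t_max, 2.0 * t_max):
        p0 = [max(float(y[0]), 0.0), max(y_span, 1e-3), t_half0]
        try:
            popt, _ = curve_fit(
                _hyperbola, t, y, p0=p0, bounds=bounds, maxfev=10000
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _hyperbola(t, *popt)
        ss = float(resid @ resid)
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        return FrapFit(np.nan, np.nan, np.nan, np.nan, converged=False, flag="no convergence")
    popt, ss_res = best
    offset, recovery, t_half = (float(v) for v in popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    flag = None
    if recovery < 1e-6:
        flag = "flat trace: t_half unidentifiable"
    elif t_half >= 10.0 * t_max * (1 - 1e-6):
        flag = "t_half at upper bound"
    return FrapFit(offset, recovery, t_half, r2, converged=True, flag=flag)


def read_trace_csv(path, n_prebleach: int = 3) -> FrapTrace:
    """Read a FRAP trace from CSV with columns time, bleach, background, reference.

    The first ``n_prebleach`` rows are the prebleach frames; their time
    values are ignored and postbleach times are taken from the remaining
    rows (measured from the bleach event).
    """
    df = pd.read_csv(path)
    required = {"time", "bleach", "background", "reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: FRAP CSV needs columns {sorted(required)}")
    return FrapTrace(
        times_s=df["time"].to_numpy()[n_prebleach:],
        bleach=df["bleach"].to_numpy(),
        background=df["background"].to_numpy(),
        reference=df["reference"].to_numpy(),
        n_prebleach=n_prebleach,
    )
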