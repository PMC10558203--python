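"""Fluorescence-trace analysis chain: image stacks -> epoch-collapsed ROI
dF/F traces -> artifact-corrected, calibrated pH time courses -> kinetics
and nonparametric group statistics.

The chain mirrors the standard interleaved-protocol analysis: camera frames
acquired during stimulation are discarded and frames within each imaging
epoch averaged; baseline fluorescence F0 comes from the first collapsed
frame; dF/F is computed over pixels whose baseline exceeds a threshold;
the population-average photoartifact measured in opsin-negative controls is
subtracted; a monotone piecewise-linear calibration (anchored at pH 7.3,
where dF/F = 0 by convention) converts dF/F to pH; acidification half-times
and single-exponential recovery fits summarize each cell's kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.filters import threshold_otsu

from .core_model import StimulusProtocol

REFERENCE_PH = 7.3


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """T x Y x X stack with per-frame timestamps and epoch labels."""

    data: np.ndarray
    t: np.ndarray           # s, strictly increasing
    labels: np.ndarray      # 'stim' | 'image' | 'dark' per frame

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.t = np.asarray(self.t, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("stack must be T x Y x X")
        if len(self.t) != len(self.data) or len(self.labels) != len(self.data):
            raise ValueError("one timestamp and label per frame required")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ROISet:
    """Integer label mask (0 = background) with per-ROI categories and
    optional dendrite -> parent-soma links."""

    mask: np.ndarray
    categories: dict[int, str]
    parents: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        present = set(np.unique(self.mask)) - {0}
        for lbl in present:
            if int(lbl) not in self.categories:
                raise ValueError(f"label {lbl} has no category")
        for dend, soma in self.parents.items():
            if soma not in self.categories:
                raise ValueError(
                    f"dendrite {dend} references missing soma {soma}")

    @property
    def labels(self) -> list[int]:
        return sorted(int(v) for v in set(np.unique(self.mask)) - {0})


@dataclass
class ROITrace:
    t: np.ndarray           # epoch times, s
    dff: np.ndarray
    category: str = "soma"
    corrected: bool = False
    F0: float = np.nan
    label: int | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.t) != len(self.dff):
            raise ValueError("t and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")


# ---------------------------------------------------------------------------
# Frame handling
# ---------------------------------------------------------------------------

def collapse_epochs(stack: FrameStack, protocol: StimulusProtocol,
                    ) -> FrameStack:
    """Average frames within each imaging epoch; discard stim/dark frames.

    Output frames are timestamped at the epoch midpoint. A frame falling
    outside every protocol epoch is an error.
    """
    edges = np.array([ep.t_start for ep in protocol.epochs]
                     + [protocol.epochs[-1].t_end])
    idx = np.searchsorted(edges, stack.t, side="right") - 1
    at_end = np.abs(stack.t - edges[-1]) <= 1e-9
    idx[at_end] = len(protocol.epochs) - 1
    bad = np.nonzero((idx < 0) | (idx >= len(protocol.epochs))
                     | (stack.t < edges[0] - 1e-9)
                     | ((stack.t > edges[-1] + 1e-9)))[0]
    if bad.size:
        raise ValueError(
            f"frames outside all protocol epochs: indices {bad.tolist()}")

    frames, times = [], []
    for k, ep in enumerate(protocol.epochs):
        if ep.channel != "image":
            continue
        sel = idx == k
        if not sel.any():
            continue
        frames.append(stack.data[sel].mean(axis=0))
        times.append(ep.t_start + ep.duration / 2.0)
    if not frames:
        raise ValueError("protocol contains no imaging epochs with frames")
    return FrameStack(data=np.stack(frames), t=np.array(times),
                      labels=np.full(len(frames), "image"))


def collapse_trace(t: np.ndarray, F: np.ndarray,
                   protocol: StimulusProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-collapse a sample-level fluorescence trace: average the
    samples falling in each imaging epoch, timestamp at the epoch midpoint
    (the trace-level analogue of ``collapse_epochs``)."""
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    edges = np.array([ep.t_start for ep in protocol.epochs]
                     + [protocol.epochs[-1].t_end])
    idx = np.searchsorted(edges, t, side="right") - 1
    times, vals = [], []
    for k, ep in enumerate(protocol.epochs):
        if ep.channel != "image":
            continue
        sel = idx == k
        if sel.any():
            times.append(ep.t_start + ep.duration / 2.0)
            vals.append(F[sel].mean())
    if not vals:
        raise ValueError("no samples fall inside imaging epochs")
    return np.array(times), np.array(vals)


def f0_mask(first_frame: np.ndarray, rule: str = "quantile",
            value: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Baseline mask restricting dF/F to signal-bearing pixels.

    rule 'absolute': mask = F0 > value. rule 'quantile': threshold at the
    given quantile of nonzero pixels, mask = F0 >= threshold (ties included,
    so a uniform frame is fully selected). rule 'otsu': Otsu threshold.
    """
    F0 = np.asarray(first_frame, dtype=float)
    if F0.size == 0:
        raise ValueError("empty frame")
    if rule == "absolute":
        mask = F0 > value
    elif rule == "quantile":
        nz = F0[F0 > 0]
        thr = np.quantile(nz, value) if nz.size else np.inf
        mask = F0 >= thr
    elif rule == "otsu":
        mask = F0 > threshold_otsu(F0)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    if not mask.any():
        warnings.warn("F0 threshold selected no pixels; empty mask returned")
    return mask, F0


def extract_trace(stack: FrameStack, roi_set: ROISet, label: int,
                  signal_mask: np.ndarray | None = None) -> ROITrace:
    """Per-epoch mean dF/F over (ROI and F0-mask) pixels.

    F0 per ROI is taken from the first collapsed frame, so dF/F is zero at
    the first epoch by construction.
    """
    if label not in roi_set.labels:
        raise ValueError(f"label {label} absent from ROI set")
    sel = roi_set.mask == label
    if signal_mask is not None:
        sel = sel & signal_mask
    if not sel.any():
        raise ValueError(f"ROI {label} has no pixels above the F0 threshold")
    means = stack.data[:, sel].mean(axis=1)
    F0 = means[0]
    if F0 == 0:
        raise ValueError(f"ROI {label} has zero baseline fluorescence")
    return ROITrace(t=stack.t, dff=(means - F0) / F0,
                    category=roi_set.categories[label], F0=float(F0),
                    label=label)


def subtract_artifact(trace: ROITrace,
                      control_traces: list[ROITrace]) -> ROITrace:
    """Subtract the epoch-wise population-average control dF/F (the
    blue-light photoartifact measured in opsin-negative cells)."""
    if not control_traces:
        raise ValueError("at least one control trace is required")
    for c in control_traces:
        if len(c.t) != len(trace.t) or not np.allclose(c.t, trace.t):
            raise ValueError("control trace epoch grid does not match")
    ctrl = np.mean([c.dff for c in control_traces], axis=0)
    return replace(trace, dff=trace.dff - ctrl, corrected=True)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear (pH, dF/F) map with dF/F = 0 at the
    reference pH (7.3 by convention)."""

    pH_knots: np.ndarray
    dff_knots: np.ndarray
    reference_pH: float = REFERENCE_PH

    def dff(self, pH) -> np.ndarray:
        return np.interp(pH, self.pH_knots, self.dff_knots)

    def pH(self, dff) -> tuple[np.ndarray, np.ndarray]:
        """Invert the map; out-of-range values are clamped to the end knots
        and flagged per sample."""
        dff = np.asarray(dff, dtype=float)
        flags = (dff < self.dff_knots[0]) | (dff > self.dff_knots[-1])
        return np.interp(dff, self.dff_knots, self.pH_knots), flags


def build_calibration(pairs, reference_pH: float = REFERENCE_PH,
                      ) -> CalibrationCurve:
    """Piecewise-linear calibration from measured (pH, dF/F) pairs.

    Requires strictly increasing pH, strictly increasing dF/F (the sensor is
    monotone), and a knot at the reference pH with dF/F = 0 (the baseline
    convention).
    """
    arr = np.array(sorted((float(p), float(d)) for p, d in pairs))
    if len(arr) < 2:
        raise ValueError("at least two calibration pairs required")
    pH, dff = arr[:, 0], arr[:, 1]
    if np.any(np.diff(pH) <= 0):
        raise ValueError("duplicate or non-increasing pH values")
    if np.any(np.diff(dff) <= 0):
        raise ValueError("dF/F must increase strictly with pH "
                         "(monotone-sensor assumption violated)")
    at_ref = np.isclose(pH, reference_pH)
    if not at_ref.any() or not np.isclose(dff[at_ref][0], 0.0):
        raise ValueError(
            f"calibration must contain the reference knot "
            f"(pH {reference_pH}, dF/F 0)")
    return CalibrationCurve(pH_knots=pH, dff_knots=dff,
                            reference_pH=reference_pH)


def dff_to_ph(trace: ROITrace, curve: CalibrationCurve,
              initial_pH: float = REFERENCE_PH,
              allow_uncorrected: bool = False,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Convert a corrected dF/F trace to a pH time course.

    pH_t inverts the calibration at dF/F_t offset so that the trace starts
    at ``initial_pH``. Returns (pH, out_of_range_flags).
    """
    if not trace.corrected and not allow_uncorrected:
        raise ValueError("trace is not artifact-corrected; pass "
                         "allow_uncorrected=True to waive")
    offset = float(curve.dff(initial_pH))
    return curve.pH(trace.dff + offset)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticsResult:
    pH_min: float = np.nan
    t_half_acid: float | None = None
    tau_rec: float | None = None
    t_half_rec: float | None = None
    fit_rmse: float = np.nan
    reason: str | None = None


def half_time_acid(trace: ROITrace, stim_window: tuple[float, float],
                   ) -> tuple[float | None, str | None]:
    """Time at which the trace first reaches half its maximum acidification.

    The maximum decrease D = max(-dF/F) over the stimulation window; the
    half-time is the first crossing of -dF/F >= D/2, linearly interpolated
    between the bracketing epochs. Returns (t_half, reason), with
    t_half None when there is no acidification.
    """
    t0, t1 = stim_window
    sel = (trace.t >= t0) & (trace.t <= t1)
    if not sel.any():
        raise ValueError("stimulation window contains no samples")
    t = trace.t[sel]
    drop = -trace.dff[sel]
    D = drop.max()
    if D <= 0:
        return None, "no acidification in the stimulation window"
    half = D / 2.0
    i = int(np.argmax(drop >= half))
    if i == 0 or drop[i - 1] >= half:
        return float(t[i]), None
    frac = (half - drop[i - 1]) / (drop[i] - drop[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), None


def fit_recovery(trace: ROITrace, recovery_window: tuple[float, float],
                 ) -> tuple[float | None, float | None, float, str | None]:
    """Single-exponential fit y(t) = y_inf + (y0 - y_inf) exp(-(t-t0)/tau)
    over the recovery window; returns (tau, t_half = tau ln 2, rmse, reason).

    Initialization: y_inf from the mean of the last 10% of the window, tau
    from a log-linear regression of (y - y_inf) — a derivative-free start
    that converges on well-behaved recoveries.
    """
    t0w, t1w = recovery_window
    sel = (trace.t >= t0w) & (trace.t <= t1w)
    t, y = trace.t[sel], trace.dff[sel]
    if len(t) < 4:
        return None, None, np.nan, "fewer than 4 samples in recovery window"
    if np.ptp(y) < 1e-12:
        return None, None, 0.0, "flat-trace: tau unidentifiable"

    n_tail = max(2, len(y) // 10)
    y_inf0 = y[-n_tail:].mean()
    resid = y - y_inf0
    sign = np.sign(resid[0]) or 1.0
    pos = sign * resid > 1e-12
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(sign * resid[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 2.0
    else:
        tau0 = (t[-1] - t[0]) / 2.0
    tau0 = float(np.clip(tau0, 1e-3, 100 * (t[-1] - t[0])))

    def model(tt, y_inf, y0, tau):
        return y_inf + (y0 - y_inf) * np.exp(-(tt - t[0]) / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[y_inf0, y[0], tau0],
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return None, None, np.nan, f"fit did not converge: {exc}"
    tau = float(popt[2])
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return tau, tau * np.log(2.0), rmse, None


def proton_fold_change(pH_from: float, pH_to: float) -> float:
    """Fold increase of free-proton concentration, 10^(pH_from - pH_to)."""
    if not (np.isfinite(pH_from) and np.isfinite(pH_to)):
        raise ValueError("pH values must be finite")
    return 10.0 ** (pH_from - pH_to)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    test: str               # 'rank-sum' | 'signed-rank'
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str             # 'exact' | 'approx'
    reason: str | None = None


def compare_groups(a, b, mode: str = "unpaired",
                   force_exact: bool | None = None) -> GroupComparison:
    """Two-sided Wilcoxon comparison of two samples.

    'unpaired' runs the rank-sum (Mann-Whitney) test, exact when both
    n <= 10 and there are no ties; 'paired' runs the signed-rank test,
    exact when n <= 15 and no zero/tied differences. Larger samples or
    ties use the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "unpaired":
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both groups must be non-empty")
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        exact = (len(a) <= 10 and len(b) <= 10 and not ties) \
            if force_exact is None else force_exact
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        return GroupComparison("rank-sum", float(res.statistic),
                               float(res.pvalue), len(a), len(b),
                               "exact" if exact else "approx")
    if mode == "paired":
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired mode needs equal lengths >= 2")
        d = a - b
        if np.all(d == 0):
            return GroupComparison("signed-rank", np.nan, np.nan,
                                   len(a), len(b), "exact",
                                   reason="all paired differences are zero")
        nz = d[d != 0]
        ties = (len(np.unique(np.abs(nz))) < len(nz)) or np.any(d == 0)
        exact = (len(a) <= 15 and not ties) \
            if force_exact is None else force_exact
        res = stats.wilcoxon(a, b, alternative="two-sided",
                             method="exact" if exact else "approx",
                             correction=False)
        return GroupComparison("signed-rank", float(res.statistic),
                               float(res.pvalue), len(a), len(b),
                               "exact" if exact else "approx")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Per-population reporting
# ---------------------------------------------------------------------------

def analyze_roi(trace: ROITrace, curve: CalibrationCurve,
                stim_window: tuple[float, float],
                recovery_window: tuple[float, float],
                initial_pH: float = REFERENCE_PH) -> KineticsResult:
    """Full per-ROI kinetics: calibrated pH minimum, acidification
    half-time, and exponential recovery fit."""
    pH, _ = dff_to_ph(trace, curve, initial_pH=initial_pH,
                      allow_uncorrected=True)
    t_half, reason_a = half_time_acid(trace, stim_window)
    # the recovery exponential is fit on the calibrated pH course, so the
    # sensor's protonation nonlinearity does not distort the time constant
    ph_trace = replace(trace, dff=pH - initial_pH)
    tau, t_half_rec, rmse, reason_r = fit_recovery(ph_trace, recovery_window)
    sel = (trace.t >= stim_window[0]) & (trace.t <= stim_window[1])
    return KineticsResult(pH_min=float(pH[sel].min()), t_half_acid=t_half,
                          tau_rec=tau, t_half_rec=t_half_rec, fit_rmse=rmse,
                          reason=reason_a or reason_r)


def dendrite_soma_report(results: dict[int, KineticsResult],
                         roi_set: ROISet) -> tuple[pd.DataFrame, list[int]]:
    """Pair each dendrite's kinetics with its parent soma's.

    Returns (paired table, unpaired labels). A dendrite whose parent link
    points at a label without results is an error.
    """
    rows = []
    paired: set[int] = set()
    for dend, soma in roi_set.parents.items():
        if soma not in results:
            raise ValueError(f"dendrite {dend} references soma {soma} "
                             "which has no results")
        if dend not in results:
            raise ValueError(f"dendrite {dend} has no results")
        rd, rs = results[dend], results[soma]
        rows.append({"soma": soma, "dendrite": dend,
                     "t_half_acid_soma": rs.t_half_acid,
                     "t_half_acid_dendrite": rd.t_half_acid,
                     "t_half_rec_soma": rs.t_half_rec,
                     "t_half_rec_dendrite": rd.t_half_rec})
        paired |= {dend, soma}
    table = pd.DataFrame(rows, columns=["soma", "dendrite",
                                        "t_half_acid_soma",
                                        "t_half_acid_dendrite",
                                        "t_half_rec_soma",
                                        "t_half_rec_dendrite"])
    unpaired = sorted(set(results) - paired)
    return table, unpaired
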