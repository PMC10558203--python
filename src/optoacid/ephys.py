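"""Voltage-clamp photocurrent characterization.

Extracts the standard channelrhodopsin gating summary from recorded (or
synthesized) current traces: peak and steady-state current and their ratio,
single-exponential opening/closing time constants, the effective power
density for 50% activation (EPD50), the reversal potential from an I-V
series, the action spectrum normalized to 488 nm, imaging-light crosstalk
fractions, and the ideal Nernst reversal-potential shift used to interpret
ion-substitution selectivity measurements.

The ratio column is computed and labelled as I_SS/I_peak (1.00 for a
sag-free opsin); published gating tables sometimes print the same quantity
under an inverted heading, so the orientation is stated explicitly here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core_model import (
    GAS_CONSTANT_J_PER_MOL_K,
    FARADAY_C_PER_MOL,
    OpsinParams,
    opsin_gate,
)

#: Fraction of the 488-nm reference current below which a photocurrent is
#: reported as undetectable ("< floor").
DETECTION_FLOOR = 0.003


@dataclass(frozen=True)
class StimSegment:
    t_on_ms: float
    t_off_ms: float
    wavelength: float = 488.0
    intensity: float = 500.0   # mW cm^-2


@dataclass
class PhotocurrentRecording:
    t_ms: np.ndarray
    I_pA: np.ndarray
    segments: tuple[StimSegment, ...] = ()
    V_hold: float = -70.0      # mV

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.I_pA = np.asarray(self.I_pA, dtype=float)
        if len(self.t_ms) != len(self.I_pA):
            raise ValueError("t and I must have equal length")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("t must be strictly increasing")
        for seg in self.segments:
            if seg.t_on_ms < self.t_ms[0] or seg.t_off_ms > self.t_ms[-1]:
                raise ValueError("stimulus segment outside the record span")


@dataclass
class CharacterizationResult:
    """Gating summary in the units of a standard opsin comparison table."""

    Vr: float | None = None                 # mV
    tau_on_fastest: float | None = None     # ms
    tau_on_at_EPD50: float | None = None    # ms
    tau_off: float | None = None            # ms
    EPD50: float | None = None              # mW cm^-2
    I_ss: float | None = None               # pA
    ss_over_peak: float | None = None       # I_SS / I_peak
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Trace operations
# ---------------------------------------------------------------------------

def smooth(I: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; edges use symmetrically shrunk windows."""
    I = np.asarray(I, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > len(I):
        raise ValueError(f"window {window} exceeds trace length {len(I)}")
    if window == 1:
        return I.copy()
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(I)])
    n = len(I)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    # shrink symmetrically so the window stays centred at the edge samples
    k = np.minimum(i - lo, hi - i)
    lo, hi = i - k, i + k
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def peak_steady(rec: PhotocurrentRecording,
                light_window: tuple[float, float],
                min_samples: int = 50) -> tuple[float, float, float]:
    """(I_peak, I_ss, I_ss/I_peak) within the light window.

    I_peak is the extremal (largest-magnitude) current after light onset;
    I_ss is the mean over the last 20% of the window. A flat, sag-free step
    gives a ratio of 1.00.
    """
    t0, t1 = light_window
    sel = (rec.t_ms >= t0) & (rec.t_ms <= t1)
    if sel.sum() < min_samples:
        raise ValueError(
            f"light window holds {int(sel.sum())} samples; "
            f">= {min_samples} required")
    I = rec.I_pA[sel]
    t = rec.t_ms[sel]
    I_peak = I[np.argmax(np.abs(I))]
    if abs(I_peak) < 1e-12:
        raise ValueError("no photocurrent detected")
    tail = t >= t1 - 0.2 * (t1 - t0)
    I_ss = I[tail].mean()
    return float(I_peak), float(I_ss), float(I_ss / I_peak)


def fit_tau(rec: PhotocurrentRecording, phase: str,
            window: tuple[float, float] | None = None,
            smooth_window: int = 5,
            ) -> tuple[float | None, float, str | None]:
    """Single-exponential time constant of channel opening or closing.

    phase 'on' fits the rise after light onset, 'off' the decay after
    light-off; the window defaults to the first stimulus segment's on (or
    post-off) interval. Returns (tau_ms, rmse, reason); ``reason`` is set
    when the fit fails. A relative RMSE above 5% of the fitted amplitude is
    appended to ``reason`` as a misspecification flag.
    """
    if phase not in ("on", "off"):
        raise ValueError("phase must be 'on' or 'off'")
    if window is None:
        if not rec.segments:
            raise ValueError("no stimulus segments and no explicit window")
        seg = rec.segments[0]
        window = (seg.t_on_ms, seg.t_off_ms) if phase == "on" \
            else (seg.t_off_ms, rec.t_ms[-1])
    sel = (rec.t_ms >= window[0]) & (rec.t_ms <= window[1])
    if sel.sum() < 10:
        raise ValueError("phase window must contain >= 10 samples")
    t = rec.t_ms[sel]
    sw = min(smooth_window, sel.sum() if sel.sum() % 2 else sel.sum() - 1)
    y = smooth(rec.I_pA[sel], sw)

    y_inf0 = y[-max(2, len(y) // 10):].mean()
    amp0 = y[0] - y_inf0
    tau0 = (t[-1] - t[0]) / 5.0

    def model(tt, y_inf, amp, tau):
        return y_inf + amp * np.exp(-(tt - t[0]) / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[y_inf0, amp0, tau0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return None, np.nan, f"fit did not converge: {exc}"
    tau = float(popt[2])
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    reason = None
    amp = abs(popt[1])
    if amp > 0 and rmse > 0.05 * amp:
        reason = ("single-exponential misfit: RMSE exceeds 5% of the "
                  "fitted amplitude")
    return tau, rmse, reason


def fit_epd50(intensities, I_ss, n_boot: int = 200, seed: int = 0,
              ) -> tuple[float, float, tuple[float, float], str | None]:
    """Light-sensitivity fit I_ss(P) = I_max * P / (P + EPD50).

    Returns (EPD50, I_max, bootstrap 95% CI on EPD50, warning). Intensities
    should span at least one decade; a narrower span leaves EPD50 poorly
    identified and is flagged rather than refused.
    """
    P = np.asarray(intensities, dtype=float)
    I = np.asarray(I_ss, dtype=float)
    if len(P) < 4:
        raise ValueError("at least 4 intensities required")
    warning = None
    if P.max() / max(P.min(), 1e-300) < 10.0:
        warning = ("intensities span less than one decade; "
                   "EPD50 is poorly identified")

    def model(p, I_max, K):
        return I_max * p / (p + K)

    def _fit(p, i):
        p0 = [i[np.argmax(p)] if np.any(i) else 1.0, np.median(p)]
        popt, _ = optimize.curve_fit(model, p, i, p0=p0,
                                     bounds=([-np.inf, 1e-12],
                                             [np.inf, np.inf]),
                                     maxfev=10000)
        return popt

    I_max, K = _fit(P, I)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(P), len(P))
        if len(np.unique(P[idx])) < 3:
            continue
        try:
            boots.append(_fit(P[idx], I[idx])[1])
        except RuntimeError:
            continue
    ci = (float(np.percentile(boots, 2.5)),
          float(np.percentile(boots, 97.5))) if boots else (np.nan, np.nan)
    return float(K), float(I_max), ci, warning


def reversal_potential(iv) -> tuple[float | None, str | None]:
    """Reversal potential by linear interpolation across the zero crossing
    of an (V, I) series; refuses to extrapolate when the current never
    changes sign. With multiple crossings the one nearest 0 mV is returned
    with a flag."""
    arr = np.array(sorted((float(v), float(i)) for v, i in iv))
    V, I = arr[:, 0], arr[:, 1]
    crossings = []
    for k in range(len(V) - 1):
        if I[k] == 0.0:
            crossings.append(V[k])
        elif I[k] * I[k + 1] < 0:
            crossings.append(V[k] - I[k] * (V[k + 1] - V[k])
                             / (I[k + 1] - I[k]))
    if I[-1] == 0.0:
        crossings.append(V[-1])
    if not crossings:
        return None, "no sign change in I(V); extrapolation refused"
    if len(crossings) == 1:
        return float(crossings[0]), None
    best = min(crossings, key=abs)
    return float(best), (f"{len(crossings)} zero crossings found; "
                         "reporting the one nearest 0 mV")


def nernst_shift(c_out_before: float, c_out_after: float,
                 ion_valence: int = 1,
                 temperature: float = 298.15) -> float:
    """Ideal-selectivity reversal shift (RT/zF) ln(c_after/c_before), mV.

    The ratio of a measured shift to this prediction serves as a
    selectivity index for the substituted ion (0 for a channel that does
    not conduct it)."""
    if c_out_before <= 0 or c_out_after <= 0:
        raise ValueError("concentrations must be > 0")
    rt_over_zf = (GAS_CONSTANT_J_PER_MOL_K * temperature
                  / (ion_valence * FARADAY_C_PER_MOL)) * 1e3
    return rt_over_zf * np.log(c_out_after / c_out_before)


@dataclass(frozen=True)
class SpectrumPoint:
    wavelength: float
    relative: float
    below_floor: bool

    def __str__(self):
        if self.below_floor:
            return f"{self.wavelength:g} nm: < {DETECTION_FLOOR}"
        return f"{self.wavelength:g} nm: {self.relative:.3f}"


def action_spectrum(I_ss_by_wavelength: dict[float, float],
                    floor: float = DETECTION_FLOOR) -> list[SpectrumPoint]:
    """Per-wavelength steady currents normalized to the 488-nm reference;
    values below ``floor`` are reported as below the detection floor."""
    ref = I_ss_by_wavelength.get(488.0)
    if ref is None:
        raise ValueError("488-nm reference recording is required")
    if abs(ref) < 1e-12:
        raise ValueError("488-nm reference current is zero")
    out = []
    for wl in sorted(I_ss_by_wavelength):
        rel = I_ss_by_wavelength[wl] / ref
        out.append(SpectrumPoint(wl, float(rel), abs(rel) < floor))
    return out


def crosstalk(I_blue: float, I_combo: float, I_red_only: float,
              floor: float = DETECTION_FLOOR) -> tuple[float, float]:
    """Imaging-light crosstalk: (activation_fraction, inactivation_fraction).

    activation = I_red_only/I_blue (red light opening the channel);
    inactivation = 1 - I_combo/I_blue (red light closing it during blue).
    """
    if abs(I_blue) <= floor:
        raise ValueError("blue reference current at or below detection floor")
    return I_red_only / I_blue, 1.0 - I_combo / I_blue


# ---------------------------------------------------------------------------
# Synthetic recordings and end-to-end characterization
# ---------------------------------------------------------------------------

def synthesize_recording(opsin: OpsinParams, intensity: float,
                         wavelength: float = 488.0, V_hold: float = -70.0,
                         t_total_ms: float = 1000.0, t_on_ms: float = 100.0,
                         t_off_ms: float = 600.0, dt_ms: float = 0.5,
                         noise_sd_pA: float = 0.0, seed: int | None = 0,
                         ) -> PhotocurrentRecording:
    """Voltage-clamp photocurrent from the gating model: I = g a (V - E)."""
    t = np.arange(0.0, t_total_ms + dt_ms / 2, dt_ms)
    on = (t >= t_on_ms) & (t < t_off_ms)
    a = opsin_gate(opsin, intensity, wavelength, t * 1e-3, light_on=on)
    I = opsin.g_max * a * (V_hold - opsin.E_ops)
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.normal(0.0, noise_sd_pA, size=I.shape)
    seg = StimSegment(t_on_ms, t_off_ms, wavelength, intensity)
    return PhotocurrentRecording(t_ms=t, I_pA=I, segments=(seg,),
                                 V_hold=V_hold)


def characterize(recordings_by_intensity: dict[float, PhotocurrentRecording],
                 iv: list[tuple[float, float]] | None = None,
                 ) -> CharacterizationResult:
    """Table-style gating summary from an intensity series (and optional
    I-V series). The brightest recording provides peak/steady currents and
    the gating time constants; the intensity series provides EPD50."""
    if not recordings_by_intensity:
        raise ValueError("at least one recording required")
    res = CharacterizationResult()
    intens = sorted(recordings_by_intensity)
    pairs = []
    for P in intens:
        rec = recordings_by_intensity[P]
        seg = rec.segments[0]
        _, I_ss, _ = peak_steady(rec, (seg.t_on_ms, seg.t_off_ms))
        pairs.append((P, abs(I_ss)))
    P_arr = [p for p, _ in pairs]
    I_arr = [i for _, i in pairs]
    if len(pairs) >= 4:
        res.EPD50, _, _, w = fit_epd50(P_arr, I_arr)
        if w:
            res.notes.append(w)

    bright = recordings_by_intensity[intens[-1]]
    seg = bright.segments[0]
    I_peak, I_ss, ratio = peak_steady(bright, (seg.t_on_ms, seg.t_off_ms))
    res.I_ss, res.ss_over_peak = abs(I_ss), abs(ratio)
    tau_on, _, _ = fit_tau(bright, "on")
    tau_off, _, _ = fit_tau(bright, "off")
    res.tau_on_fastest, res.tau_off = tau_on, tau_off
    if res.EPD50 is not None:
        near = min(intens, key=lambda p: abs(p - res.EPD50))
        tau_epd, _, _ = fit_tau(recordings_by_intensity[near], "on")
        res.tau_on_at_EPD50 = tau_epd
        if abs(near - res.EPD50) > 0.5 * res.EPD50:
            res.notes.append(
                "no recording near EPD50; tau_on_at_EPD50 taken from the "
                f"closest intensity ({near:g} mW cm^-2)")
    if iv is not None:
        res.Vr, flag = reversal_potential(iv)
        if flag:
            res.notes.append(flag)
    return res
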