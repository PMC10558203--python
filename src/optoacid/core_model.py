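"""Mechanistic forward model of a single well-mixed compartment under
interleaved optogenetic stimulation.

The causal chain is: blue light opens a channelrhodopsin (first-order gating
with intensity-dependent opening kinetics and a multiplicative
desensitization step); the open channel depolarizes the membrane (two
conductances: a potassium-dominated leak and the opsin); a fraction ``f_H``
of the opsin current is carried by protons, which acidify the cytosol
against its buffering capacity; a pH-sensitive fluorescent reporter
(pKa ~ 7.5, brighter at high pH) converts the pH time course into a
fluorescence trace, including a blue-light photoactivation artifact and
camera noise.

Units: time in seconds throughout this module; conductance nS, voltage mV,
capacitance pF (so nS*mV = pA and pF/nS = ms); lengths in micrometres;
light intensity in mW cm^-2, light dose in J cm^-2; buffering capacity in
mol L^-1 per pH unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FARADAY_C_PER_MOL = 96485.33212
GAS_CONSTANT_J_PER_MOL_K = 8.31446

#: Reference wavelength (nm) at which action spectra are normalized to 1.
REFERENCE_WAVELENGTH_NM = 488.0

#: Default blue stimulation intensity (mW cm^-2); experimental protocols in
#: this preparation use a few hundred mW cm^-2 of 488-nm light.
DEFAULT_STIM_INTENSITY = 500.0

#: Default imaging (yellow, 561 nm) intensity (mW cm^-2).
DEFAULT_IMAGE_INTENSITY = 150.0


class ProtocolError(ValueError):
    """Raised for ill-formed stimulation/imaging protocols."""


class StabilityError(ValueError):
    """Raised when an integration step exceeds the explicit-Euler bound."""


# ---------------------------------------------------------------------------
# Stimulus protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    t_start: float          # s
    duration: float         # s
    channel: str            # 'stim' | 'image' | 'dark'
    wavelength: float       # nm
    intensity: float        # mW cm^-2

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping schedule of stimulation/imaging epochs."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self):
        if not self.epochs:
            raise ProtocolError("protocol must contain at least one epoch")
        t = 0.0
        for ep in self.epochs:
            if ep.duration <= 0:
                raise ProtocolError(f"epoch duration must be > 0, got {ep.duration}")
            if ep.channel not in ("stim", "image", "dark"):
                raise ProtocolError(f"unknown channel {ep.channel!r}")
            if abs(ep.t_start - t) > 1e-9:
                raise ProtocolError("epochs must be contiguous and sorted by t_start")
            t = ep.t_end

    @property
    def total_duration(self) -> float:
        return self.epochs[-1].t_end

    def epoch_at(self, t: float) -> Epoch:
        """Epoch containing time ``t`` (right-open intervals; the final
        epoch includes its right edge)."""
        for ep in self.epochs:
            if ep.t_start <= t < ep.t_end:
                return ep
        last = self.epochs[-1]
        if abs(t - last.t_end) <= 1e-9:
            return last
        raise ProtocolError(f"time {t} s lies outside the protocol")

    def labels_at(self, t: np.ndarray) -> np.ndarray:
        """Vectorized epoch-channel lookup for an array of times."""
        edges = np.array([ep.t_start for ep in self.epochs] +
                         [self.epochs[-1].t_end])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      len(self.epochs) - 1)
        labels = np.array([ep.channel for ep in self.epochs])
        return labels[idx]

    def stim_intervals(self) -> list[tuple[float, float, float]]:
        """(t_start, t_end, intensity) for every stimulation epoch."""
        return [(ep.t_start, ep.t_end, ep.intensity)
                for ep in self.epochs if ep.channel == "stim"]

    def blue_dose_at(self, t: np.ndarray) -> np.ndarray:
        """Cumulative blue-light dose (J cm^-2) delivered by time ``t``."""
        t = np.asarray(t, dtype=float)
        dose = np.zeros_like(t)
        for t0, t1, inten in self.stim_intervals():
            dose += inten * 1e-3 * np.clip(np.minimum(t, t1) - t0, 0.0, None)
        return dose


def build_protocol(stim_s: float, image_s: float, active_total: float,
                   recovery_total: float, *,
                   stim_wavelength: float = 488.0,
                   image_wavelength: float = 561.0,
                   stim_intensity: float = DEFAULT_STIM_INTENSITY,
                   image_intensity: float = DEFAULT_IMAGE_INTENSITY,
                   ) -> StimulusProtocol:
    """Interleaved stim/image cycles for ``active_total`` seconds, followed
    by imaging-only recovery for ``recovery_total`` seconds.

    The canonical measurement uses 0.5-s stimulation interleaved with 1-s
    imaging for 150 s, then 150 s of recovery imaging (100 cycles).
    """
    for name, v in [("stim_s", stim_s), ("image_s", image_s),
                    ("active_total", active_total),
                    ("recovery_total", recovery_total)]:
        if v < 0:
            raise ProtocolError(f"{name} must be >= 0, got {v}")
    if stim_s + image_s <= 0:
        raise ProtocolError("stim_s + image_s must be > 0")

    epochs: list[Epoch] = []
    t = 0.0
    cycle = stim_s + image_s
    n_cycles = int(round(active_total / cycle)) if cycle > 0 else 0
    for _ in range(n_cycles):
        if stim_s > 0:
            epochs.append(Epoch(t, stim_s, "stim", stim_wavelength,
                                stim_intensity))
            t += stim_s
        if image_s > 0:
            epochs.append(Epoch(t, image_s, "image", image_wavelength,
                                image_intensity))
            t += image_s
    if recovery_total > 0:
        if image_s > 0:
            # Recovery keeps the acquisition cadence of the active phase:
            # the stimulation slot goes dark, imaging epochs continue, so a
            # 150-s active / 150-s recovery run yields equal epoch counts.
            n_rec = int(round(recovery_total / cycle)) if stim_s > 0 \
                else int(round(recovery_total / image_s))
            for _ in range(n_rec):
                if stim_s > 0:
                    epochs.append(Epoch(t, stim_s, "dark", stim_wavelength,
                                        0.0))
                    t += stim_s
                epochs.append(Epoch(t, image_s, "image", image_wavelength,
                                    image_intensity))
                t += image_s
        else:
            epochs.append(Epoch(t, recovery_total, "image", image_wavelength,
                                image_intensity))
    if not epochs:
        raise ProtocolError("degenerate protocol: no epochs")
    return StimulusProtocol(tuple(epochs))


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentGeometry:
    """Well-mixed compartment: a sphere (soma) or a cylinder (dendrite).

    The surface-to-volume ratio sets how fast a given membrane flux changes
    an intracellular concentration; it is 3/r for a sphere and 2/r for a
    cylinder (end caps ignored).
    """

    shape: str              # 'sphere' | 'cylinder'
    radius: float           # um
    length: float = 0.0     # um, cylinder only

    def __post_init__(self):
        if self.shape not in ("sphere", "cylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.shape == "cylinder" and self.length <= 0:
            raise ValueError("cylinder length must be > 0")

    @property
    def surface_to_volume(self) -> float:
        """um^-1; 3/r (sphere) or 2/r (cylinder, lateral surface only)."""
        return 3.0 / self.radius if self.shape == "sphere" else 2.0 / self.radius

    @property
    def volume_um3(self) -> float:
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * self.radius ** 3
        return np.pi * self.radius ** 2 * self.length

    @property
    def area_um2(self) -> float:
        if self.shape == "sphere":
            return 4.0 * np.pi * self.radius ** 2
        return 2.0 * np.pi * self.radius * self.length


@dataclass(frozen=True)
class OpsinParams:
    """Lumped channelrhodopsin description.

    ``f_H`` is the phenomenological fraction of the opsin current carried by
    protons (not a GHK permeability); proton-impermeant variants have
    ``f_H = 0``. ``EPD50`` is the effective power density for 50% of maximal
    steady-state activation. ``desensitization_ratio`` is the steady-state
    over peak current under continuous light (1 for sag-free opsins).
    """

    g_max: float                      # nS
    E_ops: float = 0.0                # mV
    f_H: float = 0.5                  # dimensionless in [0, 1]
    EPD50: float = 22.0               # mW cm^-2
    tau_on_sat: float = 5.0           # ms, opening at saturating light
    tau_off: float = 16.0             # ms
    desensitization_ratio: float = 0.65
    tau_desens: float = 1000.0        # ms, multiplicative peak->steady step
    spectrum: dict[float, float] = field(default_factory=lambda: {
        488.0: 1.0, 532.0: 0.6, 561.0: 0.2, 594.0: 0.05, 640.0: 0.003})

    def __post_init__(self):
        if min(self.g_max, self.EPD50, self.tau_on_sat, self.tau_off) <= 0:
            raise ValueError("g_max, EPD50, tau_on_sat, tau_off must be > 0")
        if not 0.0 <= self.f_H <= 1.0:
            raise ValueError("f_H must lie in [0, 1]")
        if not 0.0 < self.desensitization_ratio <= 1.0:
            raise ValueError("desensitization_ratio must lie in (0, 1]")
        ref = self.spectrum.get(REFERENCE_WAVELENGTH_NM)
        if ref is None or abs(ref - 1.0) > 1e-12:
            raise ValueError("spectrum must contain the 488-nm reference "
                             "with relative sensitivity 1")

    def sensitivity(self, wavelength: float) -> float:
        try:
            return self.spectrum[float(wavelength)]
        except KeyError:
            raise ValueError(
                f"wavelength {wavelength} nm absent from the action "
                f"spectrum {sorted(self.spectrum)}; refusing a silent zero"
            ) from None

    def steady_state_activation(self, intensity: float,
                                wavelength: float = REFERENCE_WAVELENGTH_NM,
                                ) -> float:
        """Pre-desensitization steady activation s(lambda)*P/(P+EPD50)."""
        if intensity < 0:
            raise ValueError("intensity must be >= 0")
        if intensity == 0:
            return 0.0
        return self.sensitivity(wavelength) * intensity / (intensity + self.EPD50)

    def tau_on(self, intensity: float) -> float:
        """Opening time constant (ms): tau_on_sat * (1 + EPD50/P)."""
        if intensity <= 0:
            raise ValueError("tau_on requires intensity > 0")
        return self.tau_on_sat * (1.0 + self.EPD50 / intensity)


#: CheRiff-like proton-conducting opsin (the acidifying reference actuator).
CHERIFF_LIKE = OpsinParams(g_max=3.0, E_ops=0.0, f_H=0.5, EPD50=22.0,
                           tau_on_sat=5.0, tau_off=16.0,
                           desensitization_ratio=0.65)

#: ChR2-3M-like: large currents, very light sensitive, slow, proton-tight.
CHR2_3M_LIKE = OpsinParams(g_max=6.0, E_ops=16.6, f_H=0.0, EPD50=11.6,
                           tau_on_sat=57.0, tau_off=1950.0,
                           desensitization_ratio=1.0,
                           spectrum={488.0: 1.0, 532.0: 0.6, 561.0: 0.2,
                                     594.0: 0.048, 640.0: 0.003})

#: PsCatCh2.0-like: fast, sag-free, proton-tight, less light sensitive.
PSCATCH2_LIKE = OpsinParams(g_max=4.0, E_ops=12.3, f_H=0.0, EPD50=116.0,
                            tau_on_sat=4.2, tau_off=17.6,
                            desensitization_ratio=0.92,
                            spectrum={488.0: 1.0, 532.0: 0.5, 561.0: 0.02,
                                      594.0: 0.003, 640.0: 0.003})


@dataclass(frozen=True)
class SensorParams:
    """pH reporter: Hill protonation curve plus a blue-light photoartifact.

    The artifact adds fluorescence ``F_max * artifact_rate * dose`` where
    ``dose`` is the cumulative blue exposure in J cm^-2; the default rate is
    calibrated so that an opsin-negative control under the canonical
    150-s protocol (100 x 0.5 s x 500 mW cm^-2 = 25 J cm^-2) shows a
    +0.11 dF/F rise, matching the measured control artifact.
    """

    pKa: float = 7.5
    hill_n: float = 1.0
    F_max: float = 1000.0
    artifact_rate: float = 0.11 / (1.0 + 10.0 ** (7.5 - 7.3)) / 25.0
    noise_sd: float = 0.0   # dF/F units, relative to the first clean frame

    def __post_init__(self):
        if not 4.0 < self.pKa < 10.0:
            raise ValueError("pKa must lie in (4, 10)")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def fluorescence(self, pH: np.ndarray) -> np.ndarray:
        """Clean sensor fluorescence F_max / (1 + 10^(n*(pKa - pH)))."""
        pH = np.asarray(pH, dtype=float)
        return self.F_max / (1.0 + 10.0 ** (self.hill_n * (self.pKa - pH)))


@dataclass(frozen=True)
class PhysiologyParams:
    """Passive membrane and proton-handling parameters.

    ``beta_buff`` is the cytosolic buffering capacity (mol acid per litre
    per pH unit; default 20 mM/pH, typical cytosolic range). ``k_rec`` is a
    first-order proton-extrusion rate toward ``pH_rest`` standing in for
    sodium-proton exchange; the default makes half-recovery slower than the
    150-s observation window, matching the slow, incomplete recovery seen
    experimentally.
    """

    C_m: float = 20.0            # pF
    g_leak: float = 2.0          # nS (Kir2.1-dominated)
    E_K: float = -70.0           # mV
    beta_buff: float = 0.020     # mol L^-1 per pH unit
    k_rec: float = 0.003         # s^-1
    pH_rest: float = 7.3
    temperature: float = 298.15  # K
    faraday: float = FARADAY_C_PER_MOL

    def __post_init__(self):
        if self.beta_buff <= 0:
            raise ValueError("beta_buff must be > 0")
        if self.k_rec < 0:
            raise ValueError("k_rec must be >= 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")


@dataclass
class SimTrace:
    """Simulated (V, pH, F) time courses on a common grid."""

    t: np.ndarray
    V: np.ndarray
    pH: np.ndarray
    F: np.ndarray
    epoch: np.ndarray       # per-sample channel label
    metadata: dict

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.V) == len(self.pH) == len(self.F)
                == len(self.epoch) == n):
            raise ValueError("SimTrace vectors must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.pH)) or np.any(self.pH <= 4.0) \
                or np.any(self.pH >= 9.0):
            raise ValueError("pH must be finite and within (4, 9)")


# ---------------------------------------------------------------------------
# Elementary integration steps (explicit Euler, public contract)
# ---------------------------------------------------------------------------

def opsin_gate(params: OpsinParams, intensity: float, wavelength: float,
               t_grid: np.ndarray, light_on: np.ndarray | None = None,
               a0: float = 0.0) -> np.ndarray:
    """Activation trace a(t) in [0, 1] for light of fixed intensity.

    ``light_on`` marks the samples during which the light is on (default:
    the whole grid). During light the open state relaxes toward
    s(lambda)*P/(P+EPD50) with tau_on(P); after light-off it decays with
    tau_off. A multiplicative desensitization factor relaxes from 1 to
    ``desensitization_ratio`` under light (and back in the dark) with
    ``tau_desens``, producing the peak-to-steady sag without a second
    photocycle state.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    n = len(t_grid)
    if light_on is None:
        on = np.ones(n, dtype=bool)
    else:
        on = np.asarray(light_on, dtype=bool)
        if len(on) != n:
            raise ValueError("light_on must match t_grid")
    a_inf = params.steady_state_activation(intensity, wavelength)
    tau_on_s = params.tau_on(intensity) * 1e-3 if intensity > 0 else np.inf
    tau_off_s = params.tau_off * 1e-3
    tau_d_s = params.tau_desens * 1e-3
    d_ratio = params.desensitization_ratio

    h = np.empty(n)
    d = np.empty(n)
    h_cur, d_cur = a0, 1.0
    h[0], d[0] = h_cur, d_cur
    for i in range(1, n):
        dt = t_grid[i] - t_grid[i - 1]
        if on[i - 1] and intensity > 0:
            h_cur = a_inf + (h_cur - a_inf) * np.exp(-dt / tau_on_s)
            d_cur = d_ratio + (d_cur - d_ratio) * np.exp(-dt / tau_d_s)
        else:
            h_cur = h_cur * np.exp(-dt / tau_off_s)
            d_cur = 1.0 + (d_cur - 1.0) * np.exp(-dt / tau_d_s)
        h[i], d[i] = h_cur, d_cur
    return h * d


def voltage_stability_bound(activation: float, opsin: OpsinParams,
                            phys: PhysiologyParams) -> float:
    """Largest admissible explicit-Euler step (s): C_m/(g_leak + g_max*a)."""
    g_tot = phys.g_leak + opsin.g_max * activation
    return phys.C_m / g_tot * 1e-3


def step_voltage(V: float, activation: float, opsin: OpsinParams,
                 phys: PhysiologyParams, dt: float) -> float:
    """One explicit-Euler step of C_m dV/dt = -g_leak(V-E_K) - g a (V-E_ops)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bound = voltage_stability_bound(activation, opsin, phys)
    if dt > bound:
        raise StabilityError(
            f"dt = {dt} s exceeds the explicit-Euler stability bound "
            f"C_m/(g_leak + g_max*a) = {bound:.3e} s")
    I_pA = (-phys.g_leak * (V - phys.E_K)
            - opsin.g_max * activation * (V - opsin.E_ops))
    return V + dt * 1e3 * I_pA / phys.C_m   # pA/pF = mV/ms


def proton_current_pA(V: float, activation: float, opsin: OpsinParams) -> float:
    """Proton component of the opsin current, f_H * g * a * (V - E_ops).

    Negative values are inward (protons entering, acidifying)."""
    return opsin.f_H * opsin.g_max * activation * (V - opsin.E_ops)


def ph_rate(pH: float, I_H_pA: float, geom: CompartmentGeometry,
            phys: PhysiologyParams) -> float:
    """d(pH)/dt from a proton current plus first-order extrusion.

    dpH/dt = I_H / (F * Volume * beta) + k_rec (pH_rest - pH); with the
    inward-negative current convention an inward proton current lowers pH.
    """
    if phys.beta_buff <= 0:
        raise ValueError("beta_buff must be > 0")
    mol_per_s = I_H_pA * 1e-12 / phys.faraday
    vol_L = geom.volume_um3 * 1e-15
    return mol_per_s / (vol_L * phys.beta_buff) \
        + phys.k_rec * (phys.pH_rest - pH)


def step_pH(pH: float, V: float, activation: float, opsin: OpsinParams,
            geom: CompartmentGeometry, phys: PhysiologyParams,
            dt: float) -> float:
    """One explicit-Euler step of the cytosolic pH balance."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    I_H = proton_current_pA(V, activation, opsin)
    return pH + dt * ph_rate(pH, I_H, geom, phys)


def initial_acidification_rate(current_density_pA_per_um2: float,
                               geom: CompartmentGeometry,
                               phys: PhysiologyParams) -> float:
    """|dpH/dt| at rest for a fixed inward proton current *density*.

    Equals J * (S/V) / (F * beta) up to unit conversion, so across
    geometries at fixed density it scales exactly as the
    surface-to-volume ratio.
    """
    I_H_pA = current_density_pA_per_um2 * geom.area_um2
    return abs(I_H_pA * 1e-12 / phys.faraday
               / (geom.volume_um3 * 1e-15 * phys.beta_buff))


# ---------------------------------------------------------------------------
# Fluorescence rendering
# ---------------------------------------------------------------------------

def render_fluorescence(pH: np.ndarray, t: np.ndarray,
                        protocol: StimulusProtocol, sensor: SensorParams,
                        seed: int | None = 0) -> np.ndarray:
    """Sensor fluorescence for a pH time course under a given protocol.

    F = F_max / (1 + 10^(n (pKa - pH))) + F_max * artifact_rate * dose(t)
    + Gaussian noise, where dose(t) is the cumulative blue-light exposure
    (J cm^-2). Noise sd is ``noise_sd`` times the first clean sample, so
    noise_sd is expressed in dF/F units. Deterministic given ``seed``.
    """
    pH = np.asarray(pH, dtype=float)
    if not np.all(np.isfinite(pH)):
        raise ValueError("pH trace must be finite")
    F = sensor.fluorescence(pH)
    F = F + sensor.F_max * sensor.artifact_rate * protocol.blue_dose_at(t)
    if sensor.noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, sensor.noise_sd * F[0], size=F.shape)
    return F


# ---------------------------------------------------------------------------
# Full single-compartment simulation
# ---------------------------------------------------------------------------

def _linear_recurrence(alpha: np.ndarray, beta: np.ndarray,
                       x0: float, chunk: int = 400) -> np.ndarray:
    """Solve x[i+1] = alpha[i] x[i] + beta[i] with x[0] = x0.

    Vectorized in chunks via cumulative products; chunk length keeps the
    products within floating-point range for the decay rates used here.
    """
    n = len(alpha) + 1
    x = np.empty(n)
    x[0] = x0
    pos = 0
    while pos < n - 1:
        m = min(chunk, n - 1 - pos)
        a = alpha[pos:pos + m]
        b = beta[pos:pos + m]
        P = np.cumprod(a)
        if P[-1] < 1e-200:   # very fast decay: sequential update is safe
            cur = x[pos]
            for j in range(m):
                cur = a[j] * cur + b[j]
                x[pos + 1 + j] = cur
        else:
            # x[pos+k+1] = P[k] * x[pos] + P[k] * sum_{j<=k} b[j]/P[j]
            s = np.cumsum(b / P)
            x[pos + 1:pos + m + 1] = P * (x[pos] + s)
        pos += m
    return x


def _gate_series(opsin: OpsinParams, t: np.ndarray, stim_on: np.ndarray,
                 intensity: float, wavelength: float) -> np.ndarray:
    """Gate trace on an arbitrary grid using per-step exact updates."""
    n = len(t)
    dt = np.diff(t)
    a_inf = opsin.steady_state_activation(intensity, wavelength)
    tau_on_s = opsin.tau_on(intensity) * 1e-3 if intensity > 0 else np.inf
    tau_off_s = opsin.tau_off * 1e-3
    tau_d_s = opsin.tau_desens * 1e-3
    on = stim_on[:-1]

    tau_h = np.where(on, tau_on_s, tau_off_s)
    target_h = np.where(on, a_inf, 0.0)
    alpha_h = np.exp(-dt / tau_h)
    h = _linear_recurrence(alpha_h, (1.0 - alpha_h) * target_h, 0.0)

    target_d = np.where(on, opsin.desensitization_ratio, 1.0)
    alpha_d = np.exp(-dt / tau_d_s)
    d = _linear_recurrence(alpha_d, (1.0 - alpha_d) * target_d, 1.0)
    return h * d


def simulate_cell(geom: CompartmentGeometry, opsin: OpsinParams,
                  sensor: SensorParams, phys: PhysiologyParams,
                  protocol: StimulusProtocol, seed: int | None = 0,
                  dt: float = 5e-4) -> SimTrace:
    """Jointly integrate gate, membrane voltage, and cytosolic pH, then
    render the sensor fluorescence.

    Gate, voltage, and pH all obey linear ODEs with coefficients frozen over
    each step, so each is advanced with its per-step exponential update
    (exact for frozen coefficients, unconditionally stable); coefficient
    freezing makes the scheme first-order accurate overall. Bitwise
    reproducible for a given ``seed``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = int(round(protocol.total_duration / dt)) + 1
    t = np.arange(n) * dt
    labels = protocol.labels_at(t)
    stim_on = labels == "stim"

    stim_eps = [ep for ep in protocol.epochs if ep.channel == "stim"]
    intensity = stim_eps[0].intensity if stim_eps else 0.0
    wavelength = stim_eps[0].wavelength if stim_eps else REFERENCE_WAVELENGTH_NM
    if intensity > 0:
        a = _gate_series(opsin, t, stim_on, intensity, wavelength)
    else:
        a = np.zeros(n)

    # Voltage: dV/dt = -(g_tot V - drive)/C_m ; exponential update per step.
    g_tot = phys.g_leak + opsin.g_max * a            # nS
    V_ss = (phys.g_leak * phys.E_K + opsin.g_max * a * opsin.E_ops) / g_tot
    alpha_V = np.exp(-dt * 1e3 * g_tot[:-1] / phys.C_m)
    V = _linear_recurrence(alpha_V, (1.0 - alpha_V) * V_ss[:-1], phys.E_K)

    # pH: dpH/dt = c(t) + k_rec (pH_rest - pH).
    I_H = opsin.f_H * opsin.g_max * a * (V - opsin.E_ops)        # pA
    c = I_H * 1e-12 / phys.faraday / (geom.volume_um3 * 1e-15
                                      * phys.beta_buff)          # pH/s
    if phys.k_rec > 0:
        alpha_p = np.full(n - 1, np.exp(-phys.k_rec * dt))
        target = phys.pH_rest + c[:-1] / phys.k_rec
        pH = _linear_recurrence(alpha_p, (1.0 - alpha_p) * target,
                                phys.pH_rest)
    else:
        pH = phys.pH_rest + np.concatenate([[0.0], np.cumsum(c[:-1] * dt)])

    F = render_fluorescence(pH, t, protocol, sensor, seed=seed)
    meta = {
        "seed": seed, "dt": dt,
        "geometry": dataclasses.asdict(geom),
        "opsin": dataclasses.asdict(opsin),
        "sensor": dataclasses.asdict(sensor),
        "physiology": dataclasses.asdict(phys),
    }
    return SimTrace(t=t, V=V, pH=pH, F=F, epoch=labels, metadata=meta)


# ---------------------------------------------------------------------------
# Synthetic movie rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIShape:
    """Disk-shaped region of interest on the camera frame."""

    label: int
    center_yx: tuple[float, float]   # px
    radius: float                    # px
    category: str = "soma"           # 'soma' | 'dendrite' | 'control'
    parent: int | None = None        # soma label for dendrites

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.ogrid[:shape[0], :shape[1]]
        cy, cx = self.center_yx
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius ** 2


def render_movie(traces: Sequence[SimTrace], layout: Sequence[ROIShape],
                 frame_shape: tuple[int, int], seed: int | None = 0,
                 frame_rate: float = 10.0, pixel_noise_sd: float = 0.0,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize per-compartment traces into a synthetic image stack.

    Returns ``(stack, frame_times, frame_labels, label_mask)``. Each ROI's
    pixels carry its trace's fluorescence (sampled at the frame time) plus
    independent Gaussian pixel noise; the background is zero. The returned
    16-bit-style label mask is the ground truth for segmentation tests.
    """
    if len(traces) != len(layout):
        raise ValueError("one trace per ROI shape required")
    label_mask = np.zeros(frame_shape, dtype=np.uint16)
    for shp in layout:
        m = shp.mask(frame_shape)
        if np.any(label_mask[m] != 0):
            raise ValueError(f"ROI {shp.label} overlaps another ROI")
        label_mask[m] = shp.label

    if traces:
        t_end = min(tr.t[-1] for tr in traces)
        n_frames = int(np.floor(t_end * frame_rate)) + 1
        frame_times = np.arange(n_frames) / frame_rate
        ref = traces[0]
        idx = np.clip(np.searchsorted(ref.t, frame_times, side="right") - 1,
                      0, len(ref.t) - 1)
        frame_labels = ref.epoch[idx]
    else:
        frame_times = np.array([0.0])
        frame_labels = np.array(["image"])
        idx = np.array([0])

    rng = np.random.default_rng(seed)
    stack = np.zeros((len(frame_times),) + tuple(frame_shape), dtype=float)
    for tr, shp in zip(traces, layout):
        m = shp.mask(frame_shape)
        i = np.clip(np.searchsorted(tr.t, frame_times, side="right") - 1,
                    0, len(tr.t) - 1)
        stack[:, m] = tr.F[i][:, None]
    if pixel_noise_sd > 0:
        stack = stack + rng.normal(0.0, pixel_noise_sd, size=stack.shape)
    return stack, frame_times, frame_labels, label_mask
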