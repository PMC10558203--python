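"""Gap-junction-coupled cell monolayer under patterned illumination.

A confluent monolayer is modelled as a square lattice of lumped cells with
4-neighbor ohmic coupling (conductance ``g_gap``) and no-flux boundaries.
Membrane voltage spreads between cells with an electrotonic length constant
``lambda = pitch * sqrt(g_gap / g_leak)``, whereas protons cross gap
junctions orders of magnitude more slowly (default exchange rate 0). Striped
blue illumination therefore depolarizes the whole sheet almost uniformly
while acidifying only the directly illuminated stripes — unless the proton
path is rerouted through a voltage-gated conductance present in every cell
(an explicit counterfactual mode), in which case acidification follows the
smooth voltage profile and the on/off contrast collapses to ~1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core_model import (
    CompartmentGeometry,
    OpsinParams,
    PhysiologyParams,
    StabilityError,
    CHERIFF_LIKE,
    DEFAULT_STIM_INTENSITY,
)

#: Floor on |dpH| used when forming on/off acidification ratios.
DPH_FLOOR = 1e-4


@dataclass(frozen=True)
class VoltageGatedProtonParams:
    """Counterfactual voltage-gated proton conductance, present in every
    cell regardless of illumination. Activation is a Boltzmann sigmoid of
    membrane voltage."""

    g_H: float = 1.0          # nS
    V_half: float = -50.0     # mV
    slope: float = 20.0       # mV
    E_rev: float = 10.0       # mV

    def activation(self, V: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(V) - self.V_half) / self.slope))

    def current_pA(self, V: np.ndarray) -> np.ndarray:
        """Inward-negative proton current through the gated conductance."""
        return self.g_H * self.activation(V) * (np.asarray(V) - self.E_rev)


@dataclass
class MonolayerGrid:
    """State and parameters of an n_y x n_x monolayer."""

    n_x: int
    n_y: int
    pitch: float = 20.0                    # um per cell
    g_gap: float = 50.0                    # nS per neighbor pair
    opsin: OpsinParams = CHERIFF_LIKE
    phys: PhysiologyParams = field(default_factory=PhysiologyParams)
    cell_volume_um3: float = 3200.0        # pitch^2 x ~8 um monolayer height
    k_gapH: float = 0.0                    # s^-1, gap-junction proton exchange
    vg_proton: VoltageGatedProtonParams | None = None
    expresses: np.ndarray | None = None    # per-cell opsin expression flag
    V: np.ndarray | None = None            # mV
    pH: np.ndarray | None = None

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0")
        shape = (self.n_y, self.n_x)
        if self.expresses is None:
            self.expresses = np.ones(shape, dtype=bool)
        if self.V is None:
            self.V = np.full(shape, self.phys.E_K, dtype=float)
        if self.pH is None:
            self.pH = np.full(shape, self.phys.pH_rest, dtype=float)
        for name in ("expresses", "V", "pH"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def length_constant_um(self) -> float:
        """Continuum electrotonic length constant pitch*sqrt(g_gap/g_leak)."""
        return self.pitch * np.sqrt(self.g_gap / self.phys.g_leak)

    def copy(self) -> "MonolayerGrid":
        return dataclasses.replace(
            self, expresses=self.expresses.copy(),
            V=self.V.copy(), pH=self.pH.copy())


@dataclass(frozen=True)
class IlluminationPattern:
    mask: np.ndarray          # bool, (n_y, n_x)
    intensity: float = DEFAULT_STIM_INTENSITY   # mW cm^-2
    wavelength: float = 488.0
    on_width: float | None = None   # um, for stripe patterns
    gap: float | None = None        # um


def stripe_pattern(grid: MonolayerGrid, on_width: float, gap: float,
                   intensity: float = DEFAULT_STIM_INTENSITY,
                   ) -> IlluminationPattern:
    """Vertical illumination stripes of ``on_width`` um separated by ``gap``
    um, rasterized to cell columns by their centre position."""
    if on_width <= 0 or gap < 0:
        raise ValueError("on_width must be > 0 and gap >= 0")
    period = on_width + gap
    if gap > 0 and period < 2 * grid.pitch:
        raise ValueError(
            f"stripe period {period} um is below 2 x pitch "
            f"({2 * grid.pitch} um); the pattern cannot be resolved")
    x_centers = (np.arange(grid.n_x) + 0.5) * grid.pitch
    col_on = (x_centers % period) < on_width if gap > 0 \
        else np.ones(grid.n_x, dtype=bool)
    mask = np.tile(col_on, (grid.n_y, 1))
    return IlluminationPattern(mask=mask, intensity=intensity,
                               on_width=on_width, gap=gap)


def _neighbor_sum(field2d: np.ndarray) -> np.ndarray:
    """Sum over 4-neighbors with no-flux (replicated-edge) boundaries,
    minus 4x the centre — i.e. the discrete Laplacian coupling term."""
    p = np.pad(field2d, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
            - 4.0 * field2d)


def gap_coupling_pA(grid: MonolayerGrid) -> np.ndarray:
    """Per-cell gap-junction current g_gap * sum_j (V_j - V_i); sums to
    zero over the grid (charge conservation)."""
    return grid.g_gap * _neighbor_sum(grid.V)


def activation_field(grid: MonolayerGrid, pattern: IlluminationPattern,
                     activation: float | None = None) -> np.ndarray:
    """Per-cell gate value: ``activation`` where illuminated and expressing,
    0 elsewhere. Default is the desensitized steady state at the pattern's
    intensity."""
    if pattern.mask.shape != grid.shape:
        raise ValueError("pattern mask shape must match grid")
    if activation is None:
        activation = (grid.opsin.steady_state_activation(
            pattern.intensity, pattern.wavelength)
            * grid.opsin.desensitization_ratio)
    return np.where(pattern.mask & grid.expresses, activation, 0.0)


def _proton_current_pA(grid: MonolayerGrid, a: np.ndarray) -> np.ndarray:
    """Inward-negative proton current per cell (opsin path plus, in the
    counterfactual mode, the ubiquitous voltage-gated path)."""
    I = grid.opsin.f_H * grid.opsin.g_max * a * (grid.V - grid.opsin.E_ops)
    if grid.vg_proton is not None:
        I = I + grid.vg_proton.current_pA(grid.V)
    return I


def step_field(grid: MonolayerGrid, pattern: IlluminationPattern, dt: float,
               activation: float | None = None) -> MonolayerGrid:
    """One explicit-Euler step of the coupled voltage/pH fields.

    Voltage: C_m dV_i/dt = -g_leak (V_i - E_K) - g a_i (V_i - E_ops)
    + g_gap sum_j (V_j - V_i). pH: per-cell proton current through
    ``ph_rate`` physics plus gap-junction proton exchange at rate k_gapH.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    phys, opsin = grid.phys, grid.opsin
    a = activation_field(grid, pattern, activation)
    g_tot_max = phys.g_leak + opsin.g_max * float(a.max()) + 4.0 * grid.g_gap
    bound = phys.C_m / g_tot_max * 1e-3
    if dt > bound:
        raise StabilityError(
            f"dt = {dt} s exceeds the coupled-system stability bound "
            f"C_m/(g_leak + g_max*a + 4 g_gap) = {bound:.3e} s")

    I_pA = (-phys.g_leak * (grid.V - phys.E_K)
            - opsin.g_max * a * (grid.V - opsin.E_ops)
            + grid.g_gap * _neighbor_sum(grid.V))
    V_new = grid.V + dt * 1e3 * I_pA / phys.C_m

    I_H = _proton_current_pA(grid, a)
    c = I_H * 1e-12 / phys.faraday / (grid.cell_volume_um3 * 1e-15
                                      * phys.beta_buff)
    dph = c + phys.k_rec * (phys.pH_rest - grid.pH)
    if grid.k_gapH > 0:
        dph = dph + grid.k_gapH * _neighbor_sum(grid.pH)
    pH_new = grid.pH + dt * dph

    out = grid.copy()
    out.V, out.pH = V_new, pH_new
    return out


def steady_state_voltage(grid: MonolayerGrid, pattern: IlluminationPattern,
                         activation: float | None = None) -> np.ndarray:
    """Exact steady-state voltage field by sparse linear solve.

    Solves (g_leak + g a_i) V_i - g_gap sum_j (V_j - V_i)
    = g_leak E_K + g a_i E_ops with no-flux boundaries.
    """
    phys, opsin = grid.phys, grid.opsin
    a = activation_field(grid, pattern, activation).ravel()
    ny, nx = grid.shape
    n = ny * nx
    diag = phys.g_leak + opsin.g_max * a
    rhs = phys.g_leak * phys.E_K + opsin.g_max * a * opsin.E_ops

    idx = np.arange(n).reshape(ny, nx)
    rows, cols, vals = [], [], []
    for shift in ((0, 1), (1, 0)):
        dy, dx = shift
        src = idx[:ny - dy, :nx - dx].ravel()
        dst = idx[dy:, dx:].ravel()
        rows += [src, dst]
        cols += [dst, src]
        vals += [np.full(src.size, -grid.g_gap)] * 2
        deg = np.zeros(n)
        np.add.at(deg, src, grid.g_gap)
        np.add.at(deg, dst, grid.g_gap)
        diag = diag + deg
    A = sparse.coo_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n)]),
          np.concatenate(cols + [np.arange(n)]))), shape=(n, n)).tocsr()
    return spsolve(A, rhs).reshape(ny, nx)


def simulate_monolayer(grid: MonolayerGrid, pattern: IlluminationPattern,
                       stim_total_s: float, duty: float = 1.0 / 3.0,
                       dt_pH: float = 0.05) -> MonolayerGrid:
    """Quasi-static monolayer run: voltage settles within milliseconds, pH
    evolves over seconds, so the voltage field is solved exactly once per
    illumination phase and the slow pH balance is integrated on top.

    ``stim_total_s`` is the cumulative protocol duration and ``duty`` the
    fraction of it spent under blue light (interleaved protocols stimulate
    ~1/3 of the time). Returns the grid after stimulation, with ``V`` set
    to the during-stimulation steady state.
    """
    if not 0.0 < duty <= 1.0:
        raise ValueError("duty must lie in (0, 1]")
    out = grid.copy()
    out.V = steady_state_voltage(grid, pattern)
    phys = grid.phys
    a = activation_field(out, pattern)
    I_H = _proton_current_pA(out, a)
    c_stim = I_H * 1e-12 / phys.faraday / (grid.cell_volume_um3 * 1e-15
                                           * phys.beta_buff)
    n_steps = max(1, int(round(stim_total_s / dt_pH)))
    dt = stim_total_s / n_steps
    pH = out.pH
    for _ in range(n_steps):
        dph = duty * c_stim + phys.k_rec * (phys.pH_rest - pH)
        if grid.k_gapH > 0:
            dph = dph + grid.k_gapH * _neighbor_sum(pH)
        pH = pH + dt * dph
    out.pH = pH
    return out


@dataclass(frozen=True)
class AcidificationContrast:
    dpH_on: float            # mean pH change of illuminated cells
    dpH_off: float           # mean pH change of non-illuminated cells
    ratio: float             # |dpH_on| / max(|dpH_off|, floor)
    no_signal: bool


def acidification_contrast(grids, pattern: IlluminationPattern,
                           ) -> AcidificationContrast:
    """On-stripe vs off-stripe acidification from a grid history (first and
    last states are used). The ratio is floored at 1e-4 pH units to avoid
    division by zero; if neither group acidified beyond the floor the ratio
    is reported as 1 with ``no_signal`` set."""
    first, last = grids[0], grids[-1]
    on = pattern.mask
    if on.all() or not on.any():
        raise ValueError("pattern must contain both on- and off-stripe cells")
    dpH = last.pH - first.pH
    dpH_on = float(dpH[on].mean())
    dpH_off = float(dpH[~on].mean())
    if abs(dpH_on) < DPH_FLOOR and abs(dpH_off) < DPH_FLOOR:
        return AcidificationContrast(dpH_on, dpH_off, 1.0, True)
    ratio = abs(dpH_on) / max(abs(dpH_off), DPH_FLOOR)
    return AcidificationContrast(dpH_on, dpH_off, ratio, False)
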