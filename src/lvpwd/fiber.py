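"""1D transmural fiber simulation: action-potential propagation, pseudo-ECG,
QT and Fridericia-corrected QT.

A string of virtual left-ventricular cardiomyocytes (50% endocardial, 30%
midmyocardial, 20% epicardial, paced at the endocardial end) whose physical
length is the diastolic LV posterior wall thickness.  The membrane potential
obeys the monodomain cable equation

    dV/dt = D * d2V/dx2 - I_ion / C_m,

with per-node kinetics from either the detailed ten Tusscher–Panfilov (2006)
model or a fast two-current surrogate.  A unipolar pseudo-ECG is evaluated at
a virtual electrode on the fiber axis beyond the epicardial end, and QT is
read off it with the tangent method.  An optional drug blocks the rapid
delayed-rectifier current I_Kr with Hill-equation concentration dependence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernels

__all__ = [
    "PhysioParams",
    "FiberConfig",
    "DrugBlock",
    "PseudoECG",
    "FiberResult",
    "TABLE_PHYSIO",
    "sample_physio",
    "block_fraction",
    "build_fiber",
    "simulate_fiber",
    "simulate_single_cell",
    "pseudo_ecg",
    "measure_qt",
    "fridericia",
    "apd90",
]


class StabilityError(RuntimeError):
    """Numerical blow-up of the explicit scheme."""


class MeasurementError(RuntimeError):
    """A waveform feature (e.g. the T wave) could not be detected."""


@dataclass(frozen=True)
class PhysioParams:
    """Virtual-individual physiology (population means as defaults)."""

    k_plasma_mM: float = 4.29
    na_plasma_mM: float = 139.37
    ca_plasma_mM: float = 2.36
    cell_volume_um3: float = 7254.90
    stim_period_ms: float = 909.37
    capacitance_pF: float = 55.16

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


# population mean (SD) of each physiological parameter
TABLE_PHYSIO = {
    "k_plasma_mM": (4.29, 0.28),
    "na_plasma_mM": (139.37, 1.26),
    "ca_plasma_mM": (2.36, 0.18),
    "cell_volume_um3": (7254.90, 4912.68),
    "stim_period_ms": (909.37, 136.20),
    "capacitance_pF": (55.16, 32.91),
}


def sample_physio(n: int, seed=None) -> list[PhysioParams]:
    """Draw ``n`` virtual individuals' physiological parameters.

    Each parameter is a truncated normal at +/-3 SD with a positivity floor at
    10% of the mean; the cardiomyocyte volume, whose SD is over half its mean,
    uses a log-normal matched to the same mean/SD instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {}
    for name, (m, s) in TABLE_PHYSIO.items():
        if name == "cell_volume_um3":
            sigma2 = math.log(1.0 + (s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            draws[name] = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        else:
            lo = max(m - 3.0 * s, 0.1 * m)
            hi = m + 3.0 * s
            a, b = (lo - m) / s, (hi - m) / s
            draws[name] = stats.truncnorm.rvs(a, b, loc=m, scale=s, size=n,
                                              random_state=rng)
    return [PhysioParams(**{k: float(draws[k][i]) for k in draws}) for i in range(n)]


@dataclass(frozen=True)
class DrugBlock:
    """Hill-equation block of a repolarizing current."""

    ic50_uM: float
    hill_n: float = 1.0
    concentration_uM: float = 0.0
    target_current: str = "I_Kr"

    def __post_init__(self) -> None:
        if self.ic50_uM <= 0 or self.hill_n <= 0 or self.concentration_uM < 0:
            raise ValueError("require ic50 > 0, hill_n > 0, concentration >= 0")


def block_fraction(drug: DrugBlock | None) -> float:
    """Fractional current inhibition, C^N / (C^N + IC50^N)."""
    if drug is None or drug.concentration_uM == 0.0:
        return 0.0
    cn = drug.concentration_uM ** drug.hill_n
    return cn / (cn + drug.ic50_uM ** drug.hill_n)


DEFAULT_LAYOUT = (0.5, 0.3, 0.2)  # endo, mid, epi fractions
DEFAULT_DX_MM = 0.1
DEFAULT_DT_MS = 0.015  # explicit stability bound dx^2/(2D) with safety >= 2
DEFAULT_D_MM2_MS = 0.154  # 0.00154 cm^2/ms


@dataclass(frozen=True)
class FiberConfig:
    """Geometry and numerics of the transmural string."""

    length_mm: float
    dx_mm: float = DEFAULT_DX_MM
    cell_type_layout: tuple[float, float, float] = DEFAULT_LAYOUT
    diffusion_mm2_ms: float = DEFAULT_D_MM2_MS
    dt_ms: float = DEFAULT_DT_MS
    n_beats: int = 9                  # >= 8 conditioning beats + measured beat
    stim_amplitude: float | None = None   # model-specific default if None
    stim_duration_ms: float = 1.0
    n_nodes: int = field(init=False)
    counts: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        if abs(sum(self.cell_type_layout) - 1.0) > 1e-9:
            raise ValueError("cell-type fractions must sum to 1")
        if self.dx_mm <= 0 or self.dt_ms <= 0:
            raise ValueError("dx and dt must be positive")
        n = int(math.floor(self.length_mm / self.dx_mm + 0.5))
        if n < 10:
            raise ValueError(
                f"{self.length_mm} mm at dx={self.dx_mm} mm gives only {n} nodes; "
                "need at least 10 for a resolved transmural profile")
        # segments in endo -> mid -> epi order; last takes the rounding remainder
        c0 = int(math.floor(n * self.cell_type_layout[0] + 0.5))
        c1 = int(math.floor(n * self.cell_type_layout[1] + 0.5))
        c2 = n - c0 - c1
        if min(c0, c1, c2) < 1:
            raise ValueError("every transmural segment needs at least one node")
        object.__setattr__(self, "n_nodes", n)
        object.__setattr__(self, "counts", (c0, c1, c2))
        bound = self.dx_mm ** 2 / (2.0 * self.diffusion_mm2_ms)
        if self.dt_ms > bound:
            raise ValueError(
                f"dt={self.dt_ms} ms violates the explicit stability bound "
                f"dx^2/(2D) = {bound:.4g} ms")

    @property
    def cell_types(self) -> np.ndarray:
        return np.repeat(np.array([0, 1, 2], dtype=np.int64), self.counts)

    @property
    def stability_safety_factor(self) -> float:
        return self.dx_mm ** 2 / (2.0 * self.diffusion_mm2_ms) / self.dt_ms


def build_fiber(lvpwd_mm: float, dx_mm: float = DEFAULT_DX_MM,
                layout: tuple[float, float, float] = DEFAULT_LAYOUT,
                **kwargs) -> FiberConfig:
    """Fiber configuration for a given wall thickness; endo end is paced."""
    if not (0.0 < lvpwd_mm <= 20.0):
        raise ValueError(f"wall thickness {lvpwd_mm} mm outside (0, 20] mm")
    return FiberConfig(length_mm=lvpwd_mm, dx_mm=dx_mm,
                       cell_type_layout=tuple(layout), **kwargs)


@dataclass
class FiberResult:
    """Recorded membrane-potential field of the measured (final) beat."""

    time_ms: np.ndarray            # since the measured beat's stimulus
    x_mm: np.ndarray
    V: np.ndarray                  # (n_times, n_nodes), mV
    rr_ms: float
    config: FiberConfig


@dataclass
class PseudoECG:
    time_ms: np.ndarray
    signal: np.ndarray             # arbitrary units
    rr_ms: float
    qt_ms: float | None = None
    qtcf_ms: float | None = None


def simulate_fiber(fiber: FiberConfig, physio: PhysioParams,
                   drug: DrugBlock | None = None, *,
                   cell_model: str = "tp06",
                   record_every_ms: float = 1.0,
                   paced: bool = True) -> FiberResult:
    """Pace the fiber for ``n_beats`` cycles and return the final beat's field.

    ``cell_model`` selects the detailed tp06 kinetics or the fast two-current
    surrogate.  Setting ``paced=False`` leaves the fiber unstimulated (resting
    stability checks).
    """
    n = fiber.n_nodes
    ctypes = fiber.cell_types
    gkr_scale = 1.0 - block_fraction(drug)
    n_stim = max(3, int(round(0.5 / fiber.dx_mm)))  # ~0.5 mm stimulated endo tip
    period = physio.stim_period_ms

    if cell_model == "tp06":
        amp = -52.0 if fiber.stim_amplitude is None else fiber.stim_amplitude
        cfac = ((physio.capacitance_pF / _kernels.CM_REF_PF)
                / (physio.cell_volume_um3 / _kernels.V_C))
        y = _kernels.tp06_initial_state(n)
        Vrec, status = _kernels.run_tp06(
            y, ctypes, fiber.diffusion_mm2_ms, fiber.dx_mm, fiber.dt_ms,
            period, fiber.n_beats, amp, fiber.stim_duration_ms, n_stim,
            physio.k_plasma_mM, physio.na_plasma_mM, physio.ca_plasma_mM,
            gkr_scale, cfac, record_every_ms, paced)
    elif cell_model == "surrogate":
        amp = 0.5 if fiber.stim_amplitude is None else fiber.stim_amplitude
        k_ref = TABLE_PHYSIO["k_plasma_mM"][0]
        tau_close = np.array([_kernels.MS_TAU_CLOSE[t] for t in ctypes])
        tau_close = tau_close * (1.0 + _kernels.MS_BLOCK_GAIN * block_fraction(drug))
        tau_close = tau_close * (k_ref / physio.k_plasma_mM) ** _kernels.MS_K_SENS
        u = np.zeros(n)
        hgate = np.ones(n)
        Urec, status = _kernels.run_ms(
            u, hgate, tau_close, fiber.diffusion_mm2_ms, fiber.dx_mm,
            fiber.dt_ms, period, fiber.n_beats, amp, fiber.stim_duration_ms,
            n_stim, record_every_ms, paced)
        Vrec = _kernels.MS_V_REST + _kernels.MS_V_AMP * Urec
    else:
        raise ValueError(f"unknown cell model {cell_model!r}")

    if status != 0:
        raise StabilityError(
            f"numerical blow-up (|V| > 200 mV) with dt={fiber.dt_ms} ms, "
            f"dx={fiber.dx_mm} mm; refine the discretization")
    t = np.arange(Vrec.shape[0]) * record_every_ms
    x = np.arange(n) * fiber.dx_mm
    return FiberResult(time_ms=t, x_mm=x, V=Vrec, rr_ms=period, config=fiber)


def simulate_single_cell(physio: PhysioParams, drug: DrugBlock | None = None, *,
                         cell_type: int = 0, cell_model: str = "tp06",
                         n_beats: int = 9, dt_ms: float = DEFAULT_DT_MS,
                         record_every_ms: float = 1.0,
                         paced: bool = True) -> FiberResult:
    """Isolated (diffusion-free) cardiomyocyte paced at the individual's rate.

    ``cell_type``: 0 endocardial, 1 midmyocardial, 2 epicardial.
    """
    ctypes = np.array([cell_type], dtype=np.int64)
    gkr_scale = 1.0 - block_fraction(drug)
    period = physio.stim_period_ms
    if cell_model == "tp06":
        cfac = ((physio.capacitance_pF / _kernels.CM_REF_PF)
                / (physio.cell_volume_um3 / _kernels.V_C))
        y = _kernels.tp06_initial_state(1)
        Vrec, status = _kernels.run_tp06(
            y, ctypes, 0.0, 1.0, dt_ms, period, n_beats, -52.0, 1.0, 1,
            physio.k_plasma_mM, physio.na_plasma_mM, physio.ca_plasma_mM,
            gkr_scale, cfac, record_every_ms, paced)
    elif cell_model == "surrogate":
        k_ref = TABLE_PHYSIO["k_plasma_mM"][0]
        tau_close = np.array([_kernels.MS_TAU_CLOSE[cell_type]])
        tau_close = tau_close * (1.0 + _kernels.MS_BLOCK_GAIN * block_fraction(drug))
        tau_close = tau_close * (k_ref / physio.k_plasma_mM) ** _kernels.MS_K_SENS
        u, hgate = np.zeros(1), np.ones(1)
        Urec, status = _kernels.run_ms(
            u, hgate, tau_close, 0.0, 1.0, dt_ms, period, n_beats, 0.5, 1.0, 1,
            record_every_ms, paced)
        Vrec = _kernels.MS_V_REST + _kernels.MS_V_AMP * Urec
    else:
        raise ValueError(f"unknown cell model {cell_model!r}")
    if status != 0:
        raise StabilityError(f"numerical blow-up at dt={dt_ms} ms (single cell)")
    t = np.arange(Vrec.shape[0]) * record_every_ms
    dummy = object.__new__(FiberConfig)  # no geometry for a point cell
    object.__setattr__(dummy, "length_mm", 0.0)
    object.__setattr__(dummy, "dx_mm", 1.0)
    object.__setattr__(dummy, "cell_type_layout", (1.0, 0.0, 0.0))
    object.__setattr__(dummy, "diffusion_mm2_ms", 0.0)
    object.__setattr__(dummy, "dt_ms", dt_ms)
    object.__setattr__(dummy, "n_beats", n_beats)
    object.__setattr__(dummy, "stim_amplitude", None)
    object.__setattr__(dummy, "stim_duration_ms", 1.0)
    object.__setattr__(dummy, "n_nodes", 1)
    object.__setattr__(dummy, "counts", (1, 0, 0))
    return FiberResult(time_ms=t, x_mm=np.zeros(1), V=Vrec, rr_ms=period,
                       config=dummy)


def pseudo_ecg(result: FiberResult, electrode_distance_mm: float = 20.0) -> PseudoECG:
    """Unipolar extracellular potential at an axial electrode beyond the epi end.

    Standard 1D construction: phi(t) proportional to the integral of
    (-dV/dx) * d(1/r)/dx over the fiber, r(x) the distance to the electrode.
    A transmural repolarization gradient yields an upright T wave.
    """
    if electrode_distance_mm <= 0:
        raise ValueError("electrode distance must be positive")
    x = result.x_mm
    xe = x[-1] + electrode_distance_mm
    r = xe - x
    dVdx = np.gradient(result.V, x, axis=1)
    signal = np.sum(-dVdx * (1.0 / r ** 2)[None, :], axis=1) * result.config.dx_mm
    if float(np.ptp(result.V)) < 1.0:
        warnings.warn("membrane potential field is nearly constant; flat pseudo-ECG")
    return PseudoECG(time_ms=result.time_ms, signal=signal, rr_ms=result.rr_ms)


def measure_qt(ecg: PseudoECG, *, qrs_end_ms: float = 80.0,
               baseline_window_ms: float = 50.0) -> float:
    """QT interval (ms) by the tangent method.

    Q onset is the stimulus instant of the measured beat (t = 0).  T end is
    the intersection of the steepest post-peak T-wave downslope with the
    isoelectric baseline, the baseline being the mean signal over the final
    ``baseline_window_ms`` of the cycle.
    """
    t, sig = ecg.time_ms, ecg.signal
    nb = max(int(baseline_window_ms / max(t[1] - t[0], 1e-9)), 1)
    baseline = float(np.mean(sig[-nb:]))
    s = sig - baseline
    smax = float(np.max(np.abs(s)))
    if smax < 1e-12:
        raise MeasurementError("flat pseudo-ECG; no T wave to measure")
    after = np.flatnonzero(t >= qrs_end_ms)
    if after.size == 0:
        raise MeasurementError("trace shorter than the QRS window")
    st = np.abs(s[after])
    tmax = float(np.max(st))
    if tmax < 0.02 * smax:
        raise MeasurementError("no discernible T wave after the QRS window")
    # terminal repolarization = the LAST deflection reaching 30% of the
    # post-QRS maximum; a transmural T wave may be multiphasic
    big = after[st >= 0.3 * tmax]
    splits = np.flatnonzero(np.diff(big) > 1)
    cluster = big[splits[-1] + 1:] if splits.size else big
    ipeak = cluster[np.argmax(np.abs(s[cluster]))]
    pol = 1.0 if s[ipeak] > 0 else -1.0
    sp = pol * s
    ds = np.gradient(sp, t)
    # steepest downslope between the T peak and the return to baseline
    tail = np.arange(ipeak, len(t))
    below = tail[sp[tail] < 0.05 * sp[ipeak]]
    stop = below[0] if below.size else len(t) - 1
    seg = np.arange(ipeak, max(stop, ipeak + 2))
    isl = seg[np.argmin(ds[seg])]
    slope = ds[isl]
    if slope >= 0:
        raise MeasurementError("T wave has no terminal limb")
    t_end = t[isl] - sp[isl] / slope
    qt = float(t_end)
    if not (0.0 < qt < ecg.rr_ms):
        raise MeasurementError(f"implausible QT {qt:.1f} ms for RR {ecg.rr_ms:.1f} ms")
    return qt


def fridericia(qt_ms: float, rr_ms: float) -> float:
    """Fridericia heart-rate correction, QTcF = QT / (RR/1000)^(1/3)."""
    if qt_ms <= 0 or rr_ms <= 0:
        raise ValueError("QT and RR must be positive")
    return qt_ms / (rr_ms / 1000.0) ** (1.0 / 3.0)


def apd90(time_ms: np.ndarray, v: np.ndarray) -> float:
    """Action-potential duration at 90% repolarization of a single-node trace."""
    v = np.asarray(v, dtype=float)
    vrest = float(v[0])
    vpeak = float(np.max(v))
    if vpeak - vrest < 20.0:
        raise MeasurementError("no action potential in trace")
    ipeak = int(np.argmax(v))
    v90 = vpeak - 0.9 * (vpeak - vrest)
    after = np.flatnonzero(v[ipeak:] <= v90)
    if after.size == 0:
        raise MeasurementError("trace ends before 90% repolarization")
    i = ipeak + after[0]
    # linear interpolation across the crossing
    t0, t1 = time_ms[i - 1], time_ms[i]
    f = (v[i - 1] - v90) / (v[i - 1] - v[i])
    iup = int(np.flatnonzero(v >= vrest + 0.1 * (vpeak - vrest))[0])
    return float(t0 + f * (t1 - t0) - time_ms[iup])
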