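"""Single-cell model: gating functions, RK4 stepping, calibration and
excitability characterization (f-I curve, phase response curve, adaptation).

The membrane follows a Hodgkin-Huxley-type equation with an instantaneous
sodium activation gate m (``m = m_inf(V)``), sodium inactivation h, delayed
rectifier n, and a slow potassium (M-type) gate s with a fixed 75 ms time
constant. The slow potassium conductance ``gKs_max`` is the cholinergic
control parameter: raising it strengthens spike-frequency adaptation and
shifts the phase response curve from type 1 (advance-only) to type 2 (with an
early delay lobe).

The direct current ``I_tune`` is calibrated per ``gKs_max`` so the isolated
cell fires at a common target rate (10 Hz in all network experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import NO_SPIKE, pack_neuron_params, pack_synapse_params
from .params import GateParams, NeuronParams, SynapseParams

__all__ = [
    "NeuronState",
    "PRCSample",
    "PRCResult",
    "EnsembleResult",
    "gate_steady_state",
    "gate_tau",
    "membrane_derivative",
    "rk4_step",
    "run_ensemble",
    "firing_rate",
    "calibrate_itune",
    "compute_fi_curve",
    "compute_prc",
    "step_response_isis",
    "CalibrationError",
]

SPIKE_THRESHOLD_MV = 0.0  # upward crossing defines a spike
SPIKE_LOCKOUT_MS = 2.0  # refractory window for detection


class CalibrationError(RuntimeError):
    pass


@dataclass
class NeuronState:
    """Dynamical state (V; gates h, n, s). m is instantaneous, not a state."""

    V: float
    h: float
    n: float
    s: float

    @classmethod
    def at_rest(cls, p: NeuronParams, V: float = -60.0) -> "NeuronState":
        """State with gates at their steady values for the given voltage."""
        return cls(
            V=V,
            h=gate_steady_state(V, p.h),
            n=gate_steady_state(V, p.n),
            s=gate_steady_state(V, p.s),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.n, self.s], dtype=float)


@dataclass(frozen=True)
class PRCSample:
    phase: float  # in [0, 1)
    shift: float  # (T - T_perturbed)/T; positive = phase advance


@dataclass(frozen=True)
class PRCResult:
    samples: tuple[PRCSample, ...]
    period_ms: float
    pulse_amplitude: float  # uA/cm^2
    prc_type: int  # 1 or 2

    @property
    def phases(self) -> np.ndarray:
        return np.array([s.phase for s in self.samples])

    @property
    def shifts(self) -> np.ndarray:
        return np.array([s.shift for s in self.samples])


def gate_steady_state(V: float, g: GateParams) -> float:
    """Logistic steady-state activation ``1/(1 + exp((alpha - V)/beta))``."""
    return 1.0 / (1.0 + math.exp((g.alpha - V) / g.beta))


def gate_tau(V: float, g: GateParams) -> float:
    """Gate time constant: fixed if configured, else the sigmoidal form
    ``0.37 + D/(1 + exp((gamma + V)/eps))`` (ms)."""
    return g.tau(V)


def membrane_derivative(
    state: NeuronState, p: NeuronParams, I_syn: float = 0.0
) -> NeuronState:
    """Time derivative of the state (reference implementation).

    ``I_syn`` follows the membrane equation's sign convention: it is
    subtracted, so a positive value is hyperpolarizing.
    """
    V = state.V
    m_inf = gate_steady_state(V, p.m)
    i_na = p.gNa_max * m_inf**3 * state.h * (V - p.ENa)
    i_kdr = p.gKdr_max * state.n**4 * (V - p.EK)
    i_ks = p.gKs_max * state.s * (V - p.EK)
    i_l = p.gl * (V - p.El)
    dV = (-i_na - i_kdr - i_ks - i_l + p.I_tune - I_syn) / p.cm
    dh = (gate_steady_state(V, p.h) - state.h) / gate_tau(V, p.h)
    dn = (gate_steady_state(V, p.n) - state.n) / gate_tau(V, p.n)
    ds = (gate_steady_state(V, p.s) - state.s) / gate_tau(V, p.s)
    return NeuronState(V=dV, h=dh, n=dn, s=ds)


def rk4_step(
    state: NeuronState,
    p: NeuronParams,
    I_syn_fn,
    dt: float,
    t: float = 0.0,
) -> NeuronState:
    """One classical RK4 step of the full state (reference implementation).

    ``I_syn_fn(t)`` gives the synaptic current at absolute time t. Gates are
    clamped to [0, 1] against round-off only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    def f(y: NeuronState, ts: float) -> NeuronState:
        return membrane_derivative(y, p, I_syn_fn(ts))

    def axpy(y: NeuronState, k: NeuronState, a: float) -> NeuronState:
        return NeuronState(y.V + a * k.V, y.h + a * k.h, y.n + a * k.n, y.s + a * k.s)

    k1 = f(state, t)
    k2 = f(axpy(state, k1, dt / 2), t + dt / 2)
    k3 = f(axpy(state, k2, dt / 2), t + dt / 2)
    k4 = f(axpy(state, k3, dt), t + dt)
    out = NeuronState(
        state.V + dt / 6 * (k1.V + 2 * k2.V + 2 * k3.V + k4.V),
        state.h + dt / 6 * (k1.h + 2 * k2.h + 2 * k3.h + k4.h),
        state.n + dt / 6 * (k1.n + 2 * k2.n + 2 * k3.n + k4.n),
        state.s + dt / 6 * (k1.s + 2 * k2.s + 2 * k3.s + k4.s),
    )
    if not np.isfinite(out.V):
        raise FloatingPointError(f"non-finite voltage after step at t={t}")
    for gname in ("h", "n", "s"):
        val = getattr(out, gname)
        setattr(out, gname, min(1.0, max(0.0, val)))
    return out


@dataclass
class EnsembleResult:
    """Outcome of integrating a batch of unconnected cells."""

    spike_cells: np.ndarray
    spike_times: np.ndarray  # ms
    final_V: np.ndarray
    final_h: np.ndarray
    final_n: np.ndarray
    final_s: np.ndarray
    duration_ms: float
    dt: float
    V_trace: np.ndarray | None = None  # (n_samples, n_recorded)
    trace_times: np.ndarray | None = None

    def spikes_of(self, i: int) -> np.ndarray:
        return self.spike_times[self.spike_cells == i]


_DUMMY_SYN = pack_synapse_params(
    SynapseParams(tau_F=0.3, tau_S=3.0, tau_D=1.0, E_exc=0.0, E_inh=-75.0)
)


def run_ensemble(
    p: NeuronParams,
    n_cells: int = 1,
    duration_ms: float = 5000.0,
    dt: float = 0.05,
    V0: float | np.ndarray = -60.0,
    I_extra: float | np.ndarray = 0.0,
    stim_on: float | np.ndarray = 0.0,
    stim_off: float | np.ndarray = math.inf,
    state: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
    record: bool = False,
    rec_stride: int = 4,
) -> EnsembleResult:
    """Integrate ``n_cells`` unconnected copies of the neuron.

    Each cell i receives the common calibrated ``I_tune`` plus ``I_extra[i]``
    during its stimulus window ``[stim_on[i], stim_off[i])`` — this one
    mechanism covers constant current offsets (window = whole run, used for
    f-I curves) and brief pulses (used for PRCs). Initial gates sit at their
    steady state for ``V0`` unless a full ``state`` is supplied.
    """
    nsteps = int(round(duration_ms / dt))
    if state is not None:
        V, h, n, s = (np.array(a, dtype=float) for a in state)
    else:
        V = np.full(n_cells, V0, dtype=float) if np.isscalar(V0) else np.array(V0, float)
        h = np.array([gate_steady_state(v, p.h) for v in V])
        n = np.array([gate_steady_state(v, p.n) for v in V])
        s = np.array([gate_steady_state(v, p.s) for v in V])
    nc = V.shape[0]

    def vec(x):
        return np.full(nc, x, dtype=float) if np.isscalar(x) else np.asarray(x, float)

    stim_amp = vec(I_extra)
    on = vec(stim_on)
    off = vec(stim_off)
    # inf upper bounds are fine: the kernel compares with <
    off = np.where(np.isinf(off), 1e18, off)

    is_inh = np.zeros(nc, dtype=np.bool_)
    indptr = np.zeros(nc + 1, dtype=np.int64)
    indices = np.zeros(0, dtype=np.int64)
    weights = np.zeros(0, dtype=np.float64)
    last_spike = np.full(nc, NO_SPIKE, dtype=float)
    last_detect = np.full(nc, NO_SPIKE, dtype=float)
    cap = int(nc * (duration_ms / SPIKE_LOCKOUT_MS + 2))
    spike_cells = np.zeros(cap, dtype=np.int64)
    spike_times = np.zeros(cap, dtype=np.float64)

    if record:
        record_idx = np.arange(nc, dtype=np.int64)
        n_samples = nsteps // rec_stride + 1
        V_rec = np.zeros((n_samples, nc), dtype=np.float64)
    else:
        record_idx = np.zeros(0, dtype=np.int64)
        V_rec = np.zeros((1, 0), dtype=np.float64)

    nsp, bad_cell, bad_time = _kernels.integrate(
        V, h, n, s, is_inh, pack_neuron_params(p), _DUMMY_SYN,
        indptr, indices, weights, 0.0,
        stim_amp, on, off,
        float(dt), nsteps, 0.0,
        SPIKE_THRESHOLD_MV, SPIKE_LOCKOUT_MS,
        last_spike, last_detect,
        spike_cells, spike_times,
        record_idx, rec_stride, V_rec,
    )
    if bad_cell >= 0:
        raise FloatingPointError(
            f"non-finite state in cell {bad_cell} at t={bad_time:.3f} ms"
        )
    return EnsembleResult(
        spike_cells=spike_cells[:nsp].copy(),
        spike_times=spike_times[:nsp].copy(),
        final_V=V, final_h=h, final_n=n, final_s=s,
        duration_ms=duration_ms, dt=dt,
        V_trace=V_rec if record else None,
        trace_times=np.arange(V_rec.shape[0]) * dt * rec_stride if record else None,
    )


def firing_rate(
    spike_times: np.ndarray, transient_ms: float, duration_ms: float
) -> float:
    """Steady firing rate (Hz) from spikes after a transient.

    Uses the span between first and last retained spike, ``(n-1)/span``,
    which is insensitive to window-edge alignment; returns 0 for < 2 spikes.
    """
    t = np.asarray(spike_times, dtype=float)
    t = t[(t > transient_ms) & (t <= duration_ms)]
    if t.size < 2:
        return 0.0
    span = t[-1] - t[0]
    if span <= 0:
        return 0.0
    return (t.size - 1) / span * 1000.0


def _rate_at(p: NeuronParams, itune: float, duration: float, transient: float,
             dt: float) -> float:
    res = run_ensemble(p.with_itune(itune), n_cells=1, duration_ms=duration, dt=dt)
    return firing_rate(res.spike_times, transient, duration)


def calibrate_itune(
    p: NeuronParams,
    target_rate: float = 10.0,
    tol_hz: float = 0.2,
    duration_ms: float = 5000.0,
    transient_ms: float = 1000.0,
    dt: float = 0.05,
    max_current: float = 64.0,
) -> float:
    """Find I_tune (uA/cm^2) giving the isolated cell the target rate.

    Bisection on the steady rate measured over ``duration - transient``;
    repeated per gKs value because the slow potassium current adds an outward
    load that must be compensated. Raises CalibrationError if no bracketing
    interval exists below ``max_current``.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    lo, hi = 0.0, 1.0
    step = 1.0
    while _rate_at(p, lo, duration_ms, transient_ms, dt) > target_rate:
        lo -= step
        step *= 2.0
        if lo < -max_current:
            raise CalibrationError(
                f"cell above {target_rate} Hz even at {lo} uA/cm^2 "
                f"(gKs={p.gKs_max})"
            )
    while _rate_at(p, hi, duration_ms, transient_ms, dt) < target_rate:
        hi *= 2.0
        if hi > max_current:
            raise CalibrationError(
                f"no bracketing current below {max_current} uA/cm^2 "
                f"for gKs={p.gKs_max}"
            )
    # converge well inside the stated tolerance so count-based checks agree
    inner_tol = min(0.02, tol_hz / 4.0)
    best = hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = _rate_at(p, mid, duration_ms, transient_ms, dt)
        if abs(r - target_rate) <= inner_tol:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
            best = mid
        if hi - lo < 1e-9:
            break
    r = _rate_at(p, best, duration_ms, transient_ms, dt)
    if abs(r - target_rate) > tol_hz:
        raise CalibrationError(
            f"calibration failed to reach {target_rate}+/-{tol_hz} Hz "
            f"for gKs={p.gKs_max} (got {r:.3f} Hz)"
        )
    return best


def compute_fi_curve(
    p: NeuronParams,
    currents,
    duration_ms: float = 5000.0,
    transient_ms: float = 1000.0,
    dt: float = 0.05,
) -> list[tuple[float, float]]:
    """Firing rate versus constant current offset (added to I_tune).

    All currents are integrated as one batch of unconnected cells; the rate
    is measured after the transient.
    """
    currents = np.asarray(list(currents), dtype=float)
    if np.any(np.diff(currents) < 0):
        raise ValueError("currents must be sorted ascending")
    res = run_ensemble(
        p, n_cells=currents.size, duration_ms=duration_ms, dt=dt,
        I_extra=currents,
    )
    out = []
    for i, cur in enumerate(currents):
        out.append((float(cur), firing_rate(res.spikes_of(i), transient_ms, duration_ms)))
    return out


def step_response_isis(
    p: NeuronParams,
    n_isi: int = 5,
    I_extra: float = 2.0,
    duration_ms: float = 3000.0,
    dt: float = 0.05,
) -> np.ndarray:
    """First inter-spike intervals under a constant current step from rest.

    The step is ``I_tune + I_extra``; the default extra drive pushes the
    cell into upstate-like firing, where spike-frequency adaptation shows up
    as a lengthening ISI sequence (and the slow-K gate s climbs to its
    maximum at the end of the burst)."""
    res = run_ensemble(p, n_cells=1, duration_ms=duration_ms, dt=dt, I_extra=I_extra)
    t = res.spike_times
    if t.size < n_isi + 1:
        raise RuntimeError(
            f"only {t.size} spikes in {duration_ms} ms; need {n_isi + 1}"
        )
    return np.diff(t[: n_isi + 1])


def compute_prc(
    p: NeuronParams,
    n_phases: int = 32,
    pulse_amplitude: float | None = None,
    pulse_width_ms: float = 0.5,
    dt: float = 0.05,
    type2_delta: float = 0.02,
) -> PRCResult:
    """Phase response curve of the periodically firing calibrated neuron.

    A square current pulse is delivered at each phase of a uniform grid; the
    shift is ``(T - T_perturbed)/T`` measured on the perturbed cycle only
    (positive = advance). If no amplitude is given it is auto-scaled so the
    largest |shift| lies in [1%, 10%] of a period. Classified type 2 iff the
    most negative shift is below ``-type2_delta * max|shift|``.
    """
    # --- baseline periodic firing -------------------------------------------------
    base_dur = 5000.0
    base = run_ensemble(p, n_cells=1, duration_ms=base_dur, dt=dt)
    t = base.spike_times
    late = t[t > 1500.0]
    if late.size < 8:
        raise RuntimeError("baseline firing too sparse for a PRC")
    isis = np.diff(late)
    cv = isis.std() / isis.mean()
    if cv > 0.01:
        raise RuntimeError(f"baseline not periodic (ISI CV={cv:.3%} > 1%)")
    T = float(isis[-5:].mean())
    anchors = t[t > 3000.0]
    if anchors.size == 0 or anchors[0] + 2.5 * T > base_dur:
        raise RuntimeError("baseline run too short to anchor the PRC cycle")
    ta = float(anchors[0])

    phases = (np.arange(n_phases) + 0.5) / n_phases
    duration = ta + 2.5 * T

    def shifts_for(amp: float) -> np.ndarray:
        res = run_ensemble(
            p, n_cells=n_phases, duration_ms=duration, dt=dt,
            I_extra=amp,
            stim_on=ta + phases * T,
            stim_off=ta + phases * T + pulse_width_ms,
        )
        out = np.empty(n_phases)
        for i in range(n_phases):
            st = res.spikes_of(i)
            nxt = st[st > ta + 1e-9]
            if nxt.size == 0:
                raise RuntimeError(f"perturbed cell {i} fired no spike after anchor")
            out[i] = (T - (nxt[0] - ta)) / T
        return out

    if pulse_amplitude is not None:
        amp = float(pulse_amplitude)
        shifts = shifts_for(amp) if amp != 0.0 else np.zeros(n_phases)
    else:
        amp = 0.5
        for _ in range(6):
            shifts = shifts_for(amp)
            mx = np.abs(shifts).max()
            if 0.01 <= mx <= 0.10:
                break
            if mx < 1e-7:
                amp *= 10.0
            else:
                amp *= 0.05 / mx
        else:
            raise RuntimeError("could not auto-scale the PRC pulse amplitude")

    mx = float(np.abs(shifts).max())
    if mx > 0 and float(shifts.min()) < -type2_delta * mx:
        prc_type = 2
    else:
        prc_type = 1
    samples = tuple(
        PRCSample(phase=float(ph), shift=float(sh)) for ph, sh in zip(phases, shifts)
    )
    return PRCResult(samples=samples, period_ms=T, pulse_amplitude=amp, prc_type=prc_type)
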