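"""Full-network simulation: membrane equation + conductance synapses.

All cells advance synchronously with RK4 at a fixed step (0.05 ms in all
standard runs). The synaptic drive onto cell i is

    I_syn_i = sum_j A_ij w_{j->i} kappa(t - t_j) (V_i - E_syn(species_j)),

where ``kappa`` is the delayed double-exponential kernel normalized to unit
peak and ``t_j`` is the time of the *last* spike of presynaptic cell j (a new
spike resets the kernel; spike history is not summed). Initial voltages are
drawn uniformly from [-70, -50] mV per cell (seeded) to break the lattice
symmetry, with gates at their steady state for the initial voltage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import NO_SPIKE, pack_neuron_params, pack_synapse_params
from .network import EXC, INH, HeterogeneitySpec, Network
from .neuron import SPIKE_LOCKOUT_MS, SPIKE_THRESHOLD_MV, gate_steady_state
from .params import NeuronParams, SynapseParams

__all__ = [
    "SimConfig",
    "SpikeRecord",
    "synaptic_kernel",
    "synaptic_current",
    "run_simulation",
]


def synaptic_kernel(t_since_spike, sp: SynapseParams):
    """Unit-peak synaptic conductance kernel (dimensionless).

    Zero before the delay tau_D, then
    ``K (exp(-(t - tau_D)/tau_S) - exp(-(t - tau_D)/tau_F))``; the
    normalization K puts the peak at exactly 1.
    """
    t = np.asarray(t_since_spike, dtype=float)
    td = t - sp.tau_D
    out = np.where(
        td > 0,
        sp.K * (np.exp(-np.clip(td, 0, None) / sp.tau_S)
                - np.exp(-np.clip(td, 0, None) / sp.tau_F)),
        0.0,
    )
    return out if out.ndim else float(out)


def synaptic_current(
    i: int,
    V_i: float,
    t: float,
    last_spikes: np.ndarray,
    net: Network,
    sp: SynapseParams,
) -> float:
    """Reference (slow) evaluation of the synaptic current onto cell i.

    ``last_spikes[j]`` holds the most recent spike time of cell j, or NaN for
    cells that have never spiked. Only that last spike contributes.
    """
    total = 0.0
    onto_i = net.post == i
    for pre_j, w in zip(net.pre[onto_i], net.weight[onto_i]):
        tj = last_spikes[pre_j]
        if not np.isfinite(tj):
            continue
        k = synaptic_kernel(t - tj, sp)
        if k == 0.0:
            continue
        e_rev = sp.E_exc if net.species[pre_j] == EXC else sp.E_inh
        total += w * k * (V_i - e_rev)
    return total


@dataclass(frozen=True)
class SimConfig:
    """Run configuration; ``duration_ms / dt`` must be integral.

    ``init`` selects the seeded initial condition: ``"uniform"`` (default)
    draws voltages from [-70, -50] mV with gates at steady state, producing
    a staggered initial volley from which one pattern wins;
    ``"limit_cycle"`` places each cell at a uniformly random phase of its
    intrinsic firing cycle (a smooth asynchronous start).
    """

    duration_ms: float = 5000.0
    dt: float = 0.05
    seed: int = 0
    init: str = "uniform"
    record_voltages: tuple[int, ...] = ()
    rec_stride: int = 4

    def __post_init__(self) -> None:
        nsteps = self.duration_ms / self.dt
        if abs(nsteps - round(nsteps)) > 1e-9:
            raise ValueError("duration_ms must be an integer multiple of dt")

    def fingerprint(self, extra: dict | None = None) -> str:
        d = {
            "duration_ms": self.duration_ms,
            "dt": self.dt,
            "seed": self.seed,
            **(extra or {}),
        }
        return hashlib.md5(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SpikeRecord:
    """(cell, time) spike events plus the geometry needed for analysis.

    The universal input of the measurement module; synthetic fixtures and
    simulations both produce this type.
    """

    cell_ids: np.ndarray  # (n_events,)
    times: np.ndarray  # ms, globally nondecreasing
    positions: np.ndarray  # (n_cells, 2)
    species: np.ndarray  # (n_cells,)
    L: float
    duration_ms: float
    meta: dict = field(default_factory=dict)
    V_trace: np.ndarray | None = None
    trace_times: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_spikes(self) -> int:
        return self.cell_ids.size

    def spikes_of(self, i: int) -> np.ndarray:
        return self.times[self.cell_ids == i]

    def exc_only(self) -> "SpikeRecord":
        """Restrict events to excitatory cells (geometry kept intact)."""
        keep = self.species[self.cell_ids] == EXC
        return SpikeRecord(
            cell_ids=self.cell_ids[keep], times=self.times[keep],
            positions=self.positions, species=self.species,
            L=self.L, duration_ms=self.duration_ms, meta=dict(self.meta),
        )

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        keep = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(
            cell_ids=self.cell_ids[keep], times=self.times[keep],
            positions=self.positions, species=self.species,
            L=self.L, duration_ms=self.duration_ms, meta=dict(self.meta),
        )

    def sort_coordinate(self) -> np.ndarray:
        """Raster-sorting coordinate S = y + x/L per cell."""
        return self.positions[:, 1] + self.positions[:, 0] / self.L

    def to_tsv(self, path: str | Path) -> None:
        s = self.sort_coordinate()
        sp = np.where(self.species == EXC, "excitatory", "inhibitory")
        df = pd.DataFrame({
            "cell_id": self.cell_ids,
            "t_ms": self.times,
            "x": self.positions[self.cell_ids, 0],
            "y": self.positions[self.cell_ids, 1],
            "species": sp[self.cell_ids],
            "S_coord": s[self.cell_ids],
        })
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as f:
            f.write(f"# L={self.L} duration_ms={self.duration_ms} "
                    f"n_cells={self.n_cells}\n")
            df.to_csv(f, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, positions=None, species=None) -> "SpikeRecord":
        """Read a spike table written by :meth:`to_tsv`.

        Cell geometry is reconstructed from the per-event columns; cells that
        never spiked are unknown to the table, so for full fidelity pass the
        original ``positions``/``species`` arrays.
        """
        with open(path) as f:
            header = f.readline().strip()
            df = pd.read_csv(f, sep="\t")
        kv = dict(item.split("=") for item in header.lstrip("# ").split())
        L = float(kv["L"])
        duration = float(kv["duration_ms"])
        n_cells = int(kv["n_cells"])
        if positions is None:
            positions = np.zeros((n_cells, 2))
            species_arr = np.zeros(n_cells, dtype=np.int64)
            cid = df["cell_id"].to_numpy()
            positions[cid, 0] = df["x"]
            positions[cid, 1] = df["y"]
            species_arr[cid] = np.where(df["species"] == "excitatory", EXC, INH)
        else:
            species_arr = species
        return cls(
            cell_ids=df["cell_id"].to_numpy(dtype=np.int64),
            times=df["t_ms"].to_numpy(dtype=float),
            positions=positions,
            species=species_arr,
            L=L,
            duration_ms=duration,
        )


def limit_cycle_states(
    p: NeuronParams,
    n_cells: int,
    rng: np.random.Generator,
    dt: float = 0.05,
    settle_ms: float = 3000.0,
):
    """States of ``n_cells`` copies of the calibrated neuron at uniformly
    random phases of its intrinsic firing limit cycle.

    One cell is integrated until its oscillation settles, then traced over
    one period; each network cell is assigned the state at a random sample
    of that trace. Falls back to the settled fixed point if the isolated
    cell does not oscillate (then phase is meaningless).
    """
    from .neuron import NeuronState, rk4_step, run_ensemble  # avoid a cycle

    res = run_ensemble(p, n_cells=1, duration_ms=settle_ms, dt=dt)
    t = res.spike_times
    if t.size < 3:
        return (
            np.repeat(res.final_V, n_cells),
            np.repeat(res.final_h, n_cells),
            np.repeat(res.final_n, n_cells),
            np.repeat(res.final_s, n_cells),
        )
    period = float(np.diff(t[-3:]).mean())
    n_steps = max(1, int(round(period / dt)))
    # trace one full period from the settled state, storing the full state
    # at every step (the phase origin is irrelevant for uniform sampling)
    y = NeuronState(
        V=float(res.final_V[0]), h=float(res.final_h[0]),
        n=float(res.final_n[0]), s=float(res.final_s[0]),
    )
    trace = np.empty((n_steps, 4))
    for k in range(n_steps):
        trace[k] = (y.V, y.h, y.n, y.s)
        y = rk4_step(y, p, lambda _t: 0.0, dt)
    idx = rng.integers(0, n_steps, size=n_cells)
    states = trace[idx]
    return (
        states[:, 0].copy(), states[:, 1].copy(),
        states[:, 2].copy(), states[:, 3].copy(),
    )


def _build_csr(net: Network, w_ie_fast: float | None):
    """CSR of out-edges grouped by presynaptic cell; if ``w_ie_fast`` is set,
    inhibitory edges are left out (handled analytically by the kernel)."""
    if w_ie_fast is not None:
        # drop only the dense uniform I->E block; I->I edges stay explicit
        keep = ~(
            (net.species[net.pre] == INH) & (net.species[net.post] == EXC)
        )
    else:
        keep = np.ones(net.pre.size, dtype=bool)
    pre = net.pre[keep]
    post = net.post[keep]
    w = net.weight[keep]
    order = np.argsort(pre, kind="stable")
    pre, post, w = pre[order], post[order], w[order]
    indptr = np.zeros(net.n_cells + 1, dtype=np.int64)
    np.add.at(indptr[1:], pre, 1)
    indptr = np.cumsum(indptr)
    return indptr.astype(np.int64), post.astype(np.int64), w.astype(np.float64)


def run_simulation(
    net: Network,
    p: NeuronParams,
    sp: SynapseParams,
    cfg: SimConfig = SimConfig(),
    initial_state: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
    return_state: bool = False,
):
    """Integrate the whole network and return its spike record.

    ``p.I_tune`` must already be calibrated for ``p.gKs_max``. If the network
    carries a heterogeneity, its member cells receive the seeding current
    during the initial stimulus window. Deterministic given the seed. A
    silent network is a valid (quiescent) outcome, not an error.
    """
    nc = net.n_cells
    rng = np.random.default_rng(cfg.seed)
    if initial_state is not None:
        V, h, n, s = (np.array(a, dtype=float) for a in initial_state)
    elif cfg.init == "limit_cycle":
        V, h, n, s = limit_cycle_states(p, nc, rng, dt=cfg.dt)
    elif cfg.init == "uniform":
        V = rng.uniform(-70.0, -50.0, size=nc)
        h = np.array([gate_steady_state(v, p.h) for v in V])
        n = np.array([gate_steady_state(v, p.n) for v in V])
        s = np.array([gate_steady_state(v, p.s) for v in V])
    else:
        raise ValueError(f"unknown init mode {cfg.init!r}")

    w_ie_fast = net.uniform_inhibitory_weight()
    indptr, indices, weights = _build_csr(net, w_ie_fast)
    # weights are in uS/cm^2; the membrane works in mS/cm^2
    weights = weights * 1e-3
    w_ie_kernel = (w_ie_fast * 1e-3) if w_ie_fast is not None else -1.0

    if sp.tau_D < cfg.dt:
        raise ValueError(
            "synaptic delay shorter than the time step breaks the frozen "
            "last-spike-table scheme"
        )

    stim_amp = np.zeros(nc)
    stim_on = np.zeros(nc)
    stim_off = np.zeros(nc)
    if net.heterogeneity is not None and net.het_cells.size:
        stim_amp[net.het_cells] = net.heterogeneity.stim_current
        stim_off[net.het_cells] = net.heterogeneity.stim_duration

    nsteps = int(round(cfg.duration_ms / cfg.dt))
    last_spike = np.full(nc, NO_SPIKE)
    last_detect = np.full(nc, NO_SPIKE)
    cap = int(nc * (cfg.duration_ms / SPIKE_LOCKOUT_MS + 2))
    spike_cells = np.zeros(cap, dtype=np.int64)
    spike_times = np.zeros(cap, dtype=np.float64)

    if cfg.record_voltages:
        record_idx = np.asarray(cfg.record_voltages, dtype=np.int64)
        n_samples = nsteps // cfg.rec_stride + 1
        V_rec = np.zeros((n_samples, record_idx.size))
    else:
        record_idx = np.zeros(0, dtype=np.int64)
        V_rec = np.zeros((1, 0))

    nsp, bad_cell, bad_time = _kernels.integrate(
        V, h, n, s, (net.species == INH),
        pack_neuron_params(p), pack_synapse_params(sp),
        indptr, indices, weights, w_ie_kernel,
        stim_amp, stim_on, stim_off,
        float(cfg.dt), nsteps, 0.0,
        SPIKE_THRESHOLD_MV, SPIKE_LOCKOUT_MS,
        last_spike, last_detect,
        spike_cells, spike_times,
        record_idx, cfg.rec_stride, V_rec,
    )
    if bad_cell == -2:
        raise RuntimeError(f"spike buffer overflow at t={bad_time:.2f} ms")
    if bad_cell >= 0:
        raise FloatingPointError(
            f"non-finite state in cell {bad_cell} at t={bad_time:.3f} ms"
        )

    meta = {
        "seed": cfg.seed,
        "gKs_max": p.gKs_max,
        "I_tune": p.I_tune,
        "fingerprint": cfg.fingerprint({"gKs": p.gKs_max}),
    }
    if net.heterogeneity is not None:
        meta["het_multiplier"] = net.heterogeneity.multiplier
    record = SpikeRecord(
        cell_ids=spike_cells[:nsp].copy(),
        times=spike_times[:nsp].copy(),
        positions=net.positions,
        species=net.species,
        L=net.spec.L,
        duration_ms=cfg.duration_ms,
        meta=meta,
        V_trace=V_rec if cfg.record_voltages else None,
        trace_times=(np.arange(V_rec.shape[0]) * cfg.dt * cfg.rec_stride
                     if cfg.record_voltages else None),
    )
    if return_state:
        return record, (V, h, n, s)
    return record
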