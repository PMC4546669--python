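"""Computational experiments: phase scans over (gKs, w_ie), heterogeneity
sensitivity scans, and deterministic synthetic spike fixtures for testing
the measurement code without ODE integration.

Scans reuse one I_tune calibration per gKs value. A reduced lattice
(L = 10, 100 excitatory / 16 inhibitory cells, 2 s runs) is provided for
fast qualitative checks; its global inhibitory weight is scaled by the
inhibitory-cell-count ratio so each excitatory cell receives the same total
inhibitory conductance as at full scale, and the heterogeneous region side
is scaled to preserve its area fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .measures import (
    bursting_measure,
    classify_regime,
    detect_upstates,
    phi_preference,
    upstate_statistics,
    wave_speed,
)
from .network import EXC, HeterogeneitySpec, LatticeSpec, apply_heterogeneity, build_network
from .neuron import calibrate_itune
from .params import NeuronParams, SynapseParams, load_neuron_params, load_synapse_params
from .simulate import SimConfig, SpikeRecord, run_simulation

__all__ = [
    "ScanConfig",
    "full_spec",
    "reduced_spec",
    "scaled_wie",
    "scaled_heterogeneity",
    "CalibrationTable",
    "run_phase_scan",
    "run_heterogeneity_scan",
    "make_fixture",
]


def full_spec() -> LatticeSpec:
    """The standard geometry: L = 25, 625 excitatory / 121 inhibitory cells."""
    return LatticeSpec(L=25.0, n_exc=625, n_inh=121)


def reduced_spec() -> LatticeSpec:
    """Small lattice for fast tests: L = 10, 100 excitatory / 16 inhibitory."""
    return LatticeSpec(L=10.0, n_exc=100, n_inh=16)


#: Inhibitory-weight multiplier of the reduced lattice. With only 16
#: interneurons the bump recruits proportionally more of them and their
#: shot noise is larger, so preserving total inhibitory conductance
#: (factor 121/16 ~ 7.6) over-inhibits; this factor is calibrated once so
#: the reduced lattice reproduces the full-scale regime ordering
#: (localized bump at gKs=0, traveling bump at gKs=1) at w_ie=20-equivalent.
REDUCED_INHIBITORY_SCALE = 5.0


def scaled_wie(wie: float, spec: LatticeSpec) -> float:
    """Inhibitory weight equivalent to full-scale ``wie`` on ``spec``.

    Applied to both the I->E and I->I weights of reduced-lattice runs.
    """
    if spec.n_inh == full_spec().n_inh:
        return wie
    return wie * REDUCED_INHIBITORY_SCALE


def scaled_heterogeneity(het: HeterogeneitySpec, spec: LatticeSpec) -> HeterogeneitySpec:
    """Rescale the heterogeneous region to preserve its area fraction."""
    full = full_spec()
    if spec.L == full.L:
        return het
    side = max(2.0, round(het.side * spec.L / full.L))
    origin = (
        round(het.origin[0] * spec.L / full.L),
        round(het.origin[1] * spec.L / full.L),
    )
    return replace(het, side=side, origin=origin)


class CalibrationTable:
    """Caches I_tune per gKs value for a fixed base parameter set."""

    def __init__(self, base: NeuronParams | None = None, target_rate: float = 10.0):
        self.base = base if base is not None else load_neuron_params()
        self.target_rate = target_rate
        self._cache: dict[float, float] = {}

    def params_for(self, gks: float) -> NeuronParams:
        key = round(float(gks), 9)
        if key not in self._cache:
            self._cache[key] = calibrate_itune(
                self.base.with_gks(key), target_rate=self.target_rate
            )
        return self.base.with_gks(key, I_tune=self._cache[key])

    def itune(self, gks: float) -> float:
        return self.params_for(gks).I_tune


@dataclass(frozen=True)
class ScanConfig:
    """Grid specification for phase/heterogeneity scans.

    ``wie_grid`` is always expressed in full-scale units; the reduced lattice
    rescales internally. Seeds are derived as ``seed_base + replicate``.
    """

    gks_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    wie_grid: tuple[float, ...] = (20.0,)
    replicates: int = 3
    seed_base: int = 0
    duration_ms: float | None = None  # default: 5000 full / 2000 reduced
    dt: float = 0.05
    reduced: bool = False
    heterogeneity: HeterogeneitySpec | None = None

    def __post_init__(self) -> None:
        if not self.gks_grid or not self.wie_grid:
            raise ValueError("scan grids must be nonempty")

    @property
    def spec(self) -> LatticeSpec:
        return reduced_spec() if self.reduced else full_spec()

    @property
    def run_duration(self) -> float:
        if self.duration_ms is not None:
            return self.duration_ms
        return 3000.0 if self.reduced else 5000.0

    @property
    def seeds(self) -> tuple[int, ...]:
        return tuple(self.seed_base + r for r in range(self.replicates))


def _single_run(
    sc: ScanConfig,
    calib: CalibrationTable,
    sp: SynapseParams,
    gks: float,
    wie: float,
    seed: int,
    het: HeterogeneitySpec | None,
) -> dict:
    spec = sc.spec
    w_eq = scaled_wie(wie, spec)
    w_ii = scaled_wie(20.0, spec)
    net = build_network(spec, w_ie=w_eq, w_ii=w_ii)
    region = None
    if het is not None:
        het_here = scaled_heterogeneity(het, spec)
        net = apply_heterogeneity(net, het_here)
        region = net.het_cells
    p = calib.params_for(gks)
    cfg = SimConfig(duration_ms=sc.run_duration, dt=sc.dt, seed=seed)
    rec = run_simulation(net, p, sp, cfg)

    row: dict = {"gks": gks, "wie": wie, "seed": seed, "n_spikes": rec.n_spikes}
    regime = classify_regime(rec, transient_ms=min(1000.0, sc.run_duration / 5.0))
    row["regime"] = regime.label
    row["B"] = bursting_measure(rec.exc_only())
    track = wave_speed(rec, avg_window_ms=sc.run_duration / 2.0)
    row["mean_speed"] = track.mean_speed
    row["speed_valid"] = track.valid
    for k, v in track.exclusions.items():
        row[f"excl_{k}"] = v
    ups = detect_upstates(rec)
    stats = upstate_statistics(ups)
    row["mean_spikes_per_upstate"] = stats["mean_spikes"]
    row["n_upstates"] = stats["n_upstates"]
    if region is not None:
        row["het_multiplier"] = net.heterogeneity.multiplier
        row["phi"] = phi_preference(rec, region)
        # upstate duration inside vs outside the heterogeneity
        durs_in, durs_out = [], []
        for i, cell_ups in ups.cells.items():
            if rec.species[i] != EXC:
                continue
            target = durs_in if i in set(region.tolist()) else durs_out
            target.extend(u.end - u.start for u in cell_ups)
        row["mean_upstate_ms_in"] = float(np.mean(durs_in)) if durs_in else float("nan")
        row["mean_upstate_ms_out"] = float(np.mean(durs_out)) if durs_out else float("nan")
    return row


def run_phase_scan(
    sc: ScanConfig,
    calib: CalibrationTable | None = None,
    sp: SynapseParams | None = None,
) -> pd.DataFrame:
    """Scan the (gKs, w_ie) grid; one row per (grid point, replicate).

    Individual run failures are recorded in an ``error`` column and the scan
    continues. Quiescent or synchronized points carry speed-exclusion flags
    rather than speeds (the 'empty squares' of the regime map).
    """
    calib = calib or CalibrationTable()
    sp = sp or load_synapse_params()
    rows = []
    for gks in sc.gks_grid:
        for wie in sc.wie_grid:
            for seed in sc.seeds:
                try:
                    rows.append(
                        _single_run(sc, calib, sp, gks, wie, seed, sc.heterogeneity)
                    )
                except Exception as exc:  # noqa: BLE001 - scans must survive runs
                    rows.append({
                        "gks": gks, "wie": wie, "seed": seed, "error": repr(exc),
                    })
    return pd.DataFrame(rows)


def run_heterogeneity_scan(
    sc: ScanConfig,
    multipliers,
    calib: CalibrationTable | None = None,
    sp: SynapseParams | None = None,
) -> pd.DataFrame:
    """phi (and upstate-length contrast) per (gKs, multiplier, replicate)."""
    base_het = sc.heterogeneity or HeterogeneitySpec()
    calib = calib or CalibrationTable()
    sp = sp or load_synapse_params()
    rows = []
    for gks in sc.gks_grid:
        for mult in multipliers:
            het = replace(base_het, multiplier=float(mult))
            for wie in sc.wie_grid:
                for seed in sc.seeds:
                    try:
                        rows.append(
                            _single_run(sc, calib, sp, gks, wie, seed, het)
                        )
                    except Exception as exc:  # noqa: BLE001
                        rows.append({
                            "gks": gks, "wie": wie, "seed": seed,
                            "het_multiplier": mult, "error": repr(exc),
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def _fixture_geometry(n_cells: int, L: float):
    side = round(math.sqrt(n_cells))
    if side * side != n_cells:
        raise ValueError("fixture n_cells must be a perfect square")
    idx = np.arange(side)
    xx, yy = np.meshgrid(idx, idx, indexing="ij")
    pos = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float) * (L / side)
    species = np.zeros(n_cells, dtype=np.int64)
    return pos, species


def make_fixture(
    kind: str,
    n_cells: int = 625,
    L: float = 25.0,
    duration_ms: float = 5000.0,
    speed: float = 0.05,  # lattice units per ms (traveling/planar)
    radius: float = 2.5,  # bump radius, lattice units
    period_ms: float = 10.0,  # within-bump firing period
    burst_period_ms: float = 100.0,  # synchronous fixture
    rate_hz: float = 10.0,  # asynchronous fixture
    seed: int = 0,
) -> SpikeRecord:
    """Deterministic synthetic spike records with known spatiotemporal
    structure, for unit-testing the measures without any ODE integration.

    Kinds: ``quiescent`` (empty), ``synchronous`` (coincident population
    bursts spanning complete periods, closed by the onset spike of the
    following burst so every period contributes the same pooled-ISI pattern,
    which makes the closed-form bursting measure exact), ``asynchronous``
    (independent Poisson trains), ``stationary`` (a fixed bump),
    ``traveling`` (a bump whose center moves at ``speed`` along x, wrapping),
    and ``planar`` (a full-height stripe moving along x).
    """
    pos, species = _fixture_geometry(n_cells, L)
    rng = np.random.default_rng(seed)
    cells: list[int] = []
    times: list[float] = []

    if kind == "quiescent":
        pass
    elif kind == "synchronous":
        n_bursts = int(duration_ms // burst_period_ms) - 1
        for k in range(1, n_bursts + 1):
            t = k * burst_period_ms
            cells.extend(range(n_cells))
            times.extend([t] * n_cells)
        # closing onset spike of the next burst (complete-period construction)
        cells.append(0)
        times.append((n_bursts + 1) * burst_period_ms)
    elif kind == "asynchronous":
        for i in range(n_cells):
            n_sp = rng.poisson(rate_hz * duration_ms / 1000.0)
            for t in np.sort(rng.uniform(0, duration_ms, size=n_sp)):
                cells.append(i)
                times.append(float(t))
    elif kind in ("stationary", "traveling"):
        v = 0.0 if kind == "stationary" else speed
        c0 = np.array([L / 4.0, L / 2.0])
        offsets = rng.uniform(0, period_ms, size=n_cells)
        for i in range(n_cells):
            t = offsets[i]
            while t < duration_ms:
                cx = (c0[0] + v * t) % L
                d = pos[i] - np.array([cx, c0[1]])
                d = np.abs(d)
                d = np.minimum(d, L - d)
                if math.hypot(d[0], d[1]) <= radius:
                    cells.append(i)
                    times.append(float(t))
                t += period_ms
    elif kind == "planar":
        half_width = radius
        offsets = rng.uniform(0, period_ms, size=n_cells)
        for i in range(n_cells):
            t = offsets[i]
            while t < duration_ms:
                cx = (L / 4.0 + speed * t) % L
                dx = abs(pos[i, 0] - cx)
                dx = min(dx, L - dx)
                if dx <= half_width:
                    cells.append(i)
                    times.append(float(t))
                t += period_ms
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    cells_arr = np.array(cells, dtype=np.int64)
    times_arr = np.array(times, dtype=float)
    order = np.argsort(times_arr, kind="stable")
    return SpikeRecord(
        cell_ids=cells_arr[order],
        times=times_arr[order],
        positions=pos,
        species=species,
        L=L,
        duration_ms=duration_ms,
        meta={"fixture": kind, "seed": seed},
    )
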