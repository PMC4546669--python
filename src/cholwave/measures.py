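"""Analysis statistics for network spike records.

Implements the population-level measurements of the model: the pooled-ISI bursting
measure B (synchrony), upstate detection and statistics, pairwise ISI-phase
distributions within upstates, the toroidal center of activity and wave
speed (with its exclusion rules), the heterogeneity-preference index phi,
and a regime classifier over the eight observed dynamical classes.

Undefined quantities (too few spikes, no activity) are reported as NaN
sentinels rather than raised, because quiescence is a valid network outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import EXC, connection_radius, periodic_distance
from .simulate import SpikeRecord

__all__ = [
    "Upstate",
    "UpstateSet",
    "WaveTrack",
    "RegimeLabel",
    "REGIME_LABELS",
    "bursting_measure",
    "detect_upstates",
    "upstate_statistics",
    "isi_phase_distribution",
    "center_of_activity",
    "wave_speed",
    "phi_preference",
    "classify_regime",
]

SYNCHRONY_THRESHOLD = 0.7  # B above this marks a synchronized network

REGIME_LABELS = (
    "quiescent",
    "mixed",
    "stationary_bump",
    "traveling_bump",
    "global_high_frequency",
    "multiple_bumps",
    "planar_wave",
    "global_burst",
)


# ---------------------------------------------------------------------------
# bursting measure
# ---------------------------------------------------------------------------

def bursting_measure(
    spikes: SpikeRecord,
    times: np.ndarray | None = None,
    cell_ids: np.ndarray | None = None,
) -> float:
    """Pooled-ISI bursting measure B = (CV - 1)/sqrt(N).

    All spike times are merged regardless of cell identity; CV is the
    coefficient of variation of the successive differences of the merged
    train, and N is the number of distinct cells that fired. B approaches
    ``sqrt(1 - 1/N) - 1/sqrt(N)`` (-> 1 for large N) at perfect synchrony
    and ~0 for Poisson-like asynchrony. NaN for fewer than 3 spikes.

    ``times``/``cell_ids`` may restrict the computation to a subset of the
    record's events (both must then be given consistently).
    """
    if times is None:
        times = spikes.times
        cell_ids = spikes.cell_ids
    elif cell_ids is None:
        cell_ids = spikes.cell_ids
    n_cells_active = np.unique(cell_ids).size
    if times.size < 3 or n_cells_active == 0:
        return float("nan")
    tau = np.diff(np.sort(times))
    mean = tau.mean()
    if mean <= 0:
        return float("nan")
    cv = tau.std() / mean
    return float((cv - 1.0) / math.sqrt(n_cells_active))


# ---------------------------------------------------------------------------
# upstates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Upstate:
    start: float  # ms, first spike
    end: float  # ms, last spike
    n_spikes: int


@dataclass
class UpstateSet:
    """Per-cell intervals of sustained firing."""

    cells: dict[int, list[Upstate]]
    gap_ms: float
    record: SpikeRecord = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_upstates(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def of(self, i: int) -> list[Upstate]:
        return self.cells.get(i, [])


def detect_upstates(
    spikes: SpikeRecord, gap_ms: float = 100.0, min_spikes: int = 2
) -> UpstateSet:
    """Group each cell's spikes into upstates by an ISI-gap rule.

    A maximal run of spikes whose consecutive ISIs all stay below ``gap_ms``
    forms one upstate; runs shorter than ``min_spikes`` (singletons by
    default) are discarded. The default gap separates within-upstate firing
    (ISIs of tens of ms) from the ~1 Hz down states between upstates.
    """
    cells: dict[int, list[Upstate]] = {}
    order = np.argsort(spikes.times, kind="stable")
    cid = spikes.cell_ids[order]
    t = spikes.times[order]
    for i in np.unique(cid):
        ti = t[cid == i]
        if ti.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(ti) >= gap_ms)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [ti.size - 1]])
        ups = [
            Upstate(start=float(ti[a]), end=float(ti[b]), n_spikes=int(b - a + 1))
            for a, b in zip(starts, ends)
            if b - a + 1 >= min_spikes
        ]
        if ups:
            cells[int(i)] = ups
    return UpstateSet(cells=cells, gap_ms=gap_ms, record=spikes)


def upstate_statistics(ups: UpstateSet) -> dict:
    """Moments over all upstates of all excitatory cells.

    Returns mean/sd of spikes per upstate and mean/sd of within-upstate ISIs;
    NaNs if no upstates exist.
    """
    rec = ups.record
    counts: list[int] = []
    isis: list[np.ndarray] = []
    for i, cell_ups in ups.cells.items():
        if rec is not None and rec.species[i] != EXC:
            continue
        ti = rec.spikes_of(i) if rec is not None else None
        for u in cell_ups:
            counts.append(u.n_spikes)
            if ti is not None:
                inside = ti[(ti >= u.start) & (ti <= u.end)]
                if inside.size > 1:
                    isis.append(np.diff(inside))
    if not counts:
        nan = float("nan")
        return {"mean_spikes": nan, "sd_spikes": nan,
                "mean_isi": nan, "sd_isi": nan, "n_upstates": 0}
    counts_arr = np.array(counts, dtype=float)
    isi_arr = np.concatenate(isis) if isis else np.array([])
    return {
        "mean_spikes": float(counts_arr.mean()),
        "sd_spikes": float(counts_arr.std()),
        "mean_isi": float(isi_arr.mean()) if isi_arr.size else float("nan"),
        "sd_isi": float(isi_arr.std()) if isi_arr.size else float("nan"),
        "n_upstates": len(counts),
    }


# ---------------------------------------------------------------------------
# ISI-phase distribution
# ---------------------------------------------------------------------------

def isi_phase_distribution(
    spikes: SpikeRecord,
    ups: UpstateSet | None = None,
    n_bins: int = 36,
    max_pairs: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pairwise nearest-spike phases within overlapping upstates.

    For each pair of cells whose upstates overlap in time, every spike of one
    cell inside the overlap is matched to the nearest spike of the other;
    the signed difference, normalized by the mean of the two cells' mean
    within-upstate periods, is mapped to a phase in [-pi, pi]. Synchronous
    upstates pile mass at 0 (and +/-2pi, aliased to 0); asynchronous ones are
    flat. Returns (counts, bin_edges); empty counts if nothing overlaps.
    """
    if ups is None:
        ups = detect_upstates(spikes)
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    cells = [i for i in ups.cells if spikes.species[i] == EXC]
    # mean within-upstate period per cell
    period: dict[int, float] = {}
    for i in cells:
        ti = spikes.spikes_of(i)
        isis = []
        for u in ups.of(i):
            inside = ti[(ti >= u.start) & (ti <= u.end)]
            if inside.size > 1:
                isis.append(np.diff(inside))
        if isis:
            period[i] = float(np.concatenate(isis).mean())
    cells = [i for i in cells if i in period]
    pairs = [(a, b) for ai, a in enumerate(cells) for b in cells[ai + 1:]]
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in idx]

    phases: list[float] = []
    for a, b in pairs:
        ta = spikes.spikes_of(a)
        tb = np.sort(spikes.spikes_of(b))
        if tb.size == 0:
            continue
        T = 0.5 * (period[a] + period[b])
        for ua in ups.of(a):
            for ub in ups.of(b):
                lo, hi = max(ua.start, ub.start), min(ua.end, ub.end)
                if hi <= lo:
                    continue
                sa = ta[(ta >= lo) & (ta <= hi)]
                if sa.size == 0:
                    continue
                pos = np.searchsorted(tb, sa)
                for t_spk, k in zip(sa, pos):
                    cands = []
                    if k > 0:
                        cands.append(tb[k - 1] - t_spk)
                    if k < tb.size:
                        cands.append(tb[k] - t_spk)
                    d = min(cands, key=abs)
                    ph = 2.0 * math.pi * d / T
                    ph = (ph + math.pi) % (2.0 * math.pi) - math.pi
                    phases.append(ph)
    counts, _ = np.histogram(phases, bins=edges)
    return counts, edges


# ---------------------------------------------------------------------------
# center of activity and wave speed
# ---------------------------------------------------------------------------

def center_of_activity(
    rates: np.ndarray,
    positions: np.ndarray,
    L: float,
    min_resultant: float = 1e-2,
) -> np.ndarray | None:
    """Rate-weighted center of mass on the torus via per-axis circular means.

    Each coordinate is mapped to an angle ``2 pi x / L``; the rate-weighted
    circular mean is mapped back to [0, L). Returns None when no cell is
    active or when activity is so uniform that the circular resultant of
    either axis is below ``min_resultant`` (no preferred location).
    """
    w = np.asarray(rates, dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    out = np.empty(2)
    for ax in range(2):
        theta = 2.0 * math.pi * positions[:, ax] / L
        c = float(np.sum(w * np.cos(theta))) / total
        s = float(np.sum(w * np.sin(theta))) / total
        if math.hypot(c, s) < min_resultant:
            return None
        ang = math.atan2(s, c) % (2.0 * math.pi)
        out[ax] = ang * L / (2.0 * math.pi)
    return out


@dataclass
class WaveTrack:
    """Binned center-of-activity trajectory and its mean speed."""

    bin_centers: np.ndarray  # ms
    centers: np.ndarray  # (n_bins, 2), NaN where undefined
    active_counts: np.ndarray  # excitatory cells active per bin
    speeds: np.ndarray  # units/ms between consecutive defined centers (NaN else)
    mean_speed: float  # units/ms over the averaging window
    exclusions: dict  # rule name -> bool
    bin_ms: float
    avg_window_ms: float

    @property
    def valid(self) -> bool:
        return not any(self.exclusions.values())


def _active_sets(exc: SpikeRecord, bin_ms: float):
    n_bins = int(math.ceil(exc.duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    bin_of = np.minimum((exc.times // bin_ms).astype(int), n_bins - 1)
    return n_bins, edges, bin_of


def _cluster_count(points: np.ndarray, L: float, radius: float, min_size: int) -> int:
    """Single-linkage cluster count under periodic distance; clusters below
    ``min_size`` are ignored."""
    m = points.shape[0]
    if m == 0:
        return 0
    unvisited = np.ones(m, dtype=bool)
    count = 0
    for seed_idx in range(m):
        if not unvisited[seed_idx]:
            continue
        stack = [seed_idx]
        unvisited[seed_idx] = False
        size = 0
        while stack:
            j = stack.pop()
            size += 1
            d = periodic_distance(points[j], points[unvisited], L)
            nbr = np.flatnonzero(unvisited)[d <= radius]
            for kk in nbr:
                unvisited[kk] = False
                stack.append(kk)
        if size >= min_size:
            count += 1
    return count


def wave_speed(
    spikes: SpikeRecord,
    bin_ms: float = 10.0,
    avg_window_ms: float = 2500.0,
    max_active: int = 300,
    bump_min_size: int = 10,
    bump_persistence: float = 0.5,
    linkage_radius: float | None = None,
    k_ee: float = 16.0,
) -> WaveTrack:
    """Center-of-activity speed of the excitatory population.

    The run is divided into ``bin_ms`` bins; per bin the toroidal center of
    the excitatory firing-rate distribution is computed, and the mean of the
    minimal-image displacement per bin over the final ``avg_window_ms`` gives
    the speed. Run-level exclusion flags (reported, never raised):

    - ``no_activity``: no excitatory cell active in the window;
    - ``too_many_active``: more than ``max_active`` cells active in any bin;
    - ``irregular_participation``: sd of per-bin active counts exceeds their
      mean (within the window);
    - ``multiple_bumps``: two or more persistent clusters of active cells;
    - ``synchronized``: bursting measure above 0.7.
    """
    exc = spikes.exc_only()
    n_bins, edges, bin_of = _active_sets(exc, bin_ms)
    bin_centers = edges[:-1] + bin_ms / 2.0
    n_exc = int((spikes.species == EXC).sum())
    if linkage_radius is None:
        linkage_radius = connection_radius(spikes.L, k_ee, max(n_exc, 1))

    centers = np.full((n_bins, 2), np.nan)
    active_counts = np.zeros(n_bins, dtype=int)
    cluster_counts = np.zeros(n_bins, dtype=int)
    window_start = max(0.0, exc.duration_ms - avg_window_ms)
    in_window = bin_centers >= window_start

    for b in range(n_bins):
        sel = bin_of == b
        if not sel.any():
            continue
        cid = exc.cell_ids[sel]
        uniq, counts = np.unique(cid, return_counts=True)
        active_counts[b] = uniq.size
        rates = counts / (bin_ms / 1000.0)
        pos = exc.positions[uniq]
        c = center_of_activity(rates, pos, exc.L)
        if c is not None:
            centers[b] = c
        if in_window[b]:
            cluster_counts[b] = _cluster_count(
                pos, exc.L, linkage_radius, bump_min_size
            )

    speeds = np.full(n_bins, np.nan)
    for b in range(1, n_bins):
        if np.isfinite(centers[b]).all() and np.isfinite(centers[b - 1]).all():
            speeds[b] = periodic_distance(centers[b], centers[b - 1], exc.L) / bin_ms

    win_speeds = speeds[in_window]
    mean_speed = float(np.nanmean(win_speeds)) if np.isfinite(win_speeds).any() else float("nan")

    win_counts = active_counts[in_window]
    active_bins = win_counts > 0
    b_val = bursting_measure(exc)
    window_bins = int(in_window.sum())
    exclusions = {
        "no_activity": int(win_counts.sum()) == 0,
        "too_many_active": bool((win_counts > max_active).any()),
        "irregular_participation": bool(
            active_bins.any() and win_counts.std() > win_counts.mean()
        ),
        "multiple_bumps": bool(
            window_bins > 0
            and (cluster_counts[in_window] >= 2).sum() >= bump_persistence * window_bins
        ),
        "synchronized": bool(np.isfinite(b_val) and b_val > SYNCHRONY_THRESHOLD),
    }
    return WaveTrack(
        bin_centers=bin_centers,
        centers=centers,
        active_counts=active_counts,
        speeds=speeds,
        mean_speed=mean_speed,
        exclusions=exclusions,
        bin_ms=bin_ms,
        avg_window_ms=avg_window_ms,
    )


# ---------------------------------------------------------------------------
# heterogeneity preference
# ---------------------------------------------------------------------------

def phi_preference(
    spikes: SpikeRecord,
    region_cells: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Normalized preference phi = (f_in - f_out)/(f_in + f_out).

    ``f_in``/``f_out`` are the mean firing rates of excitatory cells inside/
    outside the region over the window (default: the last half of the run).
    phi is 1 when all activity is inside, -1 when all is outside, NaN when
    the network is silent in the window.
    """
    if window is None:
        window = (spikes.duration_ms / 2.0, spikes.duration_ms)
    t0, t1 = window
    span_s = (t1 - t0) / 1000.0
    if span_s <= 0:
        raise ValueError("empty analysis window")
    exc_ids = np.flatnonzero(spikes.species == EXC)
    region = np.intersect1d(np.asarray(region_cells, dtype=np.int64), exc_ids)
    outside = np.setdiff1d(exc_ids, region)
    if region.size == 0 or outside.size == 0:
        raise ValueError("region must split excitatory cells into two groups")
    keep = (spikes.times >= t0) & (spikes.times < t1)
    cid = spikes.cell_ids[keep]
    counts = np.bincount(cid, minlength=spikes.n_cells)
    f_in = counts[region].mean() / span_s
    f_out = counts[outside].mean() / span_s
    if f_in + f_out == 0:
        return float("nan")
    return float((f_in - f_out) / (f_in + f_out))


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimeLabel:
    label: str
    diagnostics: dict

    def __post_init__(self) -> None:
        if self.label not in REGIME_LABELS:
            raise ValueError(f"unknown regime label {self.label!r}")


def _classify_window(
    spikes: SpikeRecord,
    window: tuple[float, float],
    *,
    displacement_threshold: float,
    planar_major: float,
    planar_minor: float,
    global_fraction: float,
    burst_participation: float,
    bin_ms: float,
) -> tuple[str, dict]:
    exc = spikes.exc_only()
    t0, t1 = window
    n_exc = int((spikes.species == EXC).sum())
    keep = (exc.times >= t0) & (exc.times < t1)
    times = exc.times[keep]
    cids = exc.cell_ids[keep]
    diag: dict = {"window": window}
    if times.size == 0:
        return "quiescent", diag

    participation = np.unique(cids).size / n_exc
    n_active_cells = np.unique(cids).size
    b_val = (bursting_measure(exc, times=times, cell_ids=cids)
             if times.size >= 3 and n_active_cells > 0 else float("nan"))
    diag["B"] = b_val
    diag["participation"] = participation

    n_bins = max(1, int(round((t1 - t0) / bin_ms)))
    bin_of = np.minimum(((times - t0) // bin_ms).astype(int), n_bins - 1)
    side = int(round(math.sqrt(n_exc)))
    grain = spikes.L / max(side, 1)
    r_link = connection_radius(spikes.L, 16.0, max(n_exc, 1))

    frac_global_bins = 0
    planar_bins = 0
    multi_bins = 0
    centers = np.full((n_bins, 2), np.nan)
    occupied_bins = 0
    for b in range(n_bins):
        sel = bin_of == b
        if not sel.any():
            continue
        occupied_bins += 1
        cid_b = cids[sel]
        uniq, counts = np.unique(cid_b, return_counts=True)
        pos = exc.positions[uniq]
        if uniq.size >= global_fraction * n_exc:
            frac_global_bins += 1
        nx = np.unique(np.round(pos[:, 0] / grain).astype(int)).size / side
        ny = np.unique(np.round(pos[:, 1] / grain).astype(int)).size / side
        if (nx >= planar_major and ny <= planar_minor) or (
            ny >= planar_major and nx <= planar_minor
        ):
            planar_bins += 1
        if _cluster_count(pos, spikes.L, r_link, 10) >= 2:
            multi_bins += 1
        c = center_of_activity(counts.astype(float), pos, spikes.L)
        if c is not None:
            centers[b] = c

    net_disp = np.zeros(2)
    for b in range(1, n_bins):
        if np.isfinite(centers[b]).all() and np.isfinite(centers[b - 1]).all():
            d = centers[b] - centers[b - 1]
            d = (d + spikes.L / 2.0) % spikes.L - spikes.L / 2.0
            net_disp += d
    diag["net_displacement"] = float(np.hypot(*net_disp))
    diag["bump_bins_multi"] = multi_bins
    diag["occupied_bins"] = occupied_bins

    if occupied_bins == 0:
        return "quiescent", diag
    if np.isfinite(b_val) and b_val > SYNCHRONY_THRESHOLD and (
        participation >= burst_participation
    ):
        return "global_burst", diag
    if frac_global_bins >= 0.8 * n_bins:
        return "global_high_frequency", diag
    if planar_bins >= 0.5 * occupied_bins:
        return "planar_wave", diag
    if multi_bins >= 0.5 * occupied_bins:
        return "multiple_bumps", diag
    if diag["net_displacement"] < displacement_threshold:
        return "stationary_bump", diag
    return "traveling_bump", diag


def classify_regime(
    spikes: SpikeRecord,
    transient_ms: float = 1000.0,
    displacement_threshold: float = 2.0,
    planar_major: float = 0.9,
    planar_minor: float = 0.4,
    global_fraction: float = 0.8,
    burst_participation: float = 0.5,
    bin_ms: float = 10.0,
) -> RegimeLabel:
    """Assign one of the eight dynamical regime labels to a spike record.

    A deterministic decision tree over diagnostics (bursting measure,
    per-bin participation, bump clustering, axis spans, and the net drift of
    the toroidal center of activity). If four equal sub-windows of the
    post-transient record classify differently, the run is labeled
    ``mixed``. Thresholds are heuristics chosen to separate the exemplar
    parameter points of the model; all are configurable.
    """
    t0, t1 = transient_ms, spikes.duration_ms
    if t1 <= t0:
        t0, t1 = 0.0, spikes.duration_ms
    kwargs = dict(
        displacement_threshold=displacement_threshold,
        planar_major=planar_major,
        planar_minor=planar_minor,
        global_fraction=global_fraction,
        burst_participation=burst_participation,
        bin_ms=bin_ms,
    )
    # the stationary/traveling drift criterion is defined per 2.5 s of
    # trajectory; the main label is judged on the final 2.5 s (or what fits)
    main0 = max(t0, t1 - 2500.0)
    main_kwargs = dict(kwargs)
    main_kwargs["displacement_threshold"] = (
        displacement_threshold * (t1 - main0) / 2500.0
    )
    label, diag = _classify_window(spikes, (main0, t1), **main_kwargs)

    # quiescence is judged on everything after the transient
    if label != "quiescent":
        any_exc = (
            (spikes.species[spikes.cell_ids] == EXC) & (spikes.times >= t0)
        ).any()
        if not any_exc:
            label = "quiescent"

    # stability across four sub-windows
    q = (t1 - t0) / 4.0
    sub_labels = []
    for k in range(4):
        sub_kwargs = dict(kwargs)
        sub_kwargs["displacement_threshold"] = displacement_threshold * q / 2500.0
        sl, _ = _classify_window(spikes, (t0 + k * q, t0 + (k + 1) * q), **sub_kwargs)
        sub_labels.append(sl)
    diag["sub_labels"] = sub_labels
    # sub-window labels within one "family" (localized/moving activity vs
    # quiescence vs global states) are compatible refinements; spanning more
    # than one family marks genuinely mixed dynamics
    families = {
        "stationary_bump": 0, "traveling_bump": 0, "planar_wave": 0,
        "multiple_bumps": 0,
        "quiescent": 1,
        "global_burst": 2,
        "global_high_frequency": 3,
        "mixed": 4,
    }
    if label != "quiescent" and len({families[s] for s in sub_labels}) > 1:
        label = "mixed"
    return RegimeLabel(label=label, diagnostics=diag)
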