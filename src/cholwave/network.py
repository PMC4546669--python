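"""Two-layer periodic lattice with center-surround (lateral inhibition)
connectivity.

Excitatory cells sit on a unit grid of side L; inhibitory cells on a coarser
regular grid covering the same area (offset by half an inhibitory cell so the
two layers interleave). Every excitatory cell projects to all excitatory and
inhibitory cells within species-pair radii

    R = sqrt(L^2 k / (pi N)),

where N is the cell count of the *target* layer and k the expected in-radius
neighbor count implied by the layer's density (k = density * pi R^2 holds
exactly). With the default geometry (L=25, 625 E, k_ee=16) this yields
exactly 20 excitatory neighbors on the periodic unit grid. Inhibitory cells
project globally to all excitatory cells; inhibitory-to-inhibitory coupling
is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EXC",
    "INH",
    "LatticeSpec",
    "HeterogeneitySpec",
    "Network",
    "connection_radius",
    "periodic_distance",
    "build_network",
    "apply_heterogeneity",
]

EXC = 0
INH = 1


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the two-layer lattice (all lengths in lattice units)."""

    L: float = 25.0
    n_exc: int = 625
    n_inh: int = 121
    periodic: bool = True

    def __post_init__(self) -> None:
        side_e = round(math.sqrt(self.n_exc))
        if side_e * side_e != self.n_exc:
            raise ValueError("n_exc must be a perfect square")
        side_i = round(math.sqrt(self.n_inh))
        if side_i * side_i != self.n_inh:
            raise ValueError("n_inh must be a perfect square")
        if not self.periodic:
            raise NotImplementedError("only periodic boundaries are supported")

    @property
    def side_e(self) -> int:
        return round(math.sqrt(self.n_exc))

    @property
    def side_i(self) -> int:
        return round(math.sqrt(self.n_inh))

    @property
    def grain_e(self) -> float:
        """Spacing of excitatory cells (1 for the default geometry)."""
        return self.L / self.side_e

    @property
    def grain_i(self) -> float:
        """Spacing of inhibitory cells (L/11 ~ 2.27 for the default)."""
        return self.L / self.side_i


@dataclass(frozen=True)
class HeterogeneitySpec:
    """A square patch of strengthened recurrent excitation.

    Only excitatory-to-excitatory connections beginning AND terminating
    inside the region are multiplied. Member cells also receive
    ``stim_current`` of direct current during the first ``stim_duration`` of
    a simulation, seeding activity inside the patch.
    """

    origin: tuple[float, float] = (8.0, 8.0)  # lower-left corner, lattice units
    side: float = 8.0
    multiplier: float = 1.1
    stim_current: float = 0.5  # uA/cm^2
    stim_duration: float = 500.0  # ms

    def __post_init__(self) -> None:
        if self.multiplier < 1.0:
            raise ValueError("heterogeneity multiplier must be >= 1")
        if self.side <= 0:
            raise ValueError("region side must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, y0 = self.origin
        return (
            (x >= x0) & (x < x0 + self.side) & (y >= y0) & (y < y0 + self.side)
        )


def connection_radius(L: float, k: float, N: int) -> float:
    """Connection radius R = sqrt(L^2 k / (pi N)) for target-layer size N."""
    if k <= 0 or N <= 0:
        raise ValueError("k and N must be positive")
    return math.sqrt(L * L * k / (math.pi * N))


def periodic_distance(a, b, L: float):
    """Euclidean distance under the minimal-image convention on the torus.

    Accepts single positions or arrays of shape (..., 2).
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    d = np.minimum(d, L - d)
    return np.sqrt((d * d).sum(axis=-1))


@dataclass
class Network:
    """Cell positions, species labels, and the weighted directed edge list.

    Edges are stored as parallel arrays (pre, post, weight); ``pre`` projects
    to ``post``. Weights are in uS/cm^2 (peak synaptic conductance).
    """

    spec: LatticeSpec
    positions: np.ndarray  # (n_cells, 2)
    species: np.ndarray  # (n_cells,), EXC or INH
    pre: np.ndarray  # (n_edges,)
    post: np.ndarray  # (n_edges,)
    weight: np.ndarray  # (n_edges,)
    het_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    heterogeneity: HeterogeneitySpec | None = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def exc_ids(self) -> np.ndarray:
        return np.flatnonzero(self.species == EXC)

    @property
    def inh_ids(self) -> np.ndarray:
        return np.flatnonzero(self.species == INH)

    def out_degree(self, i: int, target_species: int | None = None) -> int:
        mask = self.pre == i
        if target_species is not None:
            mask &= self.species[self.post] == target_species
        return int(mask.sum())

    def uniform_inhibitory_weight(self) -> float | None:
        """The common I->E weight if inhibition is global and uniform, else None.

        The simulator uses this to take an O(1) fast path for the global
        inhibitory projection.
        """
        inh_edges = (self.species[self.pre] == INH) & (self.species[self.post] == EXC)
        n_i, n_e = self.inh_ids.size, self.exc_ids.size
        if inh_edges.sum() != n_i * n_e:
            return None
        w = self.weight[inh_edges]
        if w.size and np.all(w == w[0]):
            return float(w[0])
        return None

    # --- I/O ---------------------------------------------------------------

    def to_tsv(self, outdir: str | Path) -> None:
        """Write nodes.tsv (id, x, y, species) and edges.tsv
        (pre_id, post_id, weight, pre_species, post_species)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sp = np.where(self.species == EXC, "excitatory", "inhibitory")
        pd.DataFrame({
            "id": np.arange(self.n_cells),
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "species": sp,
        }).to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame({
            "pre_id": self.pre,
            "post_id": self.post,
            "weight": self.weight,
            "pre_species": sp[self.pre],
            "post_species": sp[self.post],
        }).to_csv(outdir / "edges.tsv", sep="\t", index=False)
        with open(outdir / "meta.tsv", "w") as f:
            f.write("L\tn_exc\tn_inh\n")
            f.write(f"{self.spec.L}\t{self.spec.n_exc}\t{self.spec.n_inh}\n")

    @classmethod
    def from_tsv(cls, indir: str | Path) -> "Network":
        indir = Path(indir)
        nodes = pd.read_csv(indir / "nodes.tsv", sep="\t")
        edges = pd.read_csv(indir / "edges.tsv", sep="\t")
        meta = pd.read_csv(indir / "meta.tsv", sep="\t")
        spec = LatticeSpec(
            L=float(meta["L"][0]),
            n_exc=int(meta["n_exc"][0]),
            n_inh=int(meta["n_inh"][0]),
        )
        species = np.where(nodes["species"].to_numpy() == "excitatory", EXC, INH)
        return cls(
            spec=spec,
            positions=nodes[["x", "y"]].to_numpy(dtype=float),
            species=species.astype(np.int64),
            pre=edges["pre_id"].to_numpy(dtype=np.int64),
            post=edges["post_id"].to_numpy(dtype=np.int64),
            weight=edges["weight"].to_numpy(dtype=float),
        )


def _grid_positions(side: int, spacing: float, offset: float) -> np.ndarray:
    idx = np.arange(side)
    xx, yy = np.meshgrid(idx, idx, indexing="ij")
    pos = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    return pos * spacing + offset


def build_network(
    spec: LatticeSpec = LatticeSpec(),
    k_ee: float = 16.0,
    k_ei: float = 4.0,
    w_ee: float = 20.0,
    w_ei: float = 20.0,
    w_ie: float = 20.0,
    w_ii: float = 20.0,
) -> Network:
    """Construct the lattice and its center-surround connectivity.

    E cells project to every E cell within R_ee and every I cell within R_ei
    (no self-edges); I cells are globally connected, projecting to every E
    cell with weight ``w_ie`` and to every other I cell with ``w_ii``
    (mutual inhibition stabilizes the interneuron population; set
    ``w_ii=0`` to drop it). Default weights are 20 uS/cm^2 for all synapses.
    """
    L = spec.L
    pos_e = _grid_positions(spec.side_e, spec.grain_e, 0.0)
    pos_i = _grid_positions(spec.side_i, spec.grain_i, spec.grain_i / 2.0)
    positions = np.vstack([pos_e, pos_i])
    species = np.concatenate([
        np.zeros(spec.n_exc, dtype=np.int64),
        np.ones(spec.n_inh, dtype=np.int64),
    ])

    r_ee = connection_radius(L, k_ee, spec.n_exc)
    r_ei = connection_radius(L, k_ei, spec.n_inh)
    if max(r_ee, r_ei) > L / 2:
        raise ValueError("connection radius exceeds L/2: minimal image ambiguous")

    pres, posts = [], []
    # E -> E and E -> I by radius (vectorized per source cell)
    for i in range(spec.n_exc):
        d_e = periodic_distance(pos_e[i], pos_e, L)
        tgt = np.flatnonzero(d_e <= r_ee)
        tgt = tgt[tgt != i]
        pres.append(np.full(tgt.size, i))
        posts.append(tgt)
        d_i = periodic_distance(pos_e[i], pos_i, L)
        tgt_i = np.flatnonzero(d_i <= r_ei) + spec.n_exc
        pres.append(np.full(tgt_i.size, i))
        posts.append(tgt_i)
    # I -> E globally
    for j in range(spec.n_inh):
        pres.append(np.full(spec.n_exc, spec.n_exc + j))
        posts.append(np.arange(spec.n_exc))
    # I -> I globally (no self-edges)
    if w_ii > 0:
        for j in range(spec.n_inh):
            others = np.delete(np.arange(spec.n_inh), j) + spec.n_exc
            pres.append(np.full(others.size, spec.n_exc + j))
            posts.append(others)

    pre = np.concatenate(pres).astype(np.int64)
    post = np.concatenate(posts).astype(np.int64)
    weight = np.empty(pre.size, dtype=float)
    pre_e = species[pre] == EXC
    post_e = species[post] == EXC
    weight[pre_e & post_e] = w_ee
    weight[pre_e & ~post_e] = w_ei
    weight[~pre_e & post_e] = w_ie
    weight[~pre_e & ~post_e] = w_ii
    return Network(
        spec=spec, positions=positions, species=species,
        pre=pre, post=post, weight=weight,
    )


def apply_heterogeneity(net: Network, het: HeterogeneitySpec) -> Network:
    """Return a copy with recurrent E->E weights inside the region multiplied.

    Only edges whose *both* endpoints are excitatory cells inside the square
    region are scaled; the member-cell index set (used for the seeding
    stimulus and for the preference measure phi) is stored on the result.
    """
    x, y = net.positions[:, 0], net.positions[:, 1]
    inside = het.contains(x, y) & (net.species == EXC)
    members = np.flatnonzero(inside)
    if members.size == 0:
        raise ValueError("heterogeneity region contains no excitatory cells")
    sel = (
        inside[net.pre] & inside[net.post]
        & (net.species[net.pre] == EXC) & (net.species[net.post] == EXC)
    )
    weight = net.weight.copy()
    weight[sel] *= het.multiplier
    return Network(
        spec=net.spec,
        positions=net.positions,
        species=net.species,
        pre=net.pre.copy(),
        post=net.post.copy(),
        weight=weight,
        het_cells=members,
        heterogeneity=het,
    )
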