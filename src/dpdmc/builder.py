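"""Chain topologies and initial configurations for the three-component system.

The study system is a 20% polymer solution of three linear bead-spring
species in monomeric solvent:

* ``A19``  - solvophobic homopolymer, 19 A beads (4% by volume),
* ``A1S6`` - amphiphilic di-block copolymer, 1 A bead + 6 S beads (13%),
* ``S6``   - solvophilic homopolymer, 6 S beads (3%),
* ``W``    - solvent, single beads (80%).

All quantities are in reduced DPD units (R_c = m = kBT = 1).  A box of
edge L at reduced density rho holds round(rho * L^3) beads.  Chain counts
are rounded to the nearest integer and the bead deficit/surplus is absorbed
into the solvent, so the total density is exact and the composition is
perturbed by well under 0.1% for the boxes of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .interactions import SPECIES

#: Bead-type sequence of each molecular species.
ARCHITECTURES: dict[str, str] = {
    "A19": "A" * 19,
    "A1S6": "A" + "S" * 6,
    "S6": "S" * 6,
    "W": "W",
}

#: Molecule-species codes (order of ARCHITECTURES).
MOL_SPECIES = tuple(ARCHITECTURES)
MOL_A19, MOL_A1S6, MOL_S6, MOL_W = range(4)

#: Reference composition, volume percent.
REFERENCE_COMPOSITION: dict[str, float] = {"A19": 4.0, "A1S6": 13.0, "S6": 3.0, "W": 80.0}

#: Step length of the freely jointed random walk used for initial chains.
INIT_BOND_LENGTH = 0.7


@dataclass(frozen=True)
class SystemSpec:
    """Composition specification for one simulation system."""

    box_edge: float = 40.0
    rho: float = 3.0
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_COMPOSITION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        unknown = set(self.composition) - set(ARCHITECTURES)
        if unknown:
            raise ValueError(f"unknown species in composition: {sorted(unknown)}")
        total = sum(self.composition.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"composition percentages must sum to 100, got {total}")
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition percentages must be non-negative")

    @property
    def n_beads(self) -> int:
        return int(round(self.rho * self.box_edge**3))

    def with_seed(self, seed: int) -> "SystemSpec":
        return replace(self, seed=seed)


@dataclass
class Topology:
    """Bead -> molecule bookkeeping and the harmonic bond list.

    ``mol_species[i]`` is the molecule-species code of bead i (MOL_A19,
    MOL_A1S6, MOL_S6 or MOL_W); ``mol_id[i]`` numbers molecules consecutively.
    ``bonds`` holds one row (i, j) per harmonic spring; bonds exist only
    between consecutive beads of a chain, so a chain of length L contributes
    exactly L - 1 bonds and the bond graph is a disjoint union of paths.
    """

    n_beads: int
    mol_species: np.ndarray  # (N,) int8
    mol_id: np.ndarray       # (N,) int32
    bonds: np.ndarray        # (M, 2) int64
    bead_types: np.ndarray   # (N,) int8, codes into interactions.SPECIES
    chain_counts: dict[str, int]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def polymer_mask(self) -> np.ndarray:
        return self.mol_species != MOL_W

    def species_mask(self, name: str) -> np.ndarray:
        return self.mol_species == MOL_SPECIES.index(name)


@dataclass
class Configuration:
    """Bead positions/velocities/types in a periodic cubic box (reduced units).

    Coordinates are stored wrapped into ``[0, box_edge)``.
    """

    positions: np.ndarray   # (N, 3) float64
    velocities: np.ndarray  # (N, 3) float64
    types: np.ndarray       # (N,) int8
    box_edge: float

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.types = np.ascontiguousarray(self.types, dtype=np.int8)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must be (N, 3)")
        if self.types.shape != (n,):
            raise ValueError("types must be (N,)")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.velocities.copy(),
                             self.types.copy(), self.box_edge)

    def wrap(self) -> None:
        """Re-wrap all coordinates into [0, box_edge)."""
        L = self.box_edge
        self.positions -= L * np.floor(self.positions / L)


def chain_counts(spec: SystemSpec) -> dict[str, int]:
    """Number of molecules of each species for a spec.

    Chain counts are ``round(pct/100 * N_total / chain_length)``; the solvent
    count absorbs the rounding remainder so the total equals round(rho L^3).
    """
    n_total = spec.n_beads
    counts: dict[str, int] = {}
    polymer_beads = 0
    for name, arch in ARCHITECTURES.items():
        if name == "W":
            continue
        pct = spec.composition.get(name, 0.0)
        n_chain = int(round(pct / 100.0 * n_total / len(arch)))
        counts[name] = n_chain
        polymer_beads += n_chain * len(arch)
    n_w = n_total - polymer_beads
    if n_w < 0:
        raise ValueError("polymer beads exceed total bead count; check composition")
    counts["W"] = n_w
    return counts


def build_topology(spec: SystemSpec) -> Topology:
    """Construct the molecule records and bond list for a spec."""
    counts = chain_counts(spec)
    n_total = spec.n_beads
    type_code = {s: i for i, s in enumerate(SPECIES)}

    mol_species = np.empty(n_total, dtype=np.int8)
    mol_id = np.empty(n_total, dtype=np.int32)
    bead_types = np.empty(n_total, dtype=np.int8)
    bonds: list[tuple[int, int]] = []

    idx = 0
    mol = 0
    for name, arch in ARCHITECTURES.items():
        code = MOL_SPECIES.index(name)
        arch_types = [type_code[c] for c in arch]
        L = len(arch)
        for _ in range(counts[name]):
            for k, t in enumerate(arch_types):
                mol_species[idx + k] = code
                mol_id[idx + k] = mol
                bead_types[idx + k] = t
            for k in range(L - 1):
                bonds.append((idx + k, idx + k + 1))
            idx += L
            mol += 1
    assert idx == n_total, "bead bookkeeping mismatch"

    bond_arr = (np.array(bonds, dtype=np.int64) if bonds
                else np.empty((0, 2), dtype=np.int64))
    return Topology(n_beads=n_total, mol_species=mol_species, mol_id=mol_id,
                    bonds=bond_arr, bead_types=bead_types, chain_counts=counts)


def initialize_random(spec: SystemSpec, topology: Topology) -> Configuration:
    """Random initial configuration: chains as freely jointed walks, solvent
    uniform, Maxwell velocities at kBT = 1 with the net momentum removed.

    Deterministic for a given ``spec.seed``.  The soft DPD potentials
    tolerate arbitrary overlap, so no packing optimization is attempted.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box_edge
    n = topology.n_beads
    pos = np.empty((n, 3))

    # Walk each chain; molecules are laid out with consecutive bead indices.
    starts = np.flatnonzero(np.r_[True, np.diff(topology.mol_id) != 0])
    ends = np.r_[starts[1:], n]
    for s, e in zip(starts, ends):
        length = e - s
        pos[s] = rng.uniform(0.0, L, size=3)
        if length > 1:
            steps = rng.normal(size=(length - 1, 3))
            steps *= INIT_BOND_LENGTH / np.linalg.norm(steps, axis=1)[:, None]
            pos[s + 1:e] = pos[s] + np.cumsum(steps, axis=0)
    pos -= L * np.floor(pos / L)

    vel = rng.normal(0.0, 1.0, size=(n, 3))
    vel -= vel.mean(axis=0)

    return Configuration(positions=pos, velocities=vel,
                         types=topology.bead_types, box_edge=L)


def build_system(spec: SystemSpec) -> tuple[Topology, Configuration]:
    """Convenience: topology plus random initial configuration."""
    topo = build_topology(spec)
    return topo, initialize_random(spec, topo)
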