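"""DPD force field and NVT integrator.

The total force on bead i is the sum over beads j within the cutoff R_c of

* conservative soft repulsion   a_ij (1 - r/R_c) e_ij,
* dissipative drag              -gamma (1 - r/R_c)^2 (v_ij . e_ij) e_ij,
* random kicks                  sigma (1 - r/R_c) xi_ij dt^{-1/2} e_ij,

plus harmonic spring forces -C r_ij between consecutive chain beads (no
cutoff; bonded pairs also feel the nonbonded forces).  xi_ij is Gaussian
with zero mean and unit variance, drawn once per interacting pair per step
and symmetric under index exchange, so every pairwise contribution is
exactly antisymmetric and momentum is conserved to rounding error.  The
dissipative/random weight functions obey w_D = w_R^2 and sigma^2 = 2 gamma
kBT (fluctuation-dissipation), which makes the pair thermostat hold the
system at kBT.

Time integration uses the modified velocity-Verlet scheme with velocity
prediction factor lambda (0.65) and time step 0.05 tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from . import _kernels
from .builder import Configuration, Topology
from .interactions import InteractionTable


class IntegrationError(RuntimeError):
    """Raised when the integrator produces non-finite or ambiguous state."""


@dataclass(frozen=True)
class IntegratorSettings:
    """Time-stepping parameters (reduced units)."""

    dt: float = 0.05
    lambda_vv: float = 0.65
    n_steps: int = 10_000
    kBT: float = 1.0
    seed: int = 0
    snapshot_interval: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.lambda_vv <= 1.0):
            raise ValueError("lambda_vv must be in (0, 1]")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")


@dataclass
class Trajectory:
    """Snapshots plus a per-interval scalar log.

    ``frames`` maps saved step numbers to position arrays (wrapped);
    ``log`` holds step, kinetic temperature and momentum components.
    The final full state (positions and velocities) is ``final``.
    """

    steps: list[int] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)
    types: np.ndarray | None = None
    box_edge: float = 0.0
    log: pd.DataFrame | None = None
    final: Configuration | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[int, np.ndarray]]:
        return iter(zip(self.steps, self.frames))


def kinetic_temperature(velocities: np.ndarray) -> float:
    """Instantaneous kinetic temperature, 2 KE / (3 N) at unit mass."""
    return float(np.mean(velocities**2))


def pair_forces(config: Configuration, table: InteractionTable,
                seed: int = 0, dt: float = 0.05, *,
                with_noise: bool = True,
                velocities: np.ndarray | None = None) -> np.ndarray:
    """Nonbonded DPD forces for one configuration (no bonds).

    The dissipative term uses ``velocities`` if given, otherwise the
    configuration's own.  Noise can be disabled for deterministic checks.
    """
    n = config.n_beads
    fout = np.empty((n, 3))
    vel = config.velocities if velocities is None else velocities
    sig_dt = table.sigma / np.sqrt(dt) if with_noise else 0.0
    st = _kernels.rng_state(seed)
    empty_bonds = np.empty((0, 2), dtype=np.int64)
    _kernels.compute_forces(config.positions, vel, config.types, table.a,
                            table.gamma, sig_dt, empty_bonds, 0.0,
                            config.box_edge, table.r_cut, st, fout)
    return fout


def spring_forces(config: Configuration, topology: Topology,
                  spring_c: float = 4.0) -> np.ndarray:
    """Harmonic bond forces -C r_ij for every bond (minimum image)."""
    fout = np.zeros((config.n_beads, 3))
    bad = _kernels._spring_forces(config.positions, topology.bonds, spring_c,
                                  config.box_edge, fout)
    if bad >= 0:
        i, j = topology.bonds[bad]
        raise IntegrationError(
            f"bond ({i}, {j}) longer than half the box: minimum-image ambiguity")
    return fout


def build_cell_list(config: Configuration, r_cut: float) -> np.ndarray:
    """All pairs (i, j), i < j, with minimum-image distance < r_cut.

    Uses a linked-cell search when the box admits one (edge >= 3 r_cut),
    otherwise an all-pairs scan.  Returns an (n_pairs, 2) int array sorted
    lexicographically (order-independent of the internal cell walk).
    """
    pos = config.positions
    box = config.box_edge
    ncell = int(box / r_cut)
    dummy = np.empty(1, dtype=np.int64)
    if ncell >= 3:
        count = _kernels._collect_pairs_cells(pos, box, r_cut, ncell,
                                              dummy, dummy, False)
        out_i = np.empty(count, dtype=np.int64)
        out_j = np.empty(count, dtype=np.int64)
        _kernels._collect_pairs_cells(pos, box, r_cut, ncell,
                                      out_i, out_j, True)
    else:
        count = _kernels._collect_pairs_brute(pos, box, r_cut,
                                              dummy, dummy, False)
        out_i = np.empty(count, dtype=np.int64)
        out_j = np.empty(count, dtype=np.int64)
        _kernels._collect_pairs_brute(pos, box, r_cut, out_i, out_j, True)
    pairs = np.stack([np.minimum(out_i, out_j), np.maximum(out_i, out_j)],
                     axis=1)
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return pairs


def integrate_step(config: Configuration, topology: Topology,
                   table: InteractionTable, settings: IntegratorSettings,
                   forces: np.ndarray | None = None,
                   rng_state: np.ndarray | None = None
                   ) -> tuple[Configuration, np.ndarray]:
    """Advance one modified velocity-Verlet step; returns the new
    configuration and the forces consistent with it.

    ``forces`` must be the force array for the input state (computed here
    when omitted); ``rng_state`` is an xorshift128+ state advanced in
    place (derived from ``settings.seed`` when omitted).  Positions are
    rewrapped into the box.
    """
    state = config.copy()
    state.wrap()
    st = (_kernels.rng_state(settings.seed) if rng_state is None
          else rng_state)
    sig_dt = table.sigma / np.sqrt(settings.dt)
    if forces is None:
        forces = np.empty((state.n_beads, 3))
        bad = _kernels.compute_forces(
            state.positions, state.velocities, state.types, table.a,
            table.gamma, sig_dt, topology.bonds, table.spring_c,
            state.box_edge, table.r_cut, st, forces)
        if bad >= 0:
            i, j = topology.bonds[bad]
            raise IntegrationError(
                f"bond ({i}, {j}) longer than half the box")
    frc = forces.copy()
    bad = _kernels.run_chunk(state.positions, state.velocities, frc,
                             state.types, table.a, table.gamma, sig_dt,
                             topology.bonds, table.spring_c, state.box_edge,
                             table.r_cut, settings.dt, settings.lambda_vv,
                             1, st)
    if bad >= 0:
        i, j = topology.bonds[bad]
        raise IntegrationError(f"bond ({i}, {j}) exceeded half the box")
    if not (np.isfinite(state.positions).all()
            and np.isfinite(state.velocities).all()):
        raise IntegrationError("non-finite coordinates or velocities")
    return state, frc


def run(config: Configuration, topology: Topology, table: InteractionTable,
        settings: IntegratorSettings, *,
        store_frames: bool = True) -> Trajectory:
    """Integrate a system forward in the NVT ensemble.

    The input configuration is not modified.  Frames (positions) are stored
    every ``snapshot_interval`` steps, including the initial state; the
    scalar log records kinetic temperature and total momentum at the same
    cadence.  Bitwise deterministic for a given seed.
    """
    state = config.copy()
    state.wrap()
    pos, vel = state.positions, state.velocities
    n = state.n_beads
    dt = settings.dt
    sig_dt = table.sigma / np.sqrt(dt)

    st = _kernels.rng_state(settings.seed)
    frc = np.empty((n, 3))
    bad = _kernels.compute_forces(pos, vel, state.types, table.a, table.gamma,
                                  sig_dt, topology.bonds, table.spring_c,
                                  state.box_edge, table.r_cut, st, frc)
    if bad >= 0:
        i, j = topology.bonds[bad]
        raise IntegrationError(f"initial bond ({i}, {j}) longer than half the box")

    traj = Trajectory(types=state.types.copy(), box_edge=state.box_edge)
    log_rows = []

    def record(step: int) -> None:
        if store_frames:
            traj.steps.append(step)
            traj.frames.append(pos.copy())
        p = vel.sum(axis=0)
        log_rows.append((step, kinetic_temperature(vel), p[0], p[1], p[2]))

    record(0)
    step = 0
    while step < settings.n_steps:
        chunk = min(settings.snapshot_interval, settings.n_steps - step)
        bad = _kernels.run_chunk(pos, vel, frc, state.types, table.a,
                                 table.gamma, sig_dt, topology.bonds,
                                 table.spring_c, state.box_edge, table.r_cut,
                                 dt, settings.lambda_vv, chunk, st)
        step += chunk
        if bad >= 0:
            i, j = topology.bonds[bad]
            raise IntegrationError(
                f"step {step}: bond ({i}, {j}) exceeded half the box")
        if not (np.isfinite(pos).all() and np.isfinite(vel).all()):
            raise IntegrationError(f"step {step}: non-finite coordinates or velocities")
        record(step)

    traj.log = pd.DataFrame(log_rows,
                            columns=["step", "temperature", "px", "py", "pz"])
    traj.final = state
    return traj
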