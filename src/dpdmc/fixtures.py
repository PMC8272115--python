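"""Synthetic configurations with known ground truth.

These fixtures emulate the morphologies the analysis stack must recognize
— multicore micelles, single-core micelles, multicompartment aggregates,
rods, disks, slabs and fully dispersed beads — as purely geometric
constructions (lattice-filled balls and shells), so every analysis
operation can be exercised without running any dynamics.  Each fixture
carries a ground-truth record (cluster count, core counts, expected shape
and segregation classes) that the clustering / shape / order-parameter
code must recover.

Construction notes: solid regions are cubic-lattice fills with spacing
0.8 R_c, well below the 1.5 R_c cluster cutoff, so each region is
internally connected and an embedded core connects to its surrounding
matrix; distinct cores are kept > 1.5 R_c apart.  Solvophobic cores get a
thin shell of copolymer solvophobe beads (the first corona layer of a
micelle), so the copolymer-coverage heuristic sees them as shielded.
Lattice balls inherit cubic symmetry, which makes the gyration tensor
exactly isotropic (asphericity 0); rings and collinear rods realize the
disk (0.25) and rod (1) limits exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .builder import (
    MOL_A19,
    MOL_A1S6,
    MOL_S6,
    MOL_W,
    Configuration,
    Topology,
)
from .interactions import TYPE_A, TYPE_S, TYPE_W

FIXTURE_KINDS = (
    "multicore",
    "single-core",
    "mixed-compartment",
    "rod",
    "disk",
    "sphere",
    "slab",
    "mixed",
    "dispersed",
)

LATTICE_SPACING = 0.8


class FixtureGeometryError(ValueError):
    """Requested fixture geometry cannot be realized in the box."""


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of a synthetic configuration.

    ``n_cores``/``n_s_cores`` count solvophobic A / S compartments for the
    micelle-like kinds; ``core_radius`` and ``corona_radius`` are in R_c.
    """

    kind: str = "multicore"
    box_edge: float = 24.0
    n_cores: int = 3
    n_s_cores: int = 0
    core_radius: float = 1.6
    corona_radius: float | None = None
    n_beads: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind: {self.kind!r}")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")


@dataclass
class Fixture:
    """A synthetic configuration, its bead labels, and its ground truth."""

    config: Configuration
    mol_species: np.ndarray
    ground_truth: dict

    def topology(self) -> Topology:
        """Bond-free topology carrying the bead labels (for the analysis
        pipeline, which reads species masks from a Topology)."""
        n = self.config.n_beads
        return Topology(
            n_beads=n, mol_species=self.mol_species.astype(np.int8),
            mol_id=np.arange(n, dtype=np.int32),
            bonds=np.empty((0, 2), dtype=np.int64),
            bead_types=self.config.types.copy(),
            chain_counts={})


def _lattice_ball(center: np.ndarray, radius: float,
                  spacing: float = LATTICE_SPACING) -> np.ndarray:
    """Cubic-lattice points within a ball (cubically symmetric set)."""
    k = int(np.floor(radius / spacing))
    axis = np.arange(-k, k + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + center


def _core_centers(k: int, ring_radius: float) -> np.ndarray:
    """K points evenly spread on a circle (z = 0); a single core sits at
    the origin."""
    if k == 1:
        return np.zeros((1, 3))
    ang = 2.0 * np.pi * np.arange(k) / k
    return np.column_stack([ring_radius * np.cos(ang),
                            ring_radius * np.sin(ang),
                            np.zeros(k)])


def _micelle_fixture(spec: FixtureSpec) -> Fixture:
    """Multicore / single-core / mixed-compartment construction.

    A corona ball of copolymer beads (solvophilic type) embeds ``n_cores``
    A-homopolymer balls and ``n_s_cores`` S-homopolymer balls; every A core
    is wrapped in one shell of copolymer solvophobe beads.
    """
    k_a = spec.n_cores
    k_s = spec.n_s_cores
    k_tot = k_a + k_s
    rc = spec.core_radius
    gap = 2.2  # center-surface clearance beyond the 1.5 cluster cutoff
    if k_tot == 0:
        raise FixtureGeometryError("micelle fixture needs at least one core")
    if k_tot == 1:
        ring = 0.0
    else:
        # pairwise center distance on the ring must exceed 2 rc + gap
        min_center_dist = 2 * rc + gap
        ring = min_center_dist / (2 * np.sin(np.pi / k_tot))
    corona = spec.corona_radius
    if corona is None:
        corona = ring + rc + 3.0
    if corona + 1.0 > spec.box_edge / 2:
        raise FixtureGeometryError(
            f"corona radius {corona:.1f} does not fit in box {spec.box_edge}")
    if ring + rc + 1.5 > corona:
        raise FixtureGeometryError("cores do not fit inside the corona")

    center = np.full(3, spec.box_edge / 2)
    centers = _core_centers(k_tot, ring) + center
    rng = np.random.default_rng(spec.seed)

    pos_list: list[np.ndarray] = []
    mol_list: list[np.ndarray] = []
    type_list: list[np.ndarray] = []

    def add(points: np.ndarray, mol: int, typ: int) -> None:
        pos_list.append(points)
        mol_list.append(np.full(len(points), mol, dtype=np.int8))
        type_list.append(np.full(len(points), typ, dtype=np.int8))

    # corona matrix: copolymer solvophilic beads, avoiding core exclusion
    # zones (core radius + one shell + clearance below the cutoff)
    matrix = _lattice_ball(center, corona)
    keep = np.ones(len(matrix), dtype=bool)
    for c, is_a in zip(centers, [True] * k_a + [False] * k_s):
        excl = rc + (1.0 if is_a else 0.4) + 0.4
        keep &= np.linalg.norm(matrix - c, axis=1) > excl
    add(matrix[keep], MOL_A1S6, TYPE_S)

    for idx, c in enumerate(centers):
        is_a = idx < k_a
        # dense fill: condensed-core density, well above the classifier's
        # local-density requirement
        ball = _lattice_ball(c, rc, spacing=0.6)
        if is_a:
            add(ball, MOL_A19, TYPE_A)
            # copolymer solvophobe shell on the core surface
            shell = _fibonacci_shell(c, rc + 0.6,
                                     max(12, int(10 * (rc + 0.6) ** 2)))
            add(shell, MOL_A1S6, TYPE_A)
        else:
            add(ball, MOL_S6, TYPE_S)

    positions = np.vstack(pos_list)
    positions += rng.normal(scale=0.02, size=positions.shape)  # break ties
    mol_species = np.concatenate(mol_list)
    types = np.concatenate(type_list)
    config = Configuration(positions=positions,
                           velocities=np.zeros_like(positions),
                           types=types, box_edge=spec.box_edge)
    config.wrap()
    label = ("multicore-multicompartment" if (k_a >= 1 and k_s >= 1)
             else ("multicore" if k_a >= 2 else "single-core"))
    truth = {
        "kind": spec.kind, "n_aggregates": 1, "n_a_cores": k_a,
        "n_s_cores": k_s, "label": label, "delta_class": None,
        "phi_class": None, "n_beads": len(positions),
    }
    return Fixture(config=config, mol_species=mol_species,
                   ground_truth=truth)


def _fibonacci_shell(center: np.ndarray, radius: float,
                     n: int) -> np.ndarray:
    """Nearly uniform points on a sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    pts = np.column_stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta),
                           np.cos(phi)])
    return center + radius * pts


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the configuration and ground-truth record for a spec."""
    if spec.kind in ("multicore", "single-core", "mixed-compartment"):
        adjusted = spec
        if spec.kind == "single-core" and spec.n_cores != 1:
            adjusted = FixtureSpec(**{**spec.__dict__, "n_cores": 1,
                                      "n_s_cores": 0})
        if spec.kind == "mixed-compartment" and spec.n_s_cores == 0:
            adjusted = FixtureSpec(**{**spec.__dict__, "n_s_cores": 2})
        return _micelle_fixture(adjusted)
    if spec.kind == "rod":
        return _rod_fixture(spec)
    if spec.kind == "disk":
        return _disk_fixture(spec)
    if spec.kind == "sphere":
        return _sphere_fixture(spec)
    if spec.kind == "slab":
        return _slab_fixture(spec)
    if spec.kind == "mixed":
        return _mixed_fixture(spec)
    return _dispersed_fixture(spec)


def _bare_fixture(spec: FixtureSpec, positions: np.ndarray, mol: int,
                  typ: int, truth: Mapping) -> Fixture:
    positions = np.asarray(positions, dtype=float)
    config = Configuration(positions=positions,
                           velocities=np.zeros_like(positions),
                           types=np.full(len(positions), typ, np.int8),
                           box_edge=spec.box_edge)
    config.wrap()
    return Fixture(config=config,
                   mol_species=np.full(len(positions), mol, np.int8),
                   ground_truth={"kind": spec.kind,
                                 "n_beads": len(positions), **truth})


def _rod_fixture(spec: FixtureSpec) -> Fixture:
    """Exactly collinear beads: lam2 = lam3 = 0, delta = 1."""
    n = max(spec.n_beads, 3)
    length = min(0.5 * (n - 1), spec.box_edge / 2 - 1)
    z = np.linspace(0, length, n)
    pts = np.column_stack([np.full(n, 1.0), np.full(n, 1.0), z + 1.0])
    return _bare_fixture(spec, pts, MOL_A19, TYPE_A,
                         {"n_aggregates": 1, "delta_class": "rod",
                          "delta": 1.0})


def _disk_fixture(spec: FixtureSpec) -> Fixture:
    """Flat concentric 12-fold rings: lam1 = lam2 by symmetry, lam3 = 0,
    delta = 1/4."""
    center = np.full(3, spec.box_edge / 2)
    rings = []
    for r in np.arange(1.0, min(6.0, spec.box_edge / 2 - 2), 1.0):
        ang = 2 * np.pi * np.arange(12) / 12
        rings.append(np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                      np.zeros(12)]))
    pts = center + np.vstack(rings)
    return _bare_fixture(spec, pts, MOL_A19, TYPE_A,
                         {"n_aggregates": 1, "delta_class": "disk",
                          "delta": 0.25})


def _sphere_fixture(spec: FixtureSpec) -> Fixture:
    """Cubic-lattice ball: cubic symmetry forces an isotropic gyration
    tensor, delta = 0 exactly."""
    center = np.full(3, spec.box_edge / 2)
    radius = min(4.0, spec.box_edge / 2 - 2)
    pts = _lattice_ball(center, radius, spacing=0.7)
    return _bare_fixture(spec, pts, MOL_A19, TYPE_A,
                         {"n_aggregates": 1, "delta_class": "sphere",
                          "delta": 0.0})


def _slab_fixture(spec: FixtureSpec) -> Fixture:
    """Perfectly segregated half boxes of A and B beads: phi = 1 for slice
    counts that align with the interface (any even number of slices)."""
    L = spec.box_edge
    spacing = L / max(int(L / LATTICE_SPACING), 4)
    axis = (np.arange(int(round(L / spacing))) + 0.5) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    lower = pts[:, 2] < L / 2
    positions = np.vstack([pts[lower], pts[~lower]])
    n_a = int(lower.sum())
    mol = np.r_[np.full(n_a, MOL_A19, np.int8),
                np.full(len(pts) - n_a, MOL_W, np.int8)]
    types = np.r_[np.full(n_a, TYPE_A, np.int8),
                  np.full(len(pts) - n_a, TYPE_W, np.int8)]
    config = Configuration(positions=positions,
                           velocities=np.zeros_like(positions),
                           types=types, box_edge=L)
    config.wrap()
    return Fixture(config=config, mol_species=mol,
                   ground_truth={"kind": "slab", "phi_class": "segregated",
                                 "phi": 1.0, "a_count": n_a,
                                 "n_beads": len(positions)})


def _mixed_fixture(spec: FixtureSpec) -> Fixture:
    """A and B beads alternating on one lattice: every slice holds equal
    numbers of each, phi = 0 exactly."""
    L = spec.box_edge
    spacing = L / max(int(L / LATTICE_SPACING), 4)
    axis = (np.arange(int(round(L / spacing))) + 0.5) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    # alternate along x so slices perpendicular to z stay balanced
    is_a = (np.round(pts[:, 0] / spacing - 0.5).astype(int) % 2) == 0
    mol = np.where(is_a, MOL_A19, MOL_W).astype(np.int8)
    types = np.where(is_a, TYPE_A, TYPE_W).astype(np.int8)
    config = Configuration(positions=pts,
                           velocities=np.zeros((len(pts), 3)),
                           types=types, box_edge=L)
    config.wrap()
    return Fixture(config=config, mol_species=mol,
                   ground_truth={"kind": "mixed", "phi_class": "mixed",
                                 "phi": 0.0, "n_beads": len(pts)})


def _dispersed_fixture(spec: FixtureSpec) -> Fixture:
    """Isolated beads on a sparse jittered grid, pairwise > 1.5 apart:
    every bead is its own cluster."""
    L = spec.box_edge
    step = 2.4
    n_axis = int(L / step)
    if n_axis < 2:
        raise FixtureGeometryError("box too small for a dispersed fixture")
    rng = np.random.default_rng(spec.seed)
    axis = (np.arange(n_axis) + 0.5) * step
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if len(pts) > spec.n_beads:
        pts = pts[rng.choice(len(pts), spec.n_beads, replace=False)]
    pts = pts + rng.uniform(-0.4, 0.4, size=pts.shape)
    return _bare_fixture(spec, pts, MOL_A19, TYPE_A,
                         {"n_aggregates": len(pts), "n_a_cores": 0,
                          "label": "dispersed"})
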