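"""Orchestration: per-frame aggregate analysis, kinetic-stage detection,
morphology classification and solvent-selectivity sweeps.

The assembly kinetics of the reference mixture proceed in three stages:
(I) nucleation of small single-core micelles — solvophobic cores condense
and the core-size averages rise; (II) the cores saturate while micelles
coalesce through their coronas, so the whole-aggregate averages keep
rising; (III) equilibrium, where the whole-aggregate averages plateau too.
Stage boundaries are therefore read off the number-average size series of
the solvophobic cores and of the whole polymer aggregates.

Equilibrated runs are classified into one of five morphologies:

* ``dispersed``            - no aggregate holds even a few percent of the
                             polymer;
* ``soluble-particle``     - solvophobe particles exist but are mostly bare
                             (copolymer stays solvated);
* ``single-core``          - the largest aggregate carries exactly one
                             solvophobic core;
* ``multicore``            - several solvophobic cores under one corona;
* ``multicore-multicompartment`` - cores of both homopolymer chemistries
                             coexist in one aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import analysis
from .builder import (
    MOL_A19,
    MOL_A1S6,
    MOL_S6,
    MOL_W,
    SystemSpec,
    Topology,
    build_system,
)
from .engine import IntegratorSettings, Trajectory, run
from .interactions import TYPE_A, InteractionTable

MORPHOLOGY_LABELS = (
    "multicore",
    "single-core",
    "soluble-particle",
    "multicore-multicompartment",
    "dispersed",
)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the morphology classifier.

    A cluster of core-species beads only counts as a *core* (a condensed
    compartment) when it has at least ``min_core_size`` beads (20 is about
    one solvophobe chain) *and* it is condensed, meaning its beads either
    average at least ``core_density_min`` same-cluster neighbors within
    1 R_c (a dense droplet sits near 10 at rho = 3) or average at most
    ``core_burial_max`` solvent neighbors within 1 R_c (a solvent-excluded
    compartment; compartments of short chains can be irregular and locally
    dilute yet clearly buried).  Either way, loose chains that merely touch
    one another inside a solvent-swollen corona (~2-4 same-species
    neighbors, solvent exposure > 3) are rejected, which the bare distance
    criterion cannot do.  The coverage heuristic calls a core "covered" through the
    fraction of its surface beads that have a copolymer solvophobe bead
    within ``coverage_cutoff``, where surface beads are core beads with
    fewer than ``surface_neighbor_min`` same-core neighbors within
    ``surface_cutoff``.  The coverage radius is one R_c — an adsorbed
    copolymer head sits in the first coordination shell of the core
    surface — rather than the 1.5 R_c cluster cutoff, at which freely
    dissolved copolymer produces near-unit incidental contact at these
    concentrations and the measure stops discriminating adsorbed from
    bystander chains.
    """

    cluster_cutoff: float = analysis.DEFAULT_CLUSTER_CUTOFF
    min_core_size: int = 20
    core_density_min: float = 6.0
    core_burial_max: float = 2.5
    dispersed_frac: float = 0.05
    coverage_threshold: float = 0.5
    coverage_cutoff: float = 1.0
    coverage_flag_band: float = 0.1
    surface_cutoff: float = 1.0
    surface_neighbor_min: int = 10


@dataclass(frozen=True)
class FrameAnalysis:
    """Scalar aggregate metrics of one stored frame."""

    step: int
    n_aggregates: int
    Xn: float
    Xw: float
    P: float
    core_Xn: float
    core_Xw: float
    core_P: float
    largest_size: int
    largest_frac: float
    n_a_cores: int
    n_s_cores: int
    delta_largest: float
    phi_aggregate: float
    phi_core: float
    coverage: float


@dataclass(frozen=True)
class StageBoundaries:
    """Step indices delimiting kinetic stages I/II/III.

    ``stage1_end`` is the first step at which the core size series has
    entered its plateau, ``stage2_end`` the same for the whole-aggregate
    series; ``equilibrated`` is False when the latter never plateaus
    (the run is then too short, not an error).
    """

    stage1_end: int | None
    stage2_end: int | None
    equilibrated: bool


@dataclass(frozen=True)
class MorphologyResult:
    label: str
    flagged: bool
    votes: dict = field(default_factory=dict)


def _sizes_ge(clusters: Iterable[np.ndarray], min_size: int) -> list[int]:
    return [len(c) for c in clusters if len(c) >= min_size]


def analyze_frame(positions: np.ndarray, box_edge: float, topo: Topology,
                  step: int = 0,
                  params: ClassifierParams = ClassifierParams()) -> FrameAnalysis:
    """All per-frame aggregate metrics used by the stage detector and the
    morphology classifier.

    Whole aggregates are clusters of polymer beads (solvent excluded);
    cores are clusters of solvophobe-homopolymer beads.  The two order
    parameters resolve the generic two-component definition as
    polymer-vs-solvent (aggregate segregation) and
    solvophobe-homopolymer-vs-everything-else (core segregation).
    """
    cutoff = params.cluster_cutoff
    poly = np.flatnonzero(topo.mol_species != MOL_W)
    solvent = np.flatnonzero(topo.mol_species == MOL_W)
    a_homo = np.flatnonzero(topo.mol_species == MOL_A19)
    s_homo = np.flatnonzero(topo.mol_species == MOL_S6)
    other = np.flatnonzero(topo.mol_species != MOL_A19)

    agg = analysis.find_aggregates(positions, box_edge, subset=poly,
                                   cutoff=cutoff)
    stats = analysis.size_statistics(agg)
    if len(a_homo):
        cores_glob = analysis.find_aggregates(positions, box_edge,
                                              subset=a_homo, cutoff=cutoff)
        core_stats = analysis.size_statistics(cores_glob)
    else:
        core_stats = analysis.SizeStatistics(np.nan, np.nan, np.nan, 0)

    largest = agg.largest()
    largest_frac = len(largest) / max(len(poly), 1)

    per_agg_a = analysis.detect_cores(positions, box_edge, agg, a_homo,
                                      cutoff=cutoff)
    per_agg_s = analysis.detect_cores(positions, box_edge, agg, s_homo,
                                      cutoff=cutoff)
    a_cores = _condensed_cores(positions, box_edge, per_agg_a[0], solvent,
                               params)
    s_cores = _condensed_cores(positions, box_edge, per_agg_s[0], solvent,
                               params)

    try:
        delta = analysis.gyration_shape(positions[largest], box_edge,
                                        cutoff=cutoff).delta
    except analysis.UnwrapAmbiguityError:
        delta = np.nan

    phi_agg = analysis.order_parameter(positions, box_edge, poly,
                                       solvent).phi
    phi_core = analysis.order_parameter(positions, box_edge, a_homo,
                                        other).phi
    coverage = _core_coverage(positions, box_edge, a_cores, topo, params)

    return FrameAnalysis(
        step=step, n_aggregates=stats.n_clusters, Xn=stats.Xn, Xw=stats.Xw,
        P=stats.P, core_Xn=core_stats.Xn, core_Xw=core_stats.Xw,
        core_P=core_stats.P, largest_size=len(largest),
        largest_frac=largest_frac, n_a_cores=len(a_cores),
        n_s_cores=len(s_cores), delta_largest=delta,
        phi_aggregate=phi_agg, phi_core=phi_core, coverage=coverage)


def _condensed_cores(positions: np.ndarray, box_edge: float,
                     clusters: Sequence[np.ndarray],
                     solvent_idx: np.ndarray,
                     params: ClassifierParams) -> list[np.ndarray]:
    """Clusters that qualify as condensed cores.

    Requires ``min_core_size`` beads plus condensation: high same-cluster
    density *or* low solvent exposure (see :class:`ClassifierParams`).
    """
    out = []
    wtree = None
    if len(solvent_idx):
        wpos = positions[solvent_idx] - box_edge * np.floor(
            positions[solvent_idx] / box_edge)
        wpos[wpos >= box_edge] = 0.0
        wtree = cKDTree(wpos, boxsize=box_edge)
    for c in clusters:
        if len(c) < params.min_core_size:
            continue
        pts = positions[c] - box_edge * np.floor(positions[c] / box_edge)
        pts[pts >= box_edge] = 0.0
        tree = cKDTree(pts, boxsize=box_edge)
        nn = tree.query_ball_point(pts, 1.0, return_length=True) - 1
        condensed = nn.mean() >= params.core_density_min
        if not condensed and wtree is not None:
            exposure = wtree.query_ball_point(
                pts, 1.0, return_length=True).mean()
            condensed = exposure <= params.core_burial_max
        elif not condensed and wtree is None:
            condensed = True  # solvent-free configuration: nothing to expel
        if condensed:
            out.append(c)
    return out


def _core_coverage(positions: np.ndarray, box_edge: float,
                   a_cores: Sequence[np.ndarray], topo: Topology,
                   params: ClassifierParams) -> float:
    """Fraction of core surface beads shielded by a copolymer solvophobe
    bead within the cluster cutoff (NaN when there is no core)."""
    if not a_cores:
        return np.nan
    copol_a = np.flatnonzero((topo.mol_species == MOL_A1S6)
                             & (topo.bead_types == TYPE_A))
    wrapped = positions - box_edge * np.floor(positions / box_edge)
    wrapped[wrapped >= box_edge] = 0.0
    shield_tree = (cKDTree(wrapped[copol_a], boxsize=box_edge)
                   if len(copol_a) else None)
    n_surf = 0
    n_cov = 0
    for core in a_cores:
        pts = wrapped[core]
        tree = cKDTree(pts, boxsize=box_edge)
        neigh = tree.query_ball_point(pts, params.surface_cutoff,
                                      return_length=True) - 1
        surf = pts[neigh < params.surface_neighbor_min]
        if len(surf) == 0:
            continue
        n_surf += len(surf)
        if shield_tree is not None:
            hits = shield_tree.query_ball_point(
                surf, params.coverage_cutoff, return_length=True)
            n_cov += int(np.count_nonzero(hits))
    if n_surf == 0:
        return np.nan
    return n_cov / n_surf


def analyze_trajectory(traj: Trajectory, topo: Topology,
                       params: ClassifierParams = ClassifierParams(),
                       every: int = 1) -> pd.DataFrame:
    """Per-frame metrics table for the stored frames of a trajectory."""
    rows = []
    for k in range(0, traj.n_frames, every):
        fa = analyze_frame(traj.frames[k], traj.box_edge, topo,
                           step=traj.steps[k], params=params)
        rows.append(fa.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage detection
# ---------------------------------------------------------------------------

def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(series) < 2:
        return np.asarray(series, dtype=float)
    return (pd.Series(series, dtype=float)
            .rolling(window, min_periods=1, center=True).mean().to_numpy())


def _plateau_start(series: np.ndarray, window: int, tol: float) -> int | None:
    """First index from which the remaining series shows no net drift.

    For each candidate start the tail is fit with a straight line; the
    series has settled there when the fitted net change over the tail is
    within ``tol`` of the tail mean or within twice the statistical
    uncertainty of the fitted change given the tail's own fluctuations
    (at desk scale the number-average sizes fluctuate strongly with the
    stray-chain count, so a pure spread criterion would never fire).
    Returns None if the series never settles.
    """
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n < window + 1:
        return None
    for i in range(0, n - window):
        tail = s[i:]
        m = len(tail)
        x = np.arange(m, dtype=float)
        level = np.nanmean(tail)
        if not np.isfinite(level) or level == 0:
            continue
        b, a = np.polyfit(x, tail, 1)
        resid = tail - (a + b * x)
        drift = abs(b) * (m - 1)
        noise_band = 2.0 * np.nanstd(resid) * np.sqrt(12.0 / m)
        if drift <= max(tol * abs(level), noise_band):
            return i
    return None


def detect_stages(steps: Sequence[int], core_xn: Sequence[float],
                  total_xn: Sequence[float], window: int = 10,
                  tol: float = 0.05, smooth: bool = True) -> StageBoundaries:
    """Kinetic stage boundaries from the core and whole-aggregate
    number-average size series (sampled at uniform snapshot cadence).

    The stage I to II boundary is the first step at which the core series
    plateaus (relative spread < ``tol`` over every subsequent window of
    ``window`` snapshots); the II to III boundary is the same for the
    whole-aggregate series.  Both series are lightly smoothed (running
    mean over one window) before the change-point search, which keeps the
    detector stable against single coalescence jumps at desk scale.
    """
    steps = np.asarray(steps)
    core = _smooth(np.asarray(core_xn, float), window if smooth else 1)
    total = _smooth(np.asarray(total_xn, float), window if smooth else 1)
    i1 = _plateau_start(core, window, tol)
    i2 = _plateau_start(total, window, tol)
    if i1 is None and i2 is None:
        return StageBoundaries(None, None, False)
    if i2 is not None and i1 is None:
        i1 = i2
    s1 = int(steps[i1])
    if i2 is None:
        return StageBoundaries(s1, None, False)
    i2 = max(i1, i2)
    return StageBoundaries(s1, int(steps[i2]), True)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_frame(fa: FrameAnalysis,
                   params: ClassifierParams = ClassifierParams()) -> str:
    """Morphology label of a single analyzed frame (pure function)."""
    if fa.largest_frac < params.dispersed_frac:
        return "dispersed"
    if fa.n_a_cores == 0 and fa.n_s_cores == 0:
        return "dispersed"
    if (fa.n_a_cores > 0 and np.isfinite(fa.coverage)
            and fa.coverage < params.coverage_threshold):
        return "soluble-particle"
    if fa.n_a_cores >= 1 and fa.n_s_cores >= 1:
        return "multicore-multicompartment"
    if fa.n_a_cores >= 2:
        return "multicore"
    return "single-core"


def classify_morphology(frames: Sequence[FrameAnalysis],
                        params: ClassifierParams = ClassifierParams()
                        ) -> MorphologyResult:
    """Majority label over equilibrated frames, with an ambiguity flag.

    The result is flagged (never silently coerced) when the per-frame
    labels disagree substantially or the mean copolymer coverage falls
    inside the band around the soluble-particle threshold.
    """
    if not frames:
        raise ValueError("no frames to classify")
    labels = [classify_frame(fa, params) for fa in frames]
    counts = pd.Series(labels).value_counts()
    label = counts.index[0]
    agreement = counts.iloc[0] / len(labels)
    cov = np.array([fa.coverage for fa in frames], dtype=float)
    cov_mean = np.nanmean(cov) if np.isfinite(cov).any() else np.nan
    flagged = agreement < 0.75 or (
        np.isfinite(cov_mean)
        and abs(cov_mean - params.coverage_threshold) < params.coverage_flag_band)
    return MorphologyResult(label=label, flagged=bool(flagged),
                            votes=counts.to_dict())


# ---------------------------------------------------------------------------
# end-to-end drivers
# ---------------------------------------------------------------------------

@dataclass
class MorphologyReport:
    """Equilibrium summary of one simulated system."""

    label: str
    flagged: bool
    stages: StageBoundaries
    delta_eq: float
    phi_aggregate_eq: float
    phi_core_eq: float
    core_Xn_eq: float
    core_P_eq: float
    n_a_cores_eq: int
    n_s_cores_eq: int
    frames: pd.DataFrame


def summarize(df: pd.DataFrame, window: int = 10,
              params: ClassifierParams = ClassifierParams()) -> MorphologyReport:
    """Stage boundaries plus equilibrium averages over the final ``window``
    analyzed frames (frames whose asphericity is undefined because the
    aggregate transiently percolates are excluded from the delta average)."""
    stages = detect_stages(df["step"].to_numpy(), df["core_Xn"].to_numpy(),
                           df["Xn"].to_numpy(), window=window)
    tail = df.iloc[-window:]
    frames = [FrameAnalysis(**row) for row in
              tail.to_dict(orient="records")]
    cls = classify_morphology(frames, params)
    return MorphologyReport(
        label=cls.label, flagged=cls.flagged, stages=stages,
        delta_eq=(float(np.nanmean(tail["delta_largest"]))
                  if np.isfinite(tail["delta_largest"]).any() else float("nan")),
        phi_aggregate_eq=float(tail["phi_aggregate"].mean()),
        phi_core_eq=float(tail["phi_core"].mean()),
        core_Xn_eq=float(tail["core_Xn"].mean()),
        core_P_eq=float(tail["core_P"].mean()),
        n_a_cores_eq=int(round(tail["n_a_cores"].median())),
        n_s_cores_eq=int(round(tail["n_s_cores"].median())),
        frames=df)


def simulate_and_analyze(spec: SystemSpec, table: InteractionTable,
                         settings: IntegratorSettings,
                         params: ClassifierParams = ClassifierParams(),
                         analyze_every: int = 1,
                         window: int = 10) -> MorphologyReport:
    """Build, run and summarize one system."""
    topo, cfg = build_system(spec)
    traj = run(cfg, topo, table, settings)
    df = analyze_trajectory(traj, topo, params=params, every=analyze_every)
    return summarize(df, window=window, params=params)


def run_sweep(base_spec: SystemSpec, table: InteractionTable,
              parameter: str, grid: Sequence[float], seeds: Sequence[int],
              settings: IntegratorSettings,
              params: ClassifierParams = ClassifierParams(),
              analyze_every: int = 1) -> pd.DataFrame:
    """Morphology map versus one polymer-solvent repulsion parameter.

    ``parameter`` is "a_AW" or "a_SW"; every grid point is simulated for
    every seed (failed runs are recorded with an ``error`` entry and the
    sweep continues).  Returns one row per (value, seed) with the
    equilibrium label and the core statistics, segregation and shape
    metrics behind the sweep figures.
    """
    pair = {"a_AW": ("A", "W"), "a_SW": ("S", "W")}.get(parameter)
    if pair is None:
        raise ValueError(f"unknown sweep parameter: {parameter!r}")
    rows = []
    for value in grid:
        if not (25.0 <= value <= 200.0):
            raise ValueError(f"grid value {value} outside [25, 200]")
        tab = table.replace_pair(pair[0], pair[1], value)
        for seed in seeds:
            row = {"parameter": parameter, "value": float(value),
                   "seed": int(seed), "error": ""}
            try:
                rep = simulate_and_analyze(
                    base_spec.with_seed(seed), tab,
                    replace(settings, seed=int(seed)),
                    params=params, analyze_every=analyze_every)
                row.update(label=rep.label, flagged=rep.flagged,
                           equilibrated=rep.stages.equilibrated,
                           core_Xn=rep.core_Xn_eq, core_P=rep.core_P_eq,
                           phi_aggregate=rep.phi_aggregate_eq,
                           phi_core=rep.phi_core_eq, delta=rep.delta_eq,
                           n_a_cores=rep.n_a_cores_eq,
                           n_s_cores=rep.n_s_cores_eq)
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    columns = ["parameter", "value", "seed", "label", "flagged",
               "equilibrated", "core_Xn", "core_P", "phi_aggregate",
               "phi_core", "delta", "n_a_cores", "n_s_cores", "error"]
    df = pd.DataFrame(rows)
    for c in columns:
        if c not in df.columns:
            df[c] = pd.Series(dtype=float)
    return df[columns]
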