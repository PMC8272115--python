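"""Trajectory file formats: extended XYZ and LAMMPS-style text dumps.

Both formats are plain text, reduced units, orthorhombic box with origin 0
and half-open coordinates [0, L).  Extended XYZ frames carry the step and
box on the comment line (``Lattice=...`` / ``Step=...``); the dump dialect
uses the ``ITEM: TIMESTEP / NUMBER OF ATOMS / BOX BOUNDS pp pp pp /
ATOMS id type x y z`` layout, with 1-based atom ids and 1-based numeric
types in species order (A=1, S=2, W=3).  Readers restore bead order by id,
so shuffled dump files round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .builder import Configuration, Topology
from .interactions import SPECIES


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message carries the offending line."""


@dataclass
class Frame:
    step: int
    box_edge: float
    types: np.ndarray        # (N,) int8 species codes
    positions: np.ndarray    # (N, 3)
    velocities: np.ndarray | None = None

    def to_configuration(self) -> Configuration:
        vel = (self.velocities if self.velocities is not None
               else np.zeros_like(self.positions))
        return Configuration(positions=self.positions.copy(),
                             velocities=vel.copy(),
                             types=self.types.copy(),
                             box_edge=self.box_edge)


@dataclass
class TrajectoryFile:
    frames: list[Frame]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _format_of(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("xyz", "lammps"):
            raise ValueError(f"unknown trajectory format: {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".extxyz"):
        return "xyz"
    if suffix in (".dump", ".lammpstrj"):
        return "lammps"
    raise ValueError(f"cannot infer trajectory format from {path!r}; "
                     "pass fmt='xyz' or 'lammps'")


def write_frames(path, frames, fmt: str | None = None,
                 with_velocities: bool = False) -> None:
    """Write frames (``Frame`` objects or (step, Configuration) pairs)."""
    fmt = _format_of(path, fmt)
    norm: list[Frame] = []
    for fr in frames:
        if isinstance(fr, Frame):
            norm.append(fr)
        else:
            step, cfg = fr
            norm.append(Frame(step=step, box_edge=cfg.box_edge,
                              types=cfg.types, positions=cfg.positions,
                              velocities=cfg.velocities))
    with open(path, "w") as fh:
        for fr in norm:
            if fmt == "xyz":
                _write_xyz_frame(fh, fr, with_velocities)
            else:
                _write_dump_frame(fh, fr, with_velocities)


def _write_xyz_frame(fh, fr: Frame, with_vel: bool) -> None:
    L = fr.box_edge
    props = "species:S:1:pos:R:3" + (":vel:R:3" if with_vel else "")
    fh.write(f"{len(fr.positions)}\n")
    fh.write(f'Lattice="{L:.8f} 0.0 0.0 0.0 {L:.8f} 0.0 0.0 0.0 {L:.8f}" '
             f"Properties={props} Step={fr.step}\n")
    for i in range(len(fr.positions)):
        x, y, z = fr.positions[i]
        line = f"{SPECIES[fr.types[i]]} {x:.8f} {y:.8f} {z:.8f}"
        if with_vel:
            vx, vy, vz = fr.velocities[i]
            line += f" {vx:.8f} {vy:.8f} {vz:.8f}"
        fh.write(line + "\n")


def _write_dump_frame(fh, fr: Frame, with_vel: bool) -> None:
    L = fr.box_edge
    cols = "id type x y z" + (" vx vy vz" if with_vel else "")
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{fr.step}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{len(fr.positions)}\n")
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for _ in range(3):
        fh.write(f"0.0 {L:.8f}\n")
    fh.write(f"ITEM: ATOMS {cols}\n")
    for i in range(len(fr.positions)):
        x, y, z = fr.positions[i]
        line = f"{i + 1} {fr.types[i] + 1} {x:.8f} {y:.8f} {z:.8f}"
        if with_vel:
            vx, vy, vz = fr.velocities[i]
            line += f" {vx:.8f} {vy:.8f} {vz:.8f}"
        fh.write(line + "\n")


def read_frames(path, fmt: str | None = None) -> TrajectoryFile:
    """Read all frames of a trajectory file."""
    fmt = _format_of(path, fmt)
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = (_read_xyz(lines) if fmt == "xyz" else _read_dump(lines))
    return TrajectoryFile(frames=frames)


def _read_xyz(lines: list[str]) -> list[Frame]:
    frames: list[Frame] = []
    ln = 0
    code = {s: i for i, s in enumerate(SPECIES)}
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {ln + 1}: expected atom count, got {lines[ln]!r}") from exc
        if ln + 1 >= len(lines):
            raise TrajectoryParseError(
                f"frame {len(frames)}: truncated after the count line")
        comment = lines[ln + 1]
        box = _parse_lattice(comment, ln + 2)
        step = 0
        for tok in comment.split():
            if tok.startswith("Step="):
                step = int(tok[5:])
        has_vel = ":vel:" in comment
        if ln + 2 + n > len(lines):
            raise TrajectoryParseError(
                f"frame {len(frames)}: truncated (expected {n} atom lines)")
        types = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3)) if has_vel else None
        for k in range(n):
            parts = lines[ln + 2 + k].split()
            want = 7 if has_vel else 4
            if len(parts) < want or parts[0] not in code:
                raise TrajectoryParseError(
                    f"line {ln + 3 + k}: malformed atom record "
                    f"{lines[ln + 2 + k]!r}")
            types[k] = code[parts[0]]
            pos[k] = [float(v) for v in parts[1:4]]
            if has_vel:
                vel[k] = [float(v) for v in parts[4:7]]
        frames.append(Frame(step=step, box_edge=box, types=types,
                            positions=pos, velocities=vel))
        ln += 2 + n
    return frames


def _parse_lattice(comment: str, lineno: int) -> float:
    key = 'Lattice="'
    start = comment.find(key)
    if start < 0:
        raise TrajectoryParseError(f"line {lineno}: missing Lattice entry")
    end = comment.find('"', start + len(key))
    if end < 0:
        raise TrajectoryParseError(f"line {lineno}: unterminated Lattice")
    vals = [float(v) for v in comment[start + len(key):end].split()]
    if len(vals) != 9:
        raise TrajectoryParseError(f"line {lineno}: Lattice needs 9 numbers")
    return vals[0]


def _read_dump(lines: list[str]) -> list[Frame]:
    frames: list[Frame] = []
    ln = 0

    def expect(tag: str) -> None:
        nonlocal ln
        if ln >= len(lines):
            raise TrajectoryParseError(
                f"frame {len(frames)}: truncated before '{tag}'")
        if not lines[ln].startswith(tag):
            raise TrajectoryParseError(
                f"line {ln + 1}: expected '{tag}', got {lines[ln]!r}")
        ln += 1

    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        expect("ITEM: TIMESTEP")
        step = int(lines[ln]); ln += 1
        expect("ITEM: NUMBER OF ATOMS")
        n = int(lines[ln]); ln += 1
        expect("ITEM: BOX BOUNDS")
        if ln + 3 > len(lines):
            raise TrajectoryParseError(
                f"frame {len(frames)}: truncated box bounds")
        lo, hi = (float(v) for v in lines[ln].split()[:2])
        box = hi - lo
        ln += 3
        expect("ITEM: ATOMS")
        cols = lines[ln - 1].split()[2:]
        try:
            ic = {name: cols.index(name) for name in ("id", "type", "x", "y", "z")}
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {ln}: dump must carry id type x y z columns") from exc
        has_vel = all(c in cols for c in ("vx", "vy", "vz"))
        if ln + n > len(lines):
            raise TrajectoryParseError(
                f"frame {len(frames)}: truncated (expected {n} atom lines)")
        types = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3)) if has_vel else None
        seen = np.zeros(n, dtype=bool)
        for k in range(n):
            parts = lines[ln + k].split()
            if len(parts) < len(cols):
                raise TrajectoryParseError(
                    f"line {ln + k + 1}: malformed atom record")
            idx = int(parts[ic["id"]]) - 1
            if not (0 <= idx < n) or seen[idx]:
                raise TrajectoryParseError(
                    f"line {ln + k + 1}: bad or duplicate atom id "
                    f"{parts[ic['id']]}")
            seen[idx] = True
            types[idx] = int(parts[ic["type"]]) - 1
            pos[idx] = [float(parts[ic[c]]) for c in ("x", "y", "z")]
            if has_vel:
                vel[idx] = [float(parts[cols.index(c)]) for c in
                            ("vx", "vy", "vz")]
        frames.append(Frame(step=step, box_edge=box, types=types,
                            positions=pos, velocities=vel))
        ln += n
    return frames


# ---------------------------------------------------------------------------
# bead-label sidecars (molecule species per bead, for analysis)
# ---------------------------------------------------------------------------

def write_labels(path, topo: Topology, extra: dict | None = None) -> None:
    """JSON sidecar with per-bead molecule-species labels and chain counts.

    Trajectory formats carry only bead types (A/S/W); the analysis stack
    additionally needs to know which molecule species each bead belongs to
    (e.g. homopolymer A vs copolymer A)."""
    payload = {
        "mol_species": topo.mol_species.astype(int).tolist(),
        "chain_counts": topo.chain_counts,
        "n_bonds": int(topo.n_bonds),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_labels(path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    return np.asarray(payload["mol_species"], dtype=np.int8)
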