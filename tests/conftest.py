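"""Shared fixtures: small systems, reference tables, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import dpdmc


@pytest.fixture(scope="session")
def reference_table() -> dpdmc.InteractionTable:
    return dpdmc.InteractionTable.reference()


@pytest.fixture()
def small_system():
    """A small chain system (box 10, 3000 beads).

    The random-overlap start with a_AW = 115 produces a short violent
    transient (T ~ 3 for ~100 steps); the box must be large enough that
    transient bond excursions stay below the half-box minimum-image
    limit, which holds comfortably from edge 10 upward."""
    spec = dpdmc.SystemSpec(box_edge=10.0, seed=7)
    topo, cfg = dpdmc.build_system(spec)
    return spec, topo, cfg


def brute_force_pairs(positions: np.ndarray, box: float,
                      cutoff: float) -> set[tuple[int, int]]:
    """O(N^2) minimum-image pair enumeration (independent oracle)."""
    n = len(positions)
    out = set()
    for i in range(n):
        d = positions[i + 1:] - positions[i]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(axis=1))
        for k in np.flatnonzero(r < cutoff):
            out.add((i, i + 1 + int(k)))
    return out


def brute_force_clusters(positions: np.ndarray, box: float,
                         cutoff: float) -> list[frozenset[int]]:
    """Transitive closure of the proximity relation by plain BFS."""
    n = len(positions)
    pairs = brute_force_pairs(positions, box, cutoff)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    seen = [False] * n
    clusters = []
    for s in range(n):
        if seen[s]:
            continue
        comp = {s}
        seen[s] = True
        stack = [s]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    comp.add(j)
                    stack.append(j)
        clusters.append(frozenset(comp))
    return clusters
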