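"""DPD interaction parameters and their Flory-Huggins correspondence.

In dissipative particle dynamics the conservative force between two beads is
a soft, linearly decaying repulsion ``F_C = a_ij (1 - r/R_c) e_ij`` for
``r < R_c``.  The amplitude ``a_ij`` encodes the chemistry.  Like-species
amplitudes follow from matching the compressibility of water at the chosen
reduced bead density, ``a_ii = 75 / rho``, and cross-species amplitudes map
linearly onto the Flory-Huggins ``chi`` parameter at ``rho = 3``:

    a_ij - a_ii = 3.27 chi_ij

The three bead species used throughout are A (solvophobic), S (solvophilic)
and W (solvent).  The reference parameter set is the study's Table of
repulsion amplitudes: a_AA = a_SS = a_WW = 25, a_AS = 72, a_SW = 30,
a_AW = 115, with a harmonic bond constant C = 4 and the standard DPD
thermostat pair gamma = 4.5, sigma = 3 (sigma^2 = 2 gamma kBT at kBT = 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

#: Proportionality constant between (a_ij - a_ii) and chi at rho = 3.
CHI_COEFF = 3.27

#: Bead species, in the fixed order used for type codes everywhere.
SPECIES = ("A", "S", "W")

TYPE_A, TYPE_S, TYPE_W = 0, 1, 2


def aii_from_density(rho: float) -> float:
    """Like-species repulsion amplitude from the reduced bead density.

    ``a_ii = 75 / rho`` reproduces the compressibility of water for the soft
    DPD fluid; at the standard density rho = 3 this gives a_ii = 25.

    Parameters
    ----------
    rho : float
        Reduced number density (beads per R_c^3).  Must be positive.
    """
    if rho <= 0:
        raise ValueError(f"density must be positive, got {rho}")
    return 75.0 / rho


def aij_from_chi(chi: float, a_ii: float = 25.0) -> float:
    """Cross repulsion amplitude for a given Flory-Huggins chi parameter."""
    if a_ii <= 0:
        raise ValueError(f"a_ii must be positive, got {a_ii}")
    return a_ii + CHI_COEFF * chi


def chi_from_aij(a_ij: float, a_ii: float = 25.0) -> float:
    """Flory-Huggins chi parameter implied by a cross repulsion amplitude.

    Exact inverse of :func:`aij_from_chi`.
    """
    return (a_ij - a_ii) / CHI_COEFF


def _pair_key(si: str, sj: str) -> str:
    """Canonical (order-independent) key for a species pair."""
    return "-".join(sorted((si, sj)))


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric pairwise repulsion matrix plus thermostat and bond constants.

    Attributes
    ----------
    a : (3, 3) ndarray
        Maximum-repulsion amplitudes ``a_ij`` indexed by species code
        (A=0, S=1, W=2), in reduced energy per R_c.
    gamma : float
        Friction coefficient of the dissipative force.
    sigma : float
        Noise amplitude of the random force; must satisfy
        ``sigma^2 = 2 gamma kBT`` (fluctuation-dissipation).
    r_cut : float
        Interaction cutoff R_c (1 in reduced units).
    spring_c : float
        Harmonic bond constant C for consecutive chain beads.
    """

    a: np.ndarray
    gamma: float = 4.5
    sigma: float = 3.0
    r_cut: float = 1.0
    spring_c: float = 4.0
    kBT: float = 1.0
    species: tuple[str, ...] = field(default=SPECIES, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (len(self.species),) * 2:
            raise ValueError(f"a must be {len(self.species)}x{len(self.species)}, got {a.shape}")
        if not np.allclose(a, a.T):
            raise ValueError("repulsion matrix must be symmetric")
        if not np.all(a > 0):
            raise ValueError("all repulsion amplitudes must be positive")
        if not math.isclose(self.sigma**2, 2.0 * self.gamma * self.kBT, rel_tol=1e-12):
            raise ValueError(
                f"fluctuation-dissipation violated: sigma^2={self.sigma**2} "
                f"!= 2*gamma*kBT={2 * self.gamma * self.kBT}"
            )
        object.__setattr__(self, "a", a)

    # -- constructors -----------------------------------------------------

    @classmethod
    def reference(cls) -> "InteractionTable":
        """The study's reference parameter set (Table of a_ij values)."""
        return cls.from_pairs(
            {"A-A": 25.0, "S-S": 25.0, "W-W": 25.0,
             "A-S": 72.0, "S-W": 30.0, "A-W": 115.0}
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: Mapping[str, float],
        *,
        gamma: float = 4.5,
        r_cut: float = 1.0,
        spring_c: float = 4.0,
        kBT: float = 1.0,
    ) -> "InteractionTable":
        """Build a table from a mapping keyed by unordered species pairs.

        Keys are "X-Y" with X, Y in {A, S, W}; "A-W" and "W-A" are the same
        entry.  Every pair (including like pairs) must be present exactly once.
        """
        a = np.full((3, 3), np.nan)
        seen = set()
        for key, val in pairs.items():
            parts = key.split("-")
            if len(parts) != 2 or any(p not in SPECIES for p in parts):
                raise ValueError(f"bad species pair key: {key!r}")
            canon = _pair_key(*parts)
            if canon in seen:
                raise ValueError(f"duplicate entry for pair {canon}")
            seen.add(canon)
            i, j = SPECIES.index(parts[0]), SPECIES.index(parts[1])
            a[i, j] = a[j, i] = float(val)
        if np.isnan(a).any():
            missing = [
                _pair_key(SPECIES[i], SPECIES[j])
                for i in range(3) for j in range(i, 3) if np.isnan(a[i, j])
            ]
            raise ValueError(f"missing pair entries: {missing}")
        sigma = math.sqrt(2.0 * gamma * kBT)
        return cls(a=a, gamma=gamma, sigma=sigma, r_cut=r_cut,
                   spring_c=spring_c, kBT=kBT)

    def replace_pair(self, si: str, sj: str, value: float) -> "InteractionTable":
        """Return a new table with one (symmetric) entry changed."""
        a = self.a.copy()
        i, j = self.species.index(si), self.species.index(sj)
        a[i, j] = a[j, i] = float(value)
        return InteractionTable(a=a, gamma=self.gamma, sigma=self.sigma,
                                r_cut=self.r_cut, spring_c=self.spring_c,
                                kBT=self.kBT, species=self.species)

    # -- accessors --------------------------------------------------------

    def pair(self, si: str, sj: str) -> float:
        return float(self.a[self.species.index(si), self.species.index(sj)])

    def chi(self, si: str, sj: str) -> float:
        """chi parameter implied by this table for a species pair.

        Uses the like-like amplitude of the first species as a_ii (all like
        amplitudes are equal in the reference set).
        """
        a_ii = self.pair(si, si)
        return chi_from_aij(self.pair(si, sj), a_ii)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        pairs = {
            _pair_key(self.species[i], self.species[j]): float(self.a[i, j])
            for i in range(3) for j in range(i, 3)
        }
        return {
            "pairs": pairs,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "r_cut": self.r_cut,
            "spring_c": self.spring_c,
            "kBT": self.kBT,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InteractionTable":
        table = cls.from_pairs(
            d["pairs"],
            gamma=float(d.get("gamma", 4.5)),
            r_cut=float(d.get("r_cut", 1.0)),
            spring_c=float(d.get("spring_c", 4.0)),
            kBT=float(d.get("kBT", 1.0)),
        )
        if "sigma" in d and not math.isclose(float(d["sigma"]), table.sigma,
                                             rel_tol=1e-9):
            raise ValueError(
                f"sigma={d['sigma']} inconsistent with sqrt(2*gamma*kBT)={table.sigma}"
            )
        return table

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "InteractionTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "InteractionTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
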