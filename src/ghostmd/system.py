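"""Periodic molecular configurations and minimum-image geometry helpers.

Only orthorhombic cells are supported; all coordinates are Cartesian Å and
wrapped to [0, L) when requested.  The minimum-image convention is applied
throughout, which requires every interaction cutoff to stay below half the
smallest box length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ATOMIC_MASSES, ELEMENT_OF


class GhostMDError(RuntimeError):
    """Base error for physically invalid states or failed operations."""


def minimum_image(disp: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Map displacement vectors into the minimum-image convention.

    Parameters
    ----------
    disp : array, shape (..., 3)
    cell : array, shape (3,), orthorhombic box lengths (Å).
    """
    return disp - cell * np.round(disp / cell)


def wrap_positions(pos: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Wrap positions into [0, L) per axis.

    np.mod(-ε, L) rounds to exactly L for tiny negative ε; fold that back.
    """
    out = np.mod(pos, cell)
    return np.where(out >= cell, out - cell, out)


@dataclass
class Configuration:
    """One snapshot of the nuclear degrees of freedom.

    species carries the isotope label ('O', 'H', 'D'); the ghost particle is
    never part of a Configuration — it only exists transiently inside the toy
    reference calculations.
    """

    species: np.ndarray          # (N,) unicode labels
    positions: np.ndarray        # (N, 3) Å
    cell: np.ndarray             # (3,) Å, orthorhombic
    molecule_index: np.ndarray   # (N,) int

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype="U2")
        self.positions = np.asarray(self.positions, dtype=float)
        self.cell = np.asarray(self.cell, dtype=float)
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)

    # -- derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if self.n_atoms else 0

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.species])

    @property
    def elements(self) -> np.ndarray:
        """Chemical elements ('H'/'O'), collapsing the D isotope onto H."""
        return np.array([ELEMENT_OF.get(s, s) for s in self.species], dtype="U2")

    @property
    def volume(self) -> float:
        return float(np.prod(self.cell))

    def is_element(self, element: str) -> np.ndarray:
        return self.elements == element

    def copy(self) -> "Configuration":
        return Configuration(self.species.copy(), self.positions.copy(),
                             self.cell.copy(), self.molecule_index.copy())

    def with_positions(self, pos: np.ndarray) -> "Configuration":
        return Configuration(self.species, np.asarray(pos, float),
                             self.cell, self.molecule_index)

    # -- validation ----------------------------------------------------
    def validate(self, max_cutoff: float | None = None) -> None:
        """Check structural invariants; raise GhostMDError on violation."""
        if not np.all(np.isfinite(self.positions)):
            raise GhostMDError("non-finite positions")
        if self.positions.shape != (self.n_atoms, 3):
            raise GhostMDError("positions shape mismatch")
        if np.any(self.cell <= 0):
            raise GhostMDError("cell lengths must be positive")
        for m in range(self.n_molecules):
            sp = self.species[self.molecule_index == m]
            if sorted(ELEMENT_OF[s] for s in sp) != ["H", "H", "O"]:
                raise GhostMDError(
                    f"molecule {m} is not one O with two H/D sites: {sp}")
        if max_cutoff is not None and np.min(self.cell) < 2.0 * max_cutoff:
            raise GhostMDError(
                f"cell {self.cell} too small for cutoff {max_cutoff} "
                "(minimum-image requires L > 2 r_c)")

    def distances_to(self, point: np.ndarray) -> np.ndarray:
        """Minimum-image distances from every atom to a point."""
        d = minimum_image(self.positions - np.asarray(point), self.cell)
        return np.linalg.norm(d, axis=-1)
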