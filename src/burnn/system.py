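"""System topology, configurations, periodic geometry and three-region partitioning.

The buffer-region scheme splits the simulation box into an inner region I
(the molecules of interest, fixed), a buffer region Buf (solvent molecules
within a cutoff of I, reassigned adaptively), and an outer region O (the
rest).  Units throughout the package: nm, ps, kJ/mol, u, e, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "SystemTopology",
    "Configuration",
    "RegionAssignment",
    "minimum_image_vector",
    "minimum_image_displacements",
    "assign_regions",
    "InvalidConfigurationError",
]


class InvalidConfigurationError(ValueError):
    """Raised for non-finite coordinates, empty inner regions and the like."""


@dataclass(frozen=True)
class Atom:
    """A point particle with MM parameters and a dual-topology tag.

    ``dual_state`` is ``"A"`` or ``"B"`` for atoms belonging to one of the
    two alchemical end-state molecules and ``"common"`` for everything else.
    """

    id: int
    element: str
    mass: float            # u
    charge: float          # e
    lj_sigma: float        # nm
    lj_epsilon: float      # kJ/mol
    molecule_id: int
    dual_state: str = "common"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.id}: mass must be positive")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.id}: LJ parameters must be non-negative")
        if self.dual_state not in ("A", "B", "common"):
            raise ValueError(f"atom {self.id}: bad dual_state {self.dual_state!r}")


@dataclass
class SystemTopology:
    """Atoms plus bonded terms, constraints, restraints and region metadata.

    bonds:       (i, j, r0 [nm], k [kJ/mol/nm^2]) harmonic bonds
    angles:      (i, j, k, theta0 [rad], k_theta [kJ/mol/rad^2])
    constraints: (i, j, d [nm]) holonomic bond-length constraints (SHAKE)
    restraints:  (i, j, d0 [nm], kr [kJ/mol/nm^2]) harmonic distance restraints
    exclusions:  unordered atom-index pairs excluded from nonbonded sums
    inner_molecule_ids: the molecules that form the inner region I
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)
    restraints: list[tuple[int, int, float, float]] = field(default_factory=list)
    inner_molecule_ids: set[int] = field(default_factory=set)
    exclusions: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.exclusions = {(min(i, j), max(i, j)) for i, j in self.exclusions}
        self.validate()
        self._rebuild_arrays()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        for i, a in enumerate(self.atoms):
            if a.id != i:
                raise ValueError("atom ids must be 0..n-1 in order")
        for rec in self.bonds + [c + (0.0,) for c in self.constraints]:
            i, j = rec[0], rec[1]
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond/constraint indices out of range: {(i, j)}")
        for i, j, k, _, _ in self.angles:
            if not all(0 <= x < n for x in (i, j, k)):
                raise ValueError("angle indices out of range")
        for i, j, _, _ in self.restraints:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("restraint indices out of range")
        mol_states: dict[int, set[str]] = {}
        for a in self.atoms:
            mol_states.setdefault(a.molecule_id, set()).add(a.dual_state)
        for mid, states in mol_states.items():
            if "A" in states and "B" in states:
                raise ValueError(f"molecule {mid} mixes dual states A and B")

    # -- cached arrays ---------------------------------------------------
    def _rebuild_arrays(self) -> None:
        self.masses = np.array([a.mass for a in self.atoms])
        self.charges = np.array([a.charge for a in self.atoms])
        self.sigmas = np.array([a.lj_sigma for a in self.atoms])
        self.epsilons = np.array([a.lj_epsilon for a in self.atoms])
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms])
        n = len(self.atoms)
        self.exclusion_keys = np.array(
            sorted(i * n + j for i, j in self.exclusions), dtype=np.int64
        )
        self._pair_cache: dict = {}

    def excluded_mask(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Vectorized exclusion lookup for pair index arrays."""
        if len(self.exclusion_keys) == 0:
            return np.zeros(len(i), dtype=bool)
        n = len(self.atoms)
        key = np.minimum(i, j) * n + np.maximum(i, j)
        return np.isin(key, self.exclusion_keys)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def molecule_atom_indices(self, molecule_ids: Iterable[int]) -> np.ndarray:
        mids = set(molecule_ids)
        return np.array(
            [a.id for a in self.atoms if a.molecule_id in mids], dtype=int
        )

    def all_molecule_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.molecule_id, None)
        return list(seen)

    def dual_state_molecules(self, state: str) -> set[int]:
        return {a.molecule_id for a in self.atoms if a.dual_state == state}

    def is_excluded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.exclusions


@dataclass
class Configuration:
    """Positions (and optionally velocities) in an orthorhombic periodic box."""

    positions: np.ndarray          # (n, 3) nm
    box: np.ndarray                # (3,) nm
    velocities: np.ndarray | None = None   # (n, 3) nm/ps
    time: float = 0.0              # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InvalidConfigurationError("box must be three positive lengths")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidConfigurationError("non-finite positions")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)

    def copy(self) -> "Configuration":
        return Configuration(
            positions=self.positions.copy(),
            box=self.box.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            time=self.time,
        )


@dataclass(frozen=True)
class RegionAssignment:
    """Per-molecule labels I / Buf / O at one time step."""

    inner: frozenset[int]
    buffer: frozenset[int]
    outer: frozenset[int]
    cutoff: float

    def __post_init__(self) -> None:
        if self.inner & self.buffer or self.inner & self.outer or self.buffer & self.outer:
            raise ValueError("regions must be disjoint")


def minimum_image_vector(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement from ``p1`` to ``p2`` in an orthorhombic box.

    Each component of the result lies in [-L/2, L/2).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2)) and np.all(np.isfinite(box))):
        raise InvalidConfigurationError("non-finite input to minimum_image_vector")
    if np.any(box <= 0):
        raise InvalidConfigurationError("box lengths must be positive")
    d = p2 - p1
    d -= box * np.floor(d / box + 0.5)
    return d


def minimum_image_displacements(dvecs: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Vectorized minimum-image wrap of raw displacement vectors (…, 3)."""
    return dvecs - box * np.floor(dvecs / box + 0.5)


def assign_regions(
    config: Configuration, topo: SystemTopology, cutoff: float
) -> RegionAssignment:
    """Partition molecules into inner / buffer / outer regions.

    A non-inner molecule is in the buffer iff the minimum-image distance
    between any of its atoms and any inner-region atom is at most ``cutoff``
    (minimum atom-atom distance criterion, applied per molecule so molecules
    are never split across regions); otherwise it is outer.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not topo.inner_molecule_ids:
        raise InvalidConfigurationError("system has no inner molecules")

    inner_idx = topo.molecule_atom_indices(topo.inner_molecule_ids)
    inner_pos = config.positions[inner_idx]
    buffer: set[int] = set()
    outer: set[int] = set()
    for mid in topo.all_molecule_ids():
        if mid in topo.inner_molecule_ids:
            continue
        idx = topo.molecule_atom_indices([mid])
        d = config.positions[idx][:, None, :] - inner_pos[None, :, :]
        d = minimum_image_displacements(d, config.box)
        if np.min(np.linalg.norm(d, axis=-1)) <= cutoff:
            buffer.add(mid)
        else:
            outer.add(mid)
    return RegionAssignment(
        inner=frozenset(topo.inner_molecule_ids),
        buffer=frozenset(buffer),
        outer=frozenset(outer),
        cutoff=cutoff,
    )
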