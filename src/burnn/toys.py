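"""Built-in toy systems and training-data generation.

The standard fixture emulates a small-solute solvation setup: a
dual-topology solute pair at the box center — a 3-site polar solute
("methanol-like": united CH3, O, H) as end state A and a single apolar
united-atom site ("methane-like") as end state B — restrained to stay
aligned, surrounded by rigid 3-site water handled entirely through SHAKE
constraints.

Training data for the delta models are classical MD snapshots labeled with
the reference engine, optionally augmented with every step of a
steepest-descent geometry optimization of the inner+buffer cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .mlp import DeltaRecord
from .descriptors import DescriptorSpec
from .forcefield import cluster_delta_baseline
from .reference import ReferenceEngine, delta_reference, reference_energy, unwrap_subset
from .system import Atom, Configuration, SystemTopology, assign_regions

__all__ = [
    "ToySystemSpec",
    "build_toy_system",
    "generate_training_data",
    "minimize_cluster",
    "water_geometry",
]

# rigid 3-site water (SPC-like)
WATER = {
    "elements": ("OW", "HW", "HW"),
    "masses": (15.9994, 1.008, 1.008),
    "charges": (-0.82, 0.41, 0.41),
    "sigmas": (0.3166, 0.0, 0.0),
    "epsilons": (0.650, 0.0, 0.0),
    "r_oh": 0.1,
    "r_hh": 0.16330,
}

SOLUTE_A = {  # methanol-like: united CH3, O, hydroxyl H
    "elements": ("C", "O", "H"),
    "masses": (15.035, 15.9994, 1.008),
    "charges": (0.176, -0.574, 0.398),
    "sigmas": (0.3748, 0.2955, 0.0),
    "epsilons": (0.8672, 0.8492, 0.0),
    "bonds": [(0, 1, 0.1435, 320000.0), (1, 2, 0.1000, 350000.0)],
    "angles": [(0, 1, 2, np.radians(109.5), 450.0)],
}

SOLUTE_B = {  # methane-like united atom
    "elements": ("M",),
    "masses": (16.043,),
    "charges": (0.0,),
    "sigmas": (0.3730,),
    "epsilons": (1.2301,),
    "bonds": [],
    "angles": [],
}


@dataclass
class ToySystemSpec:
    n_solvent: int = 50
    box: float = 2.1                    # nm, cubic
    solute_A: str = "methanol_like"
    solute_B: str = "methane_like"
    restraint_d0: float = 0.0           # nm, solute-solute alignment restraint
    restraint_k: float = 5000.0         # kJ/mol/nm^2
    min_dist: float = 0.25              # nm, placement clash tolerance
    constrain_solute_bonds: bool = False


def water_geometry() -> np.ndarray:
    """Local coordinates of one rigid water (O at origin)."""
    r, rhh = WATER["r_oh"], WATER["r_hh"]
    half = np.arcsin(0.5 * rhh / r)
    h1 = r * np.array([np.sin(half), np.cos(half), 0.0])
    h2 = r * np.array([-np.sin(half), np.cos(half), 0.0])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def build_toy_system(
    spec: ToySystemSpec, seed: int = 0
) -> tuple[SystemTopology, Configuration]:
    """Construct the dual-topology solute pair in a water box.

    Deterministic per seed.  Raises if solvent placement cannot satisfy the
    clash tolerance within a bounded number of retries.
    """
    rng = np.random.default_rng(seed)
    L = spec.box
    center = np.array([L / 2, L / 2, L / 2])

    atoms: list[Atom] = []
    bonds, angles, constraints, restraints = [], [], [], []
    exclusions: set[tuple[int, int]] = set()
    positions: list[np.ndarray] = []

    # solute A at the box center
    a_local = np.array([[0.0, 0.0, 0.0], [0.1435, 0.0, 0.0], [0.1770, 0.0943, 0.0]])
    aid = 0
    for k, el in enumerate(SOLUTE_A["elements"]):
        atoms.append(Atom(aid, el, SOLUTE_A["masses"][k], SOLUTE_A["charges"][k],
                          SOLUTE_A["sigmas"][k], SOLUTE_A["epsilons"][k],
                          molecule_id=0, dual_state="A"))
        positions.append(center + a_local[k])
        aid += 1
    for i, j, r0, k in SOLUTE_A["bonds"]:
        if spec.constrain_solute_bonds:
            constraints.append((i, j, r0))
        else:
            bonds.append((i, j, r0, k))
    angles.extend(SOLUTE_A["angles"])

    # solute B on top of A's first site (dual topology: no A<->B interactions)
    b_start = aid
    for k, el in enumerate(SOLUTE_B["elements"]):
        atoms.append(Atom(aid, el, SOLUTE_B["masses"][k], SOLUTE_B["charges"][k],
                          SOLUTE_B["sigmas"][k], SOLUTE_B["epsilons"][k],
                          molecule_id=1, dual_state="B"))
        positions.append(center + np.array([0.02 * k + 0.01, 0.01, 0.0]))
        aid += 1
    restraints.append((0, b_start, spec.restraint_d0, spec.restraint_k))
    a_idx = list(range(b_start))
    b_idx = list(range(b_start, aid))
    for i in a_idx:
        for j in b_idx:
            exclusions.add((i, j))
    for i, j in combinations(a_idx, 2):
        exclusions.add((i, j))

    # solvent placement by rejection sampling
    wg = water_geometry()
    placed = np.array(positions)
    for w in range(spec.n_solvent):
        ok = False
        for _ in range(2000):
            origin = rng.uniform(0.0, L, size=3)
            pos_w = origin + wg @ _random_rotation(rng).T
            d = placed[None, :, :] - pos_w[:, None, :]
            d -= L * np.floor(d / L + 0.5)
            if np.min(np.linalg.norm(d, axis=-1)) >= spec.min_dist:
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place solvent molecule {w} without clashes"
            )
        mol_id = 2 + w
        base = aid
        for k, el in enumerate(WATER["elements"]):
            atoms.append(Atom(aid, el, WATER["masses"][k], WATER["charges"][k],
                              WATER["sigmas"][k], WATER["epsilons"][k],
                              molecule_id=mol_id))
            positions.append(pos_w[k])
            aid += 1
        constraints.append((base, base + 1, WATER["r_oh"]))
        constraints.append((base, base + 2, WATER["r_oh"]))
        constraints.append((base + 1, base + 2, WATER["r_hh"]))
        for i, j in combinations(range(base, base + 3), 2):
            exclusions.add((i, j))
        placed = np.array(positions)

    topo = SystemTopology(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        constraints=constraints,
        restraints=restraints,
        inner_molecule_ids={0, 1},
        exclusions=exclusions,
    )
    config = Configuration(positions=np.array(positions), box=np.array([L, L, L]))
    return topo, config


# ---------------------------------------------------------------------------
# Training data generation
# ---------------------------------------------------------------------------

def minimize_cluster(
    config: Configuration,
    topo: SystemTopology,
    subset: list[int],
    engine: ReferenceEngine,
    max_steps: int = 20,
    step0: float = 1e-4,
) -> list[Configuration]:
    """Steepest-descent minimization of the reference energy of a cluster.

    Only the subset atoms move.  Backtracking guarantees the sequence of
    accepted configurations has monotonically non-increasing reference
    energies; every accepted step is returned (the augmentation records).
    """
    out: list[Configuration] = []
    cfg = config.copy()
    ev = reference_energy(cfg, subset, engine)
    e, f = ev.energy, ev.forces
    step = 2e-3  # nm, trust-radius-style displacement of the largest force
    for _ in range(max_steps):
        fmax = float(np.abs(f).max())
        if fmax < 1e-8:
            break
        accepted = False
        while step > 1e-7:
            trial = cfg.copy()
            trial.positions[subset] = cfg.positions[subset] + step / fmax * f
            ev_t = reference_energy(trial, subset, engine)
            if ev_t.energy <= e:
                cfg, e, f = trial, ev_t.energy, ev_t.forces
                out.append(cfg.copy())
                step = min(step * 1.5, 5e-3)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return out


def generate_training_data(
    topo: SystemTopology,
    frames: list[Configuration],
    engine: ReferenceEngine,
    inner_molecules: set[int],
    descriptor: DescriptorSpec,
    buffer_cutoff: float = 0.5,
    include_minimization: bool = False,
    minimize_every: int = 10,
    max_min_steps: int = 8,
    region_molecules: set[int] | None = None,
) -> list[DeltaRecord]:
    """Label MD frames with delta-reference ground truth.

    Every frame yields one record (provenance ``md_snapshot``); when
    ``include_minimization`` is set, every ``minimize_every``-th frame is
    additionally geometry-optimized on the reference surface and each
    minimization step is appended (provenance ``minimization_step``).

    ``region_molecules`` selects the molecules the buffer is measured from;
    for dual-topology models this must be the whole inner region (both end
    states), matching the convention of the perturbed Hamiltonian, while the
    delta itself is evaluated for ``inner_molecules`` only.
    """
    inner_idx = topo.molecule_atom_indices(inner_molecules)
    saved_inner = topo.inner_molecule_ids
    if region_molecules is None:
        region_molecules = set(inner_molecules)
    records: list[DeltaRecord] = []

    def label(cfg: Configuration, provenance: str) -> DeltaRecord:
        topo.inner_molecule_ids = set(region_molecules)
        try:
            regions = assign_regions(cfg, topo, buffer_cutoff)
        finally:
            topo.inner_molecule_ids = saved_inner
        buf_idx = topo.molecule_atom_indices(regions.buffer)
        x, J, subset = descriptor.features_jacobian(cfg, topo, inner_idx, buf_idx)
        ev = delta_reference(cfg, inner_idx.tolist(), buf_idx.tolist(), engine)
        e_base, f_base = cluster_delta_baseline(cfg, topo, inner_idx, buf_idx)
        # force-matching rows: all inner atoms plus a deterministic spread of
        # buffer atoms; targets are residual gradients d(delta - baseline)/dx
        m = len(subset)
        ni = len(inner_idx)
        sel = list(range(ni))
        if m > ni:
            n_buf_rows = min(4, m - ni)
            sel += [
                ni + int(round(k * (m - ni - 1) / max(1, n_buf_rows - 1)))
                for k in range(n_buf_rows)
            ]
        sel = sorted(set(sel))
        force_rows = J[:, sel, :].reshape(len(x), -1).T.astype(np.float32)
        force_targets = (f_base - ev.forces)[sel].ravel()
        return DeltaRecord(
            descriptor=x,
            delta_energy=ev.energy,
            forces=ev.forces,
            baseline_energy=e_base,
            provenance=provenance,
            positions=cfg.positions.copy(),
            box=cfg.box.copy(),
            force_rows=force_rows,
            force_targets=force_targets,
        )

    for k, cfg in enumerate(frames):
        records.append(label(cfg, "md_snapshot"))
        if include_minimization and k % minimize_every == 0:
            topo.inner_molecule_ids = set(region_molecules)
            try:
                regions = assign_regions(cfg, topo, buffer_cutoff)
            finally:
                topo.inner_molecule_ids = saved_inner
            subset = (
                inner_idx.tolist()
                + topo.molecule_atom_indices(regions.buffer).tolist()
            )
            for mcfg in minimize_cluster(cfg, topo, subset, engine,
                                         max_steps=max_min_steps):
                records.append(label(mcfg, "minimization_step"))
    return records
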