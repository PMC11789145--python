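"""Composition of the buffer-region and lambda-coupled Hamiltonians.

The unperturbed three-region energy is

    V = [V_ref(I+Buf) - V_ref(Buf)] + V_MM(Buf) + V_MM(O)
        + V_MM(Buf<->O) + V_MM(I<->O) + restraints

where the bracketed delta term is either two explicit reference-engine calls
("burqm" mode) or a single committee-model prediction ("burnn" mode).

For alchemical perturbations a dual-topology inner region holds both
end-state molecules A and B.  Their interactions with the buffer are
lambda-coupled through the delta term while a separate inner-only model
keeps the intramolecular surface of the decoupled molecule alive:

    V(lam) = intra_A + intra_B
             + (1-lam) [Delta_A - intra_A] + lam [Delta_B - intra_B]
             + V_MM(Buf) + V_MM(O) + V_MM(Buf<->O)
             + (1-lam) V_MM(I_A<->O) + lam V_MM(I_B<->O) + restraints

so that lam=0 is exactly the unperturbed Hamiltonian of solvated A (plus
the spectator intra_B term and the restraints), and symmetrically at lam=1.
For the purely linear coupling dH/dlam is configuration-dependent but
lambda-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .forcefield import (
    InteractionScope,
    distance_restraint_energy,
    mm_energy_forces,
    scaled_cross_nonbonded,
)
from .mlp import CommitteeModel, IntraModel
from .reference import ReferenceEngine, delta_reference, reference_energy
from .system import Configuration, RegionAssignment, SystemTopology, assign_regions

__all__ = [
    "EnergyResult",
    "BurnnEvaluator",
    "PerturbedBurnnEvaluator",
    "MMPerturbedEvaluator",
    "InterpolatedEvaluator",
    "burnn_energy",
    "dH_dlambda",
    "mm_burnn_interpolation",
]


@dataclass
class EnergyResult:
    """Composed energy with named components, forces and optional dH/dlam.

    ``components`` holds the unweighted term values; ``weights`` the
    lambda-weight each term enters the total with, so the identity
    total = sum_i weights[i] * components[i] is checkable exactly.
    """

    total: float
    components: dict[str, float]
    forces: np.ndarray
    dH_dlambda: float | None = None
    weights: dict[str, float] = field(default_factory=dict)
    regions: RegionAssignment | None = None

    def weighted_sum(self) -> float:
        return sum(
            self.weights.get(k, 1.0) * v for k, v in self.components.items()
        )


def _scatter(forces: np.ndarray, subset: Sequence[int], sub_forces: np.ndarray,
             weight: float = 1.0) -> None:
    for row, a in enumerate(subset):
        forces[a] += weight * sub_forces[row]


class BurnnEvaluator:
    """Unperturbed buffer-region Hamiltonian (single inner species).

    mode "burqm" computes the delta term with two explicit reference-engine
    calls; mode "burnn" uses a trained committee model.  All MM terms are
    shared between the modes.
    """

    def __init__(
        self,
        topo: SystemTopology,
        mode: str = "burqm",
        engine: ReferenceEngine | None = None,
        delta_model: CommitteeModel | None = None,
        buffer_cutoff: float = 0.5,
        mm_cutoff: float = 1.4,
        inner_molecules: set[int] | None = None,
    ):
        if mode not in ("burqm", "burnn"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "burqm" and engine is None:
            raise ValueError("burqm mode requires a reference engine")
        if mode == "burnn" and delta_model is None:
            raise ValueError("burnn mode requires a delta model")
        if delta_model is not None:
            trained_cut = delta_model.meta.get("buffer_cutoff")
            if trained_cut is not None and abs(trained_cut - buffer_cutoff) > 1e-12:
                raise ValueError(
                    f"model trained with buffer cutoff {trained_cut}, "
                    f"evaluator uses {buffer_cutoff}"
                )
        self.topo = topo
        self.mode = mode
        self.engine = engine
        self.delta_model = delta_model
        self.buffer_cutoff = buffer_cutoff
        self.mm_cutoff = mm_cutoff
        self.inner_molecules = (
            set(inner_molecules)
            if inner_molecules is not None
            else set(topo.inner_molecule_ids)
        )

    def assign(self, config: Configuration) -> RegionAssignment:
        inner = self.inner_molecules
        topo = self.topo
        if inner == set(topo.inner_molecule_ids):
            return assign_regions(config, topo, self.buffer_cutoff)
        # region assignment relative to a sub-selection of the inner molecules
        saved = topo.inner_molecule_ids
        try:
            topo.inner_molecule_ids = set(inner)
            return assign_regions(config, topo, self.buffer_cutoff)
        finally:
            topo.inner_molecule_ids = saved

    def _delta(self, config, inner_idx, buf_idx):
        if self.mode == "burqm":
            ev = delta_reference(config, inner_idx.tolist(), buf_idx.tolist(), self.engine)
            return ev.energy, ev.forces, ev.subset, 0.0
        e, dis, f, subset = self.delta_model.predict_config(
            config, self.topo, inner_idx, buf_idx, with_forces=True
        )
        return e, f, subset, dis

    def evaluate(
        self, config: Configuration, regions: RegionAssignment | None = None
    ) -> EnergyResult:
        topo = self.topo
        if regions is None:
            regions = self.assign(config)
        # the evaluator's own inner selection governs the delta and I<->O
        # terms; this lets a pure-A Hamiltonian be evaluated on a region
        # assignment computed for a dual-topology inner region
        inner_idx = topo.molecule_atom_indices(self.inner_molecules)
        buf_idx = topo.molecule_atom_indices(regions.buffer)

        forces = np.zeros((topo.n_atoms, 3))
        comp: dict[str, float] = {}

        delta_e, delta_f, subset, disagreement = self._delta(config, inner_idx, buf_idx)
        comp["delta"] = delta_e
        _scatter(forces, subset, delta_f)

        mm_buf = mm_energy_forces(
            config, topo, InteractionScope.within(regions.buffer), self.mm_cutoff
        )
        mm_o = mm_energy_forces(
            config, topo, InteractionScope.within(regions.outer), self.mm_cutoff
        )
        comp["mm_buf"], comp["mm_o"] = mm_buf.total, mm_o.total
        forces += mm_buf.forces + mm_o.forces
        if regions.buffer and regions.outer:
            mm_bo = mm_energy_forces(
                config,
                topo,
                InteractionScope.between(regions.buffer, regions.outer),
                self.mm_cutoff,
            )
            comp["mm_buf_o"] = mm_bo.total
            forces += mm_bo.forces
        else:
            comp["mm_buf_o"] = 0.0
        if regions.outer:
            mm_io = mm_energy_forces(
                config,
                topo,
                InteractionScope.between(self.inner_molecules, regions.outer),
                self.mm_cutoff,
            )
            comp["mm_i_o"] = mm_io.total
            forces += mm_io.forces
        else:
            comp["mm_i_o"] = 0.0
        e_r, f_r = distance_restraint_energy(config, topo.restraints)
        comp["restraint"] = e_r
        forces += f_r
        total = sum(comp.values())
        res = EnergyResult(total=total, components=comp, forces=forces, regions=regions)
        res.components["qbc_disagreement"] = disagreement
        res.weights["qbc_disagreement"] = 0.0
        return res


def burnn_energy(
    config: Configuration,
    topo: SystemTopology,
    regions: RegionAssignment | None = None,
    delta_model: CommitteeModel | None = None,
    engine: ReferenceEngine | None = None,
    buffer_cutoff: float = 0.5,
    mm_cutoff: float = 1.4,
) -> EnergyResult:
    """One-shot three-region energy; model if given, else reference engine."""
    mode = "burnn" if delta_model is not None else "burqm"
    ev = BurnnEvaluator(
        topo,
        mode=mode,
        engine=engine,
        delta_model=delta_model,
        buffer_cutoff=buffer_cutoff,
        mm_cutoff=mm_cutoff,
    )
    return ev.evaluate(config, regions=regions)


class PerturbedBurnnEvaluator:
    """Dual-topology lambda-coupled buffer-region Hamiltonian.

    ``models`` carries delta_A, delta_B (committee models for each end-state
    molecule plus buffer) and intra_A, intra_B (inner-only models keeping
    the decoupled molecule's intramolecular surface).  In "burqm" mode the
    reference engine replaces all four.

    The inner<->outer MM coupling is linear by default; Beutler soft-core
    parameters may be supplied, in which case the soft-core lambda terms
    enter dH/dlam analytically.
    """

    def __init__(
        self,
        topo: SystemTopology,
        lam: float,
        models: dict | None = None,
        engine: ReferenceEngine | None = None,
        buffer_cutoff: float = 0.5,
        mm_cutoff: float = 1.4,
        alpha_lj: float = 0.0,
        alpha_c: float = 0.0,
    ):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.topo = topo
        self.lam = lam
        self.engine = engine
        self.models = models or {}
        if engine is None:
            missing = {"delta_A", "delta_B", "intra_A", "intra_B"} - set(self.models)
            if missing:
                raise ValueError(
                    f"missing models {sorted(missing)}; a decoupled molecule "
                    "without an intra model loses its intramolecular forces"
                )
        self.buffer_cutoff = buffer_cutoff
        self.mm_cutoff = mm_cutoff
        self.alpha_lj = alpha_lj
        self.alpha_c = alpha_c
        self.mols_A = topo.dual_state_molecules("A")
        self.mols_B = topo.dual_state_molecules("B")
        if not self.mols_A or not self.mols_B:
            raise ValueError("dual topology requires tagged A and B molecules")
        self.atoms_A = topo.molecule_atom_indices(self.mols_A)
        self.atoms_B = topo.molecule_atom_indices(self.mols_B)

    def assign(self, config: Configuration) -> RegionAssignment:
        return assign_regions(config, self.topo, self.buffer_cutoff)

    # -- delta / intra terms --------------------------------------------
    def _delta_term(self, config, which: str, buf_idx):
        atoms = self.atoms_A if which == "A" else self.atoms_B
        if self.engine is not None:
            ev = delta_reference(config, atoms.tolist(), buf_idx.tolist(), self.engine)
            return ev.energy, ev.forces, ev.subset
        model: CommitteeModel = self.models[f"delta_{which}"]
        e, _, f, subset = model.predict_config(
            config, self.topo, atoms, buf_idx, with_forces=True
        )
        return e, f, subset

    def _intra_term(self, config, which: str):
        atoms = self.atoms_A if which == "A" else self.atoms_B
        if self.engine is not None:
            ev = reference_energy(config, atoms.tolist(), self.engine)
            return ev.energy, ev.forces, ev.subset
        model: IntraModel = self.models[f"intra_{which}"]
        e, _, f, subset = model.predict_config(config, self.topo, with_forces=True)
        return e, f, subset

    def evaluate(
        self, config: Configuration, regions: RegionAssignment | None = None
    ) -> EnergyResult:
        topo, lam = self.topo, self.lam
        if regions is None:
            regions = self.assign(config)
        buf_idx = topo.molecule_atom_indices(regions.buffer)
        forces = np.zeros((topo.n_atoms, 3))
        comp: dict[str, float] = {}
        weights: dict[str, float] = {}

        dA, fA, sA = self._delta_term(config, "A", buf_idx)
        dB, fB, sB = self._delta_term(config, "B", buf_idx)
        iA, fiA, siA = self._intra_term(config, "A")
        iB, fiB, siB = self._intra_term(config, "B")
        comp["delta_mlp_A"], weights["delta_mlp_A"] = dA, 1.0 - lam
        comp["delta_mlp_B"], weights["delta_mlp_B"] = dB, lam
        # intra terms enter as intra + w*(delta - intra): net intra weight
        comp["intra_A"], weights["intra_A"] = iA, lam
        comp["intra_B"], weights["intra_B"] = iB, 1.0 - lam
        _scatter(forces, sA, fA, 1.0 - lam)
        _scatter(forces, sB, fB, lam)
        _scatter(forces, siA, fiA, lam)
        _scatter(forces, siB, fiB, 1.0 - lam)

        mm_buf = mm_energy_forces(
            config, topo, InteractionScope.within(regions.buffer), self.mm_cutoff
        )
        mm_o = mm_energy_forces(
            config, topo, InteractionScope.within(regions.outer), self.mm_cutoff
        )
        comp["mm_buf"], weights["mm_buf"] = mm_buf.total, 1.0
        comp["mm_o"], weights["mm_o"] = mm_o.total, 1.0
        forces += mm_buf.forces + mm_o.forces
        if regions.buffer and regions.outer:
            mm_bo = mm_energy_forces(
                config,
                topo,
                InteractionScope.between(regions.buffer, regions.outer),
                self.mm_cutoff,
            )
            comp["mm_buf_o"], weights["mm_buf_o"] = mm_bo.total, 1.0
            forces += mm_bo.forces
        else:
            comp["mm_buf_o"], weights["mm_buf_o"] = 0.0, 1.0

        dH = (dB - iB) - (dA - iA)
        softcore = self.alpha_lj > 0 or self.alpha_c > 0
        if regions.outer:
            if softcore:
                eA, fA_o, dA_o = scaled_cross_nonbonded(
                    config, topo, self.mols_A, regions.outer, lam, "A",
                    self.mm_cutoff, self.alpha_lj, self.alpha_c,
                )
                eB, fB_o, dB_o = scaled_cross_nonbonded(
                    config, topo, self.mols_B, regions.outer, lam, "B",
                    self.mm_cutoff, self.alpha_lj, self.alpha_c,
                )
                comp["mm_i_o_A"], weights["mm_i_o_A"] = eA, 1.0
                comp["mm_i_o_B"], weights["mm_i_o_B"] = eB, 1.0
                forces += fA_o + fB_o
                dH += dA_o + dB_o
            else:
                mm_ioA = mm_energy_forces(
                    config, topo,
                    InteractionScope.between(self.mols_A, regions.outer),
                    self.mm_cutoff,
                )
                mm_ioB = mm_energy_forces(
                    config, topo,
                    InteractionScope.between(self.mols_B, regions.outer),
                    self.mm_cutoff,
                )
                comp["mm_i_o_A"], weights["mm_i_o_A"] = mm_ioA.total, 1.0 - lam
                comp["mm_i_o_B"], weights["mm_i_o_B"] = mm_ioB.total, lam
                forces += (1.0 - lam) * mm_ioA.forces + lam * mm_ioB.forces
                dH += mm_ioB.total - mm_ioA.total
        else:
            comp["mm_i_o_A"], weights["mm_i_o_A"] = 0.0, 1.0 - lam
            comp["mm_i_o_B"], weights["mm_i_o_B"] = 0.0, lam

        e_r, f_r = distance_restraint_energy(config, topo.restraints)
        comp["restraint"], weights["restraint"] = e_r, 1.0
        forces += f_r

        total = sum(weights[k] * comp[k] for k in comp)
        return EnergyResult(
            total=total,
            components=comp,
            forces=forces,
            dH_dlambda=dH,
            weights=weights,
            regions=regions,
        )


def dH_dlambda(
    config: Configuration,
    topo: SystemTopology,
    regions: RegionAssignment | None = None,
    lam: float = 0.0,
    models: dict | None = None,
    engine: ReferenceEngine | None = None,
    **kwargs,
) -> float:
    """Analytic lambda-derivative of the perturbed Hamiltonian."""
    ev = PerturbedBurnnEvaluator(
        topo, lam, models=models, engine=engine, **kwargs
    )
    return float(ev.evaluate(config, regions=regions).dH_dlambda)


class MMPerturbedEvaluator:
    """Pure-MM dual-topology Hamiltonian (the classical legs of the cycle).

    Intramolecular terms of both end-state molecules stay fully on;
    only their nonbonded interactions with the environment are scaled,
    optionally through Beutler soft-core.
    """

    def __init__(
        self,
        topo: SystemTopology,
        lam: float,
        mm_cutoff: float = 1.4,
        alpha_lj: float = 0.0,
        alpha_c: float = 0.0,
    ):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.topo = topo
        self.lam = lam
        self.mm_cutoff = mm_cutoff
        self.alpha_lj = alpha_lj
        self.alpha_c = alpha_c
        self.mols_A = topo.dual_state_molecules("A")
        self.mols_B = topo.dual_state_molecules("B")
        all_mols = set(topo.all_molecule_ids())
        self.env_mols = all_mols - self.mols_A - self.mols_B

    def evaluate(
        self, config: Configuration, regions: RegionAssignment | None = None
    ) -> EnergyResult:
        topo, lam = self.topo, self.lam
        forces = np.zeros((topo.n_atoms, 3))
        comp: dict[str, float] = {}
        weights: dict[str, float] = {}

        env = mm_energy_forces(
            config, topo, InteractionScope.within(self.env_mols), self.mm_cutoff
        )
        comp["mm_env"], weights["mm_env"] = env.total, 1.0
        forces += env.forces
        for which, mols in (("A", self.mols_A), ("B", self.mols_B)):
            intra = mm_energy_forces(
                config, topo, InteractionScope.within(mols), self.mm_cutoff
            )
            comp[f"intra_mm_{which}"], weights[f"intra_mm_{which}"] = intra.total, 1.0
            forces += intra.forces
        dH = 0.0
        for which, mols in (("A", self.mols_A), ("B", self.mols_B)):
            e, f, de = scaled_cross_nonbonded(
                config, topo, mols, self.env_mols, lam, which,
                self.mm_cutoff, self.alpha_lj, self.alpha_c,
            )
            comp[f"cross_{which}"], weights[f"cross_{which}"] = e, 1.0
            forces += f
            dH += de
        e_r, f_r = distance_restraint_energy(config, topo.restraints)
        comp["restraint"], weights["restraint"] = e_r, 1.0
        forces += f_r
        total = sum(weights[k] * comp[k] for k in comp)
        return EnergyResult(
            total=total, components=comp, forces=forces, dH_dlambda=dH, weights=weights
        )


class InterpolatedEvaluator:
    """H(mu) = (1-mu) H_MM + mu H_BuRNN on identical coordinates.

    Used for the vertical legs of the thermodynamic cycle, perturbing
    between the classical and the buffer-region descriptions of the same
    chemical end state.  dH/dmu = H_BuRNN - H_MM.
    """

    def __init__(self, mm_evaluator, burnn_evaluator, mu: float):
        if not 0.0 <= mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        self.mm = mm_evaluator
        self.burnn = burnn_evaluator
        self.mu = mu

    def evaluate(
        self, config: Configuration, regions: RegionAssignment | None = None
    ) -> EnergyResult:
        res_mm = self.mm.evaluate(config)
        res_bu = self.burnn.evaluate(config, regions=regions)
        mu = self.mu
        total = (1.0 - mu) * res_mm.total + mu * res_bu.total
        forces = (1.0 - mu) * res_mm.forces + mu * res_bu.forces
        comp = {"mm_total": res_mm.total, "burnn_total": res_bu.total}
        return EnergyResult(
            total=total,
            components=comp,
            forces=forces,
            dH_dlambda=res_bu.total - res_mm.total,
            weights={"mm_total": 1.0 - mu, "burnn_total": mu},
            regions=res_bu.regions,
        )


def mm_burnn_interpolation(
    config: Configuration, mu: float, mm_total: float, burnn_total: float
) -> tuple[float, float]:
    """Linear MM<->BuRNN interpolation of two totals on shared coordinates."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    return (1.0 - mu) * mm_total + mu * burnn_total, burnn_total - mm_total
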