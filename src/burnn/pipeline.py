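"""End-to-end drivers: model fitting, lambda series, vertical legs, cycles.

These functions wire the pieces together the way a production study would:
classical MD generates training frames, the reference engine labels them,
curation and mean-centering produce the dataset, a committee is trained per
end state (plus the inner-only models), and the perturbed Hamiltonians are
sampled over a lambda grid feeding thermodynamic integration.

Every driver takes a seed and is deterministic for fixed inputs; derived
seeds are spawned arithmetically and stay below 2^31.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import CycleLeg, TISeries, cycle_closure, ti_integrate, ti_series_from_samples
from .descriptors import DescriptorSpec
from .hamiltonian import (
    BurnnEvaluator,
    InterpolatedEvaluator,
    MMPerturbedEvaluator,
    PerturbedBurnnEvaluator,
)
from .md import MDOptions, Trajectory, run_simulation
from .mlp import (
    CommitteeModel,
    IntraModel,
    adaptive_sample,
    curate_dataset,
    subtract_reference,
    train_committee,
    train_intra_model,
)
from .reference import MockQMEngine, ReferenceEngine
from .system import Configuration, SystemTopology
from .toys import ToySystemSpec, build_toy_system, generate_training_data

__all__ = [
    "FEPSettings",
    "sample_mm_frames",
    "fit_state_models",
    "fit_dual_models",
    "lambda_series",
    "run_fep_leg",
    "run_vertical_leg",
    "run_thermodynamic_cycle",
    "adaptive_training_round",
]


@dataclass
class FEPSettings:
    """Sampling parameters shared by all FEP legs (desk-scale defaults)."""

    lambdas: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 5))
    n_steps: int = 400
    dt: float = 0.002               # ps; SHAKE-constrained water allows 2 fs
    sample_every: int = 2
    equil_fraction: float = 0.25
    temperature: float = 298.15
    thermostat: str = "andersen"
    buffer_cutoff: float = 0.5
    mm_cutoff: float = 1.0
    alpha_lj: float = 0.0
    alpha_c: float = 0.0
    n_replicas: int = 1


def sample_mm_frames(
    topo: SystemTopology,
    config: Configuration,
    lam: float,
    n_frames: int,
    seed: int,
    cadence: int = 10,
    dt: float = 0.002,
    temperature: float = 298.15,
    mm_cutoff: float = 1.0,
    engine: ReferenceEngine | None = None,
    buffer_cutoff: float = 0.5,
) -> list[Configuration]:
    """MD snapshots of the dual-topology system at one lambda.

    With ``engine`` absent the sampling Hamiltonian is classical (the
    initial-data convention); with an engine the reference-level perturbed
    Hamiltonian itself is propagated, covering the configurations that
    model-driven dynamics will later visit.
    """
    if engine is None:
        ev = MMPerturbedEvaluator(topo, lam, mm_cutoff=mm_cutoff)
    else:
        ev = PerturbedBurnnEvaluator(
            topo, lam, engine=engine,
            buffer_cutoff=buffer_cutoff, mm_cutoff=mm_cutoff,
        )
    opts = MDOptions(
        dt=dt,
        n_steps=n_frames * cadence,
        temperature=temperature,
        thermostat="berendsen",
        seed=seed,
        sample_every=cadence,
    )
    traj = run_simulation(topo, config, ev, opts)
    return traj.frames[1:]  # drop the un-equilibrated initial frame


def fit_state_models(
    topo: SystemTopology,
    frames: list[Configuration],
    engine: ReferenceEngine,
    state: str,
    seed: int,
    descriptor: DescriptorSpec | None = None,
    buffer_cutoff: float = 0.5,
    hyper: dict | None = None,
    include_minimization: bool = True,
    n_members: int = 2,
    adaptive_rounds: int = 1,
    disagreement_threshold: float = 1.0,
) -> tuple[CommitteeModel, IntraModel]:
    """Delta committee plus inner-only model for one end-state molecule.

    After the initial fit, ``adaptive_rounds`` Query-by-Committee passes
    over the frame pool label high-disagreement frames with the reference
    engine and retrain — the adaptive-sampling loop that keeps rare
    configurations (for example near-contacts around a decoupled end state)
    from poisoning the committee.
    """
    mols = topo.dual_state_molecules(state)
    inner_idx = topo.molecule_atom_indices(mols)
    if descriptor is None:
        descriptor = DescriptorSpec.from_topology(topo)
    region_mols = set(topo.inner_molecule_ids)
    records = generate_training_data(
        topo, frames, engine, mols, descriptor,
        buffer_cutoff=buffer_cutoff,
        include_minimization=include_minimization,
        region_molecules=region_mols,
    )
    ds = subtract_reference(curate_dataset(records))
    committee = train_committee(
        ds, n_members=n_members, seed=seed, hyper=hyper, descriptor=descriptor
    )
    for round_k in range(adaptive_rounds):
        picked = adaptive_sample(
            frames, committee, disagreement_threshold, topo, inner_idx,
            buffer_cutoff=buffer_cutoff, region_molecules=region_mols,
        )
        if not picked:
            break
        extra = generate_training_data(
            topo, [frames[k] for k in picked], engine, mols, descriptor,
            buffer_cutoff=buffer_cutoff, region_molecules=region_mols,
        )
        for r in extra:
            r.provenance = "adaptive"
        records = records + extra
        ds = subtract_reference(curate_dataset(records))
        committee = train_committee(
            ds, n_members=n_members, seed=seed + 1000 * (round_k + 1),
            hyper=hyper, descriptor=descriptor,
        )
    committee.meta.update(
        {
            "buffer_cutoff": buffer_cutoff,
            "state": state,
            "kind": "delta",
            "training_records": records,
        }
    )
    intra = train_intra_model(
        frames, topo, inner_idx, engine, n_members=n_members, seed=seed + 1,
        hyper=hyper, descriptor=descriptor,
    )
    return committee, intra


def fit_dual_models(
    topo: SystemTopology,
    config: Configuration,
    engine: ReferenceEngine,
    seed: int = 0,
    n_frames: int = 300,
    cadence: int = 5,
    buffer_cutoff: float = 0.5,
    mm_cutoff: float = 1.0,
    hyper: dict | None = None,
    include_minimization: bool = False,
) -> dict:
    """Train all four models of the perturbed Hamiltonian.

    Frames are pooled from runs at both end states and at the path midpoint,
    half sampled with the classical Hamiltonian (the initial-data
    convention) and half with the reference-level perturbed Hamiltonian —
    emulating the iterative workflow in which later training rounds draw
    from the perturbed simulations themselves.  This gives each delta
    committee support over the configurations model-driven FEP dynamics
    will visit.
    """
    descriptor = DescriptorSpec.from_topology(topo)
    n_run = max(1, n_frames // 6)
    frames = []
    k = 0
    for level_engine in (None, engine):
        for lam in (0.0, 0.5, 1.0):
            frames += sample_mm_frames(
                topo, config, lam, n_run, seed=seed * 13 + 1 + k,
                cadence=cadence, mm_cutoff=mm_cutoff, engine=level_engine,
                buffer_cutoff=buffer_cutoff,
            )
            k += 1
    delta_A, intra_A = fit_state_models(
        topo, frames, engine, "A", seed * 13 + 3, descriptor,
        buffer_cutoff, hyper, include_minimization,
    )
    delta_B, intra_B = fit_state_models(
        topo, frames, engine, "B", seed * 13 + 4, descriptor,
        buffer_cutoff, hyper, include_minimization,
    )
    return {
        "delta_A": delta_A,
        "delta_B": delta_B,
        "intra_A": intra_A,
        "intra_B": intra_B,
        "descriptor": descriptor,
        "frames": frames,
    }


def _leg_samples(
    topo: SystemTopology,
    config: Configuration,
    make_evaluator,
    schedule: np.ndarray,
    settings: FEPSettings,
    seed: int,
) -> list[list[np.ndarray]]:
    """Per-point, per-replica dH/dlambda samples for one leg."""
    samples: list[list[np.ndarray]] = []
    expected = settings.n_steps // settings.sample_every
    for i, lam in enumerate(schedule):
        reps = []
        for r in range(settings.n_replicas):
            ev = make_evaluator(float(lam))
            collected: list[np.ndarray] = []
            # a surrogate-driven trajectory can occasionally blow up; the
            # crashed tail is discarded and the point is re-run with fresh
            # velocities (deterministic retry schedule)
            for attempt in range(3):
                opts = MDOptions(
                    dt=settings.dt,
                    n_steps=settings.n_steps,
                    temperature=settings.temperature,
                    thermostat=settings.thermostat,
                    seed=(seed * 97 + i * 7 + r + attempt * 7919) % (2**31 - 1),
                    sample_every=settings.sample_every,
                )
                traj = run_simulation(topo, config, ev, opts, on_error="truncate")
                d = traj.energy_series["dH_dlambda"].to_numpy()
                if "terminated_early" in traj.metadata:
                    d = d[: max(0, len(d) - max(1, len(d) // 5))]
                skip = int(settings.equil_fraction * len(d))
                collected.append(d[skip:])
                if sum(len(c) for c in collected) >= expected // 2:
                    break
            reps.append(np.concatenate(collected) if collected else np.array([0.0]))
        samples.append(reps)
    return samples


def lambda_series(
    topo: SystemTopology,
    config: Configuration,
    make_evaluator,
    schedule: np.ndarray,
    settings: FEPSettings,
    seed: int,
) -> TISeries:
    return ti_series_from_samples(
        schedule, _leg_samples(topo, config, make_evaluator, schedule, settings, seed)
    )


def run_fep_leg(
    topo: SystemTopology,
    config: Configuration,
    settings: FEPSettings,
    seed: int,
    level: str = "mm",
    models: dict | None = None,
    engine: ReferenceEngine | None = None,
) -> tuple[float, float, TISeries]:
    """A->B alchemical leg at the MM, BuRQM or BuRNN level of theory."""
    if level == "mm":
        def make(lam):
            return MMPerturbedEvaluator(
                topo, lam, mm_cutoff=settings.mm_cutoff,
                alpha_lj=settings.alpha_lj, alpha_c=settings.alpha_c,
            )
    elif level in ("burnn", "burqm"):
        def make(lam):
            return PerturbedBurnnEvaluator(
                topo, lam,
                models=models if level == "burnn" else None,
                engine=engine if level == "burqm" else None,
                buffer_cutoff=settings.buffer_cutoff,
                mm_cutoff=settings.mm_cutoff,
            )
    else:
        raise ValueError(f"unknown level {level!r}")
    series = lambda_series(topo, config, make, settings.lambdas, settings, seed)
    dG, err = ti_integrate(series)
    return dG, err, series


def run_vertical_leg(
    topo: SystemTopology,
    config: Configuration,
    settings: FEPSettings,
    seed: int,
    end_state: str,
    models: dict,
    mus: np.ndarray | None = None,
) -> tuple[float, float, TISeries]:
    """MM -> BuRNN perturbation of one chemical end state (vertical leg).

    The end state is held fixed (lam = 0 for A, 1 for B) while mu
    interpolates between the classical and the buffer-region Hamiltonian.
    """
    lam = 0.0 if end_state == "A" else 1.0
    if mus is None:
        mus = np.linspace(0.0, 1.0, 5)

    def make(mu):
        mm = MMPerturbedEvaluator(topo, lam, mm_cutoff=settings.mm_cutoff)
        bu = PerturbedBurnnEvaluator(
            topo, lam, models=models,
            buffer_cutoff=settings.buffer_cutoff, mm_cutoff=settings.mm_cutoff,
        )
        return InterpolatedEvaluator(mm, bu, mu)

    series = lambda_series(topo, config, make, mus, settings, seed)
    dG, err = ti_integrate(series)
    return dG, err, series


def run_thermodynamic_cycle(
    topo: SystemTopology,
    config: Configuration,
    models: dict,
    settings: FEPSettings,
    seed: int = 0,
) -> tuple[float, float, list[CycleLeg]]:
    """Four-leg cycle: vertical A up, BuRNN A->B, vertical B down, MM B->A.

    For a state function the signed sum vanishes up to sampling error;
    the returned closure and its propagated error quantify that.
    """
    dg_va, e_va, _ = run_vertical_leg(topo, config, settings, seed + 11, "A", models)
    dg_bu, e_bu, _ = run_fep_leg(
        topo, config, settings, seed + 22, level="burnn", models=models
    )
    dg_vb, e_vb, _ = run_vertical_leg(topo, config, settings, seed + 33, "B", models)
    dg_mm, e_mm, _ = run_fep_leg(topo, config, settings, seed + 44, level="mm")
    legs = [
        CycleLeg("vertical_A_mm_to_burnn", dg_va, e_va, +1,
                 start="A_mm", end="A_burnn"),
        CycleLeg("burnn_A_to_B", dg_bu, e_bu, +1, start="A_burnn", end="B_burnn"),
        CycleLeg("vertical_B_mm_to_burnn", dg_vb, e_vb, -1,
                 start="B_mm", end="B_burnn"),
        CycleLeg("mm_A_to_B", dg_mm, e_mm, -1, start="A_mm", end="B_mm"),
    ]
    closure, err = cycle_closure(legs)
    return closure, err, legs


def refine_models(
    topo: SystemTopology,
    config: Configuration,
    models: dict,
    engine: ReferenceEngine,
    seed: int = 0,
    rounds: int = 3,
    probe_steps: int = 300,
    probe_lambdas: tuple = (0.0, 0.5, 1.0),
    disagreement_threshold: float = 1.0,
    buffer_cutoff: float = 0.5,
    mm_cutoff: float = 1.0,
    hyper: dict | None = None,
) -> dict:
    """Adaptive-sampling rounds over model-driven FEP trajectories.

    Each round runs short perturbed simulations with the current committees
    (truncating gracefully if a trajectory blows up), labels frames whose
    committee disagreement exceeds the threshold with the reference engine,
    and retrains.  This is the stabilizing train -> simulate -> select ->
    retrain loop: trajectories drift into configurations the initial data
    did not cover, and exactly those frames get added.
    """
    from .md import MDOptions, run_simulation

    region_mols = set(topo.inner_molecule_ids)
    for rnd in range(rounds):
        probe_frames: list[Configuration] = []
        crashed = False
        for i, lam in enumerate(probe_lambdas):
            ev = PerturbedBurnnEvaluator(
                topo, float(lam), models=models,
                buffer_cutoff=buffer_cutoff, mm_cutoff=mm_cutoff,
            )
            opts = MDOptions(
                dt=0.002, n_steps=probe_steps, thermostat="andersen",
                seed=(seed * 31 + rnd * 7 + i) % (2**31 - 1), sample_every=2,
            )
            traj = run_simulation(topo, config, ev, opts, on_error="truncate")
            new = traj.frames
            if "terminated_early" in traj.metadata:
                crashed = True
                # frames recorded just before a blow-up are already corrupted;
                # keep only the leading, still-physical part of the run
                new = new[: max(0, len(new) - 25)]
            probe_frames += [
                f for f in new if np.all(np.isfinite(f.positions))
            ]
        n_new = 0
        for state in ("A", "B"):
            committee = models[f"delta_{state}"]
            mols = topo.dual_state_molecules(state)
            inner_idx = topo.molecule_atom_indices(mols)
            picked = adaptive_sample(
                probe_frames, committee, disagreement_threshold, topo,
                inner_idx, buffer_cutoff=buffer_cutoff,
                region_molecules=region_mols,
            )
            if not picked:
                continue
            extra = generate_training_data(
                topo, [probe_frames[k] for k in picked], engine, mols,
                committee.descriptor, buffer_cutoff=buffer_cutoff,
                region_molecules=region_mols,
            )
            for r in extra:
                r.provenance = "adaptive"
            pool = committee.meta.get("training_records", []) + extra
            ds = subtract_reference(curate_dataset(pool))
            retrained = train_committee(
                ds, n_members=len(committee.members),
                seed=(seed * 131 + rnd * 17) % (2**31 - 1),
                hyper=hyper or committee.hyperparameters,
                descriptor=committee.descriptor,
            )
            retrained.meta.update(committee.meta)
            retrained.meta["training_records"] = pool
            models[f"delta_{state}"] = retrained
            # refresh the matching intra model on the enlarged geometry pool
            intra_pool = (models.get("frames") or [])[::2] + (
                probe_frames[:: max(1, len(probe_frames) // 150)] or probe_frames
            )
            models[f"intra_{state}"] = train_intra_model(
                intra_pool, topo, inner_idx, engine,
                n_members=len(committee.members),
                seed=(seed * 131 + rnd * 17 + 1) % (2**31 - 1),
                hyper=hyper, descriptor=committee.descriptor,
            )
            n_new += len(extra)
        if n_new == 0 and not crashed:
            break
    return models


def adaptive_training_round(
    topo: SystemTopology,
    config: Configuration,
    model: CommitteeModel,
    engine: ReferenceEngine,
    frames: list[Configuration],
    state: str,
    disagreement_threshold: float,
    seed: int,
    hyper: dict | None = None,
) -> tuple[CommitteeModel, list[int]]:
    """One train -> simulate -> select -> retrain round of adaptive sampling.

    Frames whose committee disagreement exceeds the threshold are labeled
    with the reference engine, appended to the training pool, and the
    committee is retrained with a fresh split seed.
    """
    mols = topo.dual_state_molecules(state)
    inner_idx = topo.molecule_atom_indices(mols)
    picked = adaptive_sample(
        frames, model, disagreement_threshold, topo, inner_idx,
        buffer_cutoff=model.meta.get("buffer_cutoff", 0.5),
    )
    if not picked:
        return model, []
    new_records = generate_training_data(
        topo, [frames[k] for k in picked], engine, mols, model.descriptor,
        buffer_cutoff=model.meta.get("buffer_cutoff", 0.5),
    )
    for r in new_records:
        r.provenance = "adaptive"
    pool = model.meta.get("training_records", [])
    all_records = pool + new_records if pool else new_records
    ds = subtract_reference(curate_dataset(all_records))
    retrained = train_committee(
        ds, n_members=len(model.members), seed=seed,
        hyper=hyper or model.hyperparameters, descriptor=model.descriptor,
    )
    retrained.meta.update(model.meta)
    retrained.meta["training_records"] = all_records
    return retrained, picked
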