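"""Leapfrog molecular dynamics with SHAKE, thermostats and recording.

The propagator is deliberately simple: leapfrog Verlet, holonomic
bond-length constraints via SHAKE (with the matching velocity projection),
and either Berendsen weak-coupling or Andersen collision thermostatting.
Berendsen is the lineage default for production-style runs; Andersen gives
rigorously canonical sampling and is used wherever free-energy averages are
compared against closed forms.

Region reassignment for buffer-region Hamiltonians happens every
``region_update_every`` steps (default: every step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is expected to be present
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not args else args[0]

from .system import (
    Configuration,
    SystemTopology,
    minimum_image_displacements,
)

__all__ = [
    "KB",
    "MDState",
    "MDOptions",
    "Trajectory",
    "IntegrationError",
    "ShakeError",
    "integrate_step",
    "apply_shake",
    "apply_rattle_velocities",
    "thermostat_scale",
    "kinetic_energy",
    "instantaneous_temperature",
    "maxwell_boltzmann_velocities",
    "run_simulation",
]

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant)
KB = 0.00831446261815324


class IntegrationError(RuntimeError):
    """Non-finite forces or positions; carries the offending frame."""

    def __init__(self, message: str, config: Configuration | None = None):
        super().__init__(message)
        self.config = config


class ShakeError(RuntimeError):
    """SHAKE failed to converge within the iteration budget."""


@dataclass
class MDState:
    configuration: Configuration
    step: int = 0
    temperature_inst: float = 0.0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )


@dataclass
class MDOptions:
    dt: float = 0.0005              # ps (0.5 fs unconstrained default)
    n_steps: int = 1000
    temperature: float = 298.15     # K
    thermostat: str | None = "berendsen"   # berendsen | andersen | langevin | None
    tau: float = 0.1                # ps, Berendsen coupling time
    andersen_nu: float = 20.0       # 1/ps, Andersen collision frequency
    langevin_gamma: float = 5.0     # 1/ps, Langevin friction (BAOAB)
    seed: int = 0
    sample_every: int = 10
    region_update_every: int = 1
    remove_com: bool = True
    dof_override: int | None = None
    wrap: bool = True
    velocity_mask: np.ndarray | None = None   # (n,3) bool, active components
    shake_tol: float = 1e-6
    shake_max_iter: int = 500


@dataclass
class Trajectory:
    frames: list[Configuration]
    energy_series: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.energy_series):
            raise ValueError("frames and energy series must be index-aligned")


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return float(0.5 * np.sum(masses[:, None] * velocities**2))


def n_degrees_of_freedom(topo: SystemTopology, opts: MDOptions) -> int:
    if opts.dof_override is not None:
        return opts.dof_override
    n = 3 * topo.n_atoms - len(topo.constraints)
    if opts.remove_com:
        n -= 3
    return max(n, 1)


def instantaneous_temperature(
    velocities: np.ndarray, masses: np.ndarray, ndf: int
) -> float:
    return 2.0 * kinetic_energy(velocities, masses) / (ndf * KB)


def maxwell_boltzmann_velocities(
    topo: SystemTopology,
    temperature: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    sig = np.sqrt(KB * temperature / topo.masses)
    v = rng.normal(size=(topo.n_atoms, 3)) * sig[:, None]
    if mask is not None:
        v = np.where(mask, v, 0.0)
    return v


def apply_shake(
    positions_before: np.ndarray,
    positions_after: np.ndarray,
    constraints: list[tuple[int, int, float]],
    masses: np.ndarray,
    box: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, int]:
    """Iteratively restore bond-length constraints after an unconstrained move.

    Corrections act along the pre-move bond vectors (classic SHAKE).  The
    convergence criterion is relative: |d - d0| / d0 <= tol for every
    constraint.  Returns the corrected positions and the iteration count.
    """
    if not constraints:
        return positions_after.copy(), 0
    pos = positions_after.copy()
    ci = np.array([c[0] for c in constraints], dtype=np.int64)
    cj = np.array([c[1] for c in constraints], dtype=np.int64)
    d0 = np.array([c[2] for c in constraints], dtype=np.float64)
    r_old = minimum_image_displacements(
        positions_before[cj] - positions_before[ci], box
    )
    status, n_iter = _shake_kernel(
        pos, r_old, ci, cj, d0, 1.0 / masses, box, tol, max_iter
    )
    if status == 1:
        raise ShakeError("degenerate constraint geometry")
    if status == 2:
        raise ShakeError(f"SHAKE did not converge in {max_iter} iterations")
    return pos, int(n_iter)


@njit(cache=True)
def _shake_kernel(pos, r_old, ci, cj, d0, inv_m, box, tol, max_iter):
    n_c = len(ci)
    for it in range(1, max_iter + 1):
        converged = True
        for c in range(n_c):
            i, j = ci[c], cj[c]
            rn = np.empty(3)
            for k in range(3):
                d = pos[j, k] - pos[i, k]
                d -= box[k] * np.floor(d / box[k] + 0.5)
                rn[k] = d
            d2 = rn[0] * rn[0] + rn[1] * rn[1] + rn[2] * rn[2]
            if abs(np.sqrt(d2) - d0[c]) / d0[c] > tol:
                converged = False
                dot = (
                    r_old[c, 0] * rn[0] + r_old[c, 1] * rn[1] + r_old[c, 2] * rn[2]
                )
                denom = 2.0 * (inv_m[i] + inv_m[j]) * dot
                if abs(denom) < 1e-12:
                    return 1, it
                g = (d2 - d0[c] * d0[c]) / denom
                for k in range(3):
                    pos[i, k] += g * inv_m[i] * r_old[c, k]
                    pos[j, k] -= g * inv_m[j] * r_old[c, k]
        if converged:
            return 0, it
    return 2, max_iter


def apply_rattle_velocities(
    positions: np.ndarray,
    velocities: np.ndarray,
    constraints: list[tuple[int, int, float]],
    masses: np.ndarray,
    box: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Project velocities onto the constraint manifold (d/dt |r_ij| = 0)."""
    if not constraints:
        return velocities
    v = velocities.copy()
    ci = np.array([c[0] for c in constraints], dtype=np.int64)
    cj = np.array([c[1] for c in constraints], dtype=np.int64)
    d0 = np.array([c[2] for c in constraints], dtype=np.float64)
    r = minimum_image_displacements(positions[cj] - positions[ci], box)
    _rattle_kernel(v, r, ci, cj, d0, 1.0 / masses, tol, max_iter)
    return v


@njit(cache=True)
def _rattle_kernel(v, r, ci, cj, d0, inv_m, tol, max_iter):
    n_c = len(ci)
    for _ in range(max_iter):
        worst = 0.0
        for c in range(n_c):
            i, j = ci[c], cj[c]
            cv = 0.0
            for k in range(3):
                cv += (v[j, k] - v[i, k]) * r[c, k]
            scale = abs(cv) / (d0[c] * d0[c])
            if scale > worst:
                worst = scale
            g = cv / ((inv_m[i] + inv_m[j]) * d0[c] * d0[c])
            for k in range(3):
                v[i, k] += g * inv_m[i] * r[c, k]
                v[j, k] -= g * inv_m[j] * r[c, k]
        if worst < tol:
            break


def thermostat_scale(
    velocities: np.ndarray,
    masses: np.ndarray,
    ndf: int,
    T_target: float,
    tau: float,
    dt: float,
) -> tuple[np.ndarray, float]:
    """Berendsen weak-coupling velocity scaling toward T_target.

    tau = dt rescales instantaneously; tau -> infinity recovers NVE.
    Returns (scaled velocities, scale factor).
    """
    if tau < dt:
        raise ValueError("coupling time must be at least dt")
    T = instantaneous_temperature(velocities, masses, ndf)
    if T <= 0:
        return velocities, 1.0
    lam = float(np.sqrt(1.0 + dt / tau * (T_target / T - 1.0)))
    return velocities * lam, lam


def integrate_step(
    state: MDState,
    evaluator,
    topo: SystemTopology,
    opts: MDOptions,
    regions=None,
    forces: np.ndarray | None = None,
):
    """One leapfrog step (with SHAKE and thermostatting); returns
    (new_state, EnergyResult_at_old_positions, new_forces_placeholder).

    ``forces`` may carry the forces already evaluated at the current
    positions to avoid a redundant energy call; the energy result of that
    evaluation is re-used for recording.
    """
    cfg = state.configuration
    if forces is None:
        res = evaluator.evaluate(cfg, regions=regions)
    else:
        res = forces
    f = res.forces
    if not np.all(np.isfinite(f)):
        raise IntegrationError("non-finite forces", config=cfg)
    dt = opts.dt
    masses = topo.masses[:, None]
    v = cfg.velocities
    if v is None:
        v = np.zeros_like(cfg.positions)

    if opts.thermostat == "langevin":
        # BAOAB splitting with on-step velocities; exact OU step in the
        # middle gives near-unbiased configurational averages.  Holonomic
        # constraints are not supported on this path.
        if topo.constraints:
            raise ValueError("langevin integrator does not support constraints")
        gamma = opts.langevin_gamma
        c1 = np.exp(-gamma * dt)
        sig = np.sqrt(KB * opts.temperature / topo.masses * (1.0 - c1 * c1))
        # full kick: the closing half-kick of the previous BAOAB step and
        # the opening half-kick of this one both use f(x_t)
        v_half = v + f / masses * dt
        x_mid = cfg.positions + v_half * (dt / 2.0)
        noise = state.rng.normal(size=v.shape) * sig[:, None]
        v_ou = c1 * v_half + noise
        if opts.velocity_mask is not None:
            v_ou = np.where(opts.velocity_mask, v_ou, 0.0)
        x_new = x_mid + v_ou * (dt / 2.0)
        if opts.wrap:
            x_new = x_new - cfg.box * np.floor(x_new / cfg.box)
        # the closing B half-kick is applied at the start of the next step
        # (velocities here are on-step up to that half-kick)
        new_cfg = Configuration(
            positions=x_new, box=cfg.box.copy(), velocities=v_ou,
            time=cfg.time + dt,
        )
        ndf = n_degrees_of_freedom(topo, opts)
        new_state = MDState(
            configuration=new_cfg,
            step=state.step + 1,
            temperature_inst=instantaneous_temperature(v_ou, topo.masses, ndf),
            rng=state.rng,
        )
        return new_state, res, v_ou

    v_new = v + f / masses * dt
    if opts.velocity_mask is not None:
        v_new = np.where(opts.velocity_mask, v_new, 0.0)
    x_new = cfg.positions + v_new * dt
    if topo.constraints:
        x_new, _ = apply_shake(
            cfg.positions, x_new, topo.constraints, topo.masses, cfg.box,
            tol=opts.shake_tol, max_iter=opts.shake_max_iter,
        )
        v_new = (x_new - cfg.positions) / dt

    ndf = n_degrees_of_freedom(topo, opts)
    if opts.thermostat == "berendsen":
        v_new, _ = thermostat_scale(
            v_new, topo.masses, ndf, opts.temperature, opts.tau, dt
        )
    elif opts.thermostat == "andersen":
        p = min(opts.andersen_nu * dt, 1.0)
        hit = state.rng.random(topo.n_atoms) < p
        if np.any(hit):
            fresh = maxwell_boltzmann_velocities(
                topo, opts.temperature, state.rng, mask=opts.velocity_mask
            )
            v_new = np.where(hit[:, None], fresh, v_new)
            if topo.constraints:
                v_new = apply_rattle_velocities(
                    x_new, v_new, topo.constraints, topo.masses, cfg.box
                )
            if opts.velocity_mask is not None:
                v_new = np.where(opts.velocity_mask, v_new, 0.0)
    elif opts.thermostat is not None:
        raise ValueError(f"unknown thermostat {opts.thermostat!r}")

    if opts.wrap:
        x_new = x_new - cfg.box * np.floor(x_new / cfg.box)
    new_cfg = Configuration(
        positions=x_new, box=cfg.box.copy(), velocities=v_new, time=cfg.time + dt
    )
    T_inst = instantaneous_temperature(v_new, topo.masses, ndf)
    new_state = MDState(
        configuration=new_cfg,
        step=state.step + 1,
        temperature_inst=T_inst,
        rng=state.rng,
    )
    # on-step velocity estimate (average of the two half-step velocities);
    # makes the recorded total energy second-order accurate for leapfrog
    v_on = 0.5 * (v + v_new)
    return new_state, res, v_on


def run_simulation(
    topo: SystemTopology,
    initial: Configuration,
    evaluator,
    opts: MDOptions,
    metadata: dict | None = None,
    on_error: str = "raise",
) -> Trajectory:
    """Propagate and record a trajectory with an aligned energy series.

    Deterministic for a fixed seed: velocities (when absent from the initial
    configuration) are drawn from the Maxwell-Boltzmann distribution with the
    run seed, and all stochastic thermostat moves share the same generator.

    The energy series has one row per recorded frame with the total and the
    named Hamiltonian components, the instantaneous temperature and, for
    lambda-coupled evaluators, dH/dlambda.
    """
    rng = np.random.default_rng(opts.seed)
    cfg = initial.copy()
    if cfg.velocities is None:
        v = maxwell_boltzmann_velocities(
            topo, opts.temperature, rng, mask=opts.velocity_mask
        )
        if opts.remove_com and opts.velocity_mask is None:
            v -= np.average(v, axis=0, weights=topo.masses)
        if topo.constraints:
            v = apply_rattle_velocities(
                cfg.positions, v, topo.constraints, topo.masses, cfg.box
            )
        cfg.velocities = v
    state = MDState(configuration=cfg, rng=rng)
    ndf = n_degrees_of_freedom(topo, opts)

    frames: list[Configuration] = []
    rows: list[dict] = []
    regions = None

    def record(state: MDState, res, v_on: np.ndarray) -> None:
        c = state.configuration
        ke = kinetic_energy(v_on, topo.masses)
        row = {
            "step": state.step,
            "time": c.time,
            "potential": res.total,
            "kinetic": ke,
            "total_energy": res.total + ke,
            "temperature": instantaneous_temperature(v_on, topo.masses, ndf),
        }
        if res.dH_dlambda is not None:
            row["dH_dlambda"] = res.dH_dlambda
        for k, val in res.components.items():
            row[f"E_{k}"] = val
        rows.append(row)
        frames.append(c.copy())

    has_regions = hasattr(evaluator, "assign")
    terminated_early = None
    for step in range(opts.n_steps):
        if has_regions and (regions is None or step % opts.region_update_every == 0):
            regions = evaluator.assign(state.configuration)
        try:
            res = evaluator.evaluate(state.configuration, regions=regions)
            pre_state = state
            state, _, v_on = integrate_step(
                state, evaluator, topo, opts, regions=regions, forces=res
            )
        except (ShakeError, IntegrationError, FloatingPointError):
            if on_error != "truncate":
                raise
            terminated_early = step
            break
        if step % opts.sample_every == 0:
            record(pre_state, res, v_on)
    if terminated_early is not None:
        meta = dict(metadata or {})
        meta.update(seed=opts.seed, terminated_early=terminated_early)
        return Trajectory(
            frames=frames, energy_series=pd.DataFrame(rows), metadata=meta
        )
    # closing record at the final configuration with a half-kick velocity
    if has_regions:
        regions = evaluator.assign(state.configuration)
    res = evaluator.evaluate(state.configuration, regions=regions)
    v_on = state.configuration.velocities + res.forces / topo.masses[:, None] * (
        opts.dt / 2.0
    )
    if topo.constraints:
        v_on = apply_rattle_velocities(
            state.configuration.positions, v_on, topo.constraints, topo.masses,
            state.configuration.box,
        )
    record(state, res, v_on)

    meta = dict(metadata or {})
    meta.setdefault("seed", opts.seed)
    meta.setdefault("dt", opts.dt)
    meta.setdefault("n_steps", opts.n_steps)
    meta.setdefault("thermostat", opts.thermostat)
    return Trajectory(frames=frames, energy_series=pd.DataFrame(rows), metadata=meta)
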