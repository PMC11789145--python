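"""Classical potential energy and forces for region-scoped molecule subsets.

All MM terms of the buffer-region Hamiltonian live here: harmonic bonds and
angles, Lennard-Jones and Coulomb nonbonded interactions under the minimum
image convention with a plain cutoff, harmonic distance restraints, and the
Beutler-style soft-core form used for alchemically vanishing molecules.

Scopes realize the subscripts of the three-region energy decomposition:
``within_set`` sums all interactions internal to a set of molecules,
``between_sets`` only the nonbonded cross terms of two disjoint sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .system import (
    Configuration,
    SystemTopology,
    minimum_image_displacements,
)

__all__ = [
    "COULOMB_CONST",
    "InteractionScope",
    "MMEnergyBreakdown",
    "mm_energy_forces",
    "softcore_nonbonded",
    "softcore_pair",
    "scaled_cross_nonbonded",
    "distance_restraint_energy",
    "SingularityError",
]

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONST = 138.935458

_MIN_SEPARATION = 1e-6  # nm; closer pairs are treated as singular


class SingularityError(FloatingPointError):
    """Two interacting atoms closer than the numerical singularity guard."""


@dataclass(frozen=True)
class InteractionScope:
    kind: str                       # "within_set" | "between_sets"
    set_a: frozenset[int]
    set_b: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("within_set", "between_sets"):
            raise ValueError(f"unknown scope kind {self.kind!r}")
        if self.kind == "between_sets":
            if self.set_b is None:
                raise ValueError("between_sets requires set_b")
            if self.set_a & self.set_b:
                raise ValueError("between_sets requires disjoint sets")

    @classmethod
    def within(cls, mols: Iterable[int]) -> "InteractionScope":
        return cls("within_set", frozenset(mols))

    @classmethod
    def between(cls, a: Iterable[int], b: Iterable[int]) -> "InteractionScope":
        return cls("between_sets", frozenset(a), frozenset(b))


@dataclass
class MMEnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    restraint: float = 0.0
    forces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.lj + self.coulomb + self.restraint


def _nonbonded_pairs(
    topo: SystemTopology, scope: InteractionScope
) -> tuple[np.ndarray, np.ndarray]:
    """Atom index pairs (i, j) for the nonbonded sum of a scope (cached)."""
    cache_key = (scope.kind, scope.set_a, scope.set_b)
    cached = topo._pair_cache.get(cache_key)
    if cached is not None:
        return cached
    if scope.kind == "within_set":
        idx = topo.molecule_atom_indices(scope.set_a)
        if len(idx) < 2:
            return np.empty(0, int), np.empty(0, int)
        ii, jj = np.triu_indices(len(idx), k=1)
        i, j = idx[ii], idx[jj]
    else:
        ia = topo.molecule_atom_indices(scope.set_a)
        ib = topo.molecule_atom_indices(scope.set_b)
        if len(ia) == 0 or len(ib) == 0:
            return np.empty(0, int), np.empty(0, int)
        i, j = np.meshgrid(ia, ib, indexing="ij")
        i, j = i.ravel(), j.ravel()
    keep = ~topo.excluded_mask(i, j)
    i, j = i[keep], j[keep]
    if len(topo._pair_cache) < 4096:
        topo._pair_cache[cache_key] = (i, j)
    return i, j


def _pair_geometry(
    positions: np.ndarray, box: np.ndarray, i: np.ndarray, j: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    dvec = minimum_image_displacements(positions[j] - positions[i], box)
    r = np.linalg.norm(dvec, axis=1)
    return dvec, r


def _lj_coulomb(
    config: Configuration,
    topo: SystemTopology,
    i: np.ndarray,
    j: np.ndarray,
    cutoff: float,
) -> tuple[float, float, np.ndarray]:
    """Plain LJ + Coulomb over explicit pairs; returns (E_lj, E_c, forces)."""
    n = topo.n_atoms
    forces = np.zeros((n, 3))
    if len(i) == 0:
        return 0.0, 0.0, forces
    dvec, r = _pair_geometry(config.positions, config.box, i, j)
    within = r <= cutoff
    i, j, dvec, r = i[within], j[within], dvec[within], r[within]
    if len(i) == 0:
        return 0.0, 0.0, forces
    if np.any(r < _MIN_SEPARATION):
        raise SingularityError("overlapping atoms in nonbonded pair")
    sig = 0.5 * (topo.sigmas[i] + topo.sigmas[j])
    eps = np.sqrt(topo.epsilons[i] * topo.epsilons[j])
    qq = COULOMB_CONST * topo.charges[i] * topo.charges[j]

    inv_r = 1.0 / r
    sr6 = (sig * inv_r) ** 6
    # shifted-potential truncation: subtracting the value at the cutoff
    # keeps the energy continuous when pairs cross it (an abrupt Coulomb
    # cutoff injects energy at every crossing)
    sr6c = (sig / cutoff) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (sr6c * sr6c - sr6c)
    e_c = qq * (inv_r - 1.0 / cutoff)
    # dE/dr for each pair
    de_dr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv_r - qq * inv_r**2
    # force on j is -dE/dr * (dvec / r); on i the opposite
    fpair = (-de_dr * inv_r)[:, None] * dvec
    np.add.at(forces, j, fpair)
    np.add.at(forces, i, -fpair)
    return float(np.sum(e_lj)), float(np.sum(e_c)), forces


def _bonded_terms(
    config: Configuration, topo: SystemTopology, atom_set: set[int]
) -> tuple[float, float, np.ndarray]:
    """Harmonic bond and angle energies for terms fully inside ``atom_set``."""
    n = topo.n_atoms
    forces = np.zeros((n, 3))
    e_bond = 0.0
    pos, box = config.positions, config.box
    for bi, bj, r0, k in topo.bonds:
        if bi not in atom_set or bj not in atom_set:
            continue
        d = minimum_image_displacements(pos[bj] - pos[bi], box)
        r = float(np.linalg.norm(d))
        e_bond += 0.5 * k * (r - r0) ** 2
        f = -k * (r - r0) * d / r
        forces[bj] += f
        forces[bi] -= f
    e_angle = 0.0
    for ai, aj, ak, th0, kth in topo.angles:
        if not {ai, aj, ak} <= atom_set:
            continue
        rij = minimum_image_displacements(pos[ai] - pos[aj], box)
        rkj = minimum_image_displacements(pos[ak] - pos[aj], box)
        nij, nkj = np.linalg.norm(rij), np.linalg.norm(rkj)
        cos_t = float(np.dot(rij, rkj) / (nij * nkj))
        cos_t = min(1.0, max(-1.0, cos_t))
        theta = np.arccos(cos_t)
        e_angle += 0.5 * kth * (theta - th0) ** 2
        sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
        de_dtheta = kth * (theta - th0)
        # F_i = dV/dtheta * (r_kj_hat - cos(t) r_ij_hat) / (|r_ij| sin t)
        fi = de_dtheta / (nij * sin_t) * (rkj / nkj - cos_t * rij / nij)
        fk = de_dtheta / (nkj * sin_t) * (rij / nij - cos_t * rkj / nkj)
        forces[ai] += fi
        forces[ak] += fk
        forces[aj] -= fi + fk
    return e_bond, e_angle, forces


def distance_restraint_energy(
    config: Configuration,
    restraints: list[tuple[int, int, float, float]],
) -> tuple[float, np.ndarray]:
    """Full-harmonic distance restraints: E = 1/2 kr (d - d0)^2 per term."""
    n = config.positions.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    for i, j, d0, kr in restraints:
        dvec = minimum_image_displacements(
            config.positions[j] - config.positions[i], config.box
        )
        d = float(np.linalg.norm(dvec))
        energy += 0.5 * kr * (d - d0) ** 2
        if d > _MIN_SEPARATION:
            f = -kr * (d - d0) * dvec / d
            forces[j] += f
            forces[i] -= f
    return energy, forces


def mm_energy_forces(
    config: Configuration,
    topo: SystemTopology,
    scope: InteractionScope,
    cutoff: float = 1.4,
    include_restraints: bool = False,
) -> MMEnergyBreakdown:
    """MM energy and forces for a scope.

    Bonded terms (and, if requested, restraints) are counted only when every
    participating atom lies inside a ``within_set`` scope; ``between_sets``
    scopes contain nonbonded cross terms only.
    """
    out = MMEnergyBreakdown(forces=np.zeros((topo.n_atoms, 3)))
    i, j = _nonbonded_pairs(topo, scope)
    e_lj, e_c, f_nb = _lj_coulomb(config, topo, i, j, cutoff)
    out.lj, out.coulomb = e_lj, e_c
    out.forces += f_nb
    if scope.kind == "within_set":
        atom_set = set(topo.molecule_atom_indices(scope.set_a).tolist())
        e_b, e_a, f_b = _bonded_terms(config, topo, atom_set)
        out.bond, out.angle = e_b, e_a
        out.forces += f_b
        if include_restraints:
            inside = [
                r for r in topo.restraints if r[0] in atom_set and r[1] in atom_set
            ]
            e_r, f_r = distance_restraint_energy(config, inside)
            out.restraint = e_r
            out.forces += f_r
    return out


# ---------------------------------------------------------------------------
# Soft-core nonbonded interactions (Beutler-style)
# ---------------------------------------------------------------------------

def softcore_pair(
    r: float | np.ndarray,
    lam: float,
    state: str,
    q_prod: float | np.ndarray,
    sigma: float | np.ndarray,
    epsilon: float | np.ndarray,
    alpha_lj: float,
    alpha_c: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Soft-core LJ + Coulomb for one pair; returns (E, dE/dr, dE/dlam).

    A state-A molecule is fully coupled at lambda=0 and vanishes at
    lambda=1: its interactions carry weight (1-lambda) and a softening
    coordinate s=lambda in the Beutler denominators

        E_LJ = 4 eps w [ sig^12/(a_lj sig^6 s + r^6)^2 - sig^6/(a_lj sig^6 s + r^6) ]
        E_C  = w f q_i q_j / sqrt(a_c s + r^2)

    with the roles of w and s mirrored for state B.  At alpha=0 this
    reduces to plain linear coupling w * E_plain(r).
    """
    if alpha_lj < 0 or alpha_c < 0:
        raise ValueError("soft-core alphas must be non-negative")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if state == "A":
        w, s, dw, ds = 1.0 - lam, lam, -1.0, 1.0
    elif state == "B":
        w, s, dw, ds = lam, 1.0 - lam, 1.0, -1.0
    else:
        raise ValueError("state must be 'A' or 'B'")
    r = np.asarray(r, dtype=float)
    sig6 = np.asarray(sigma, dtype=float) ** 6
    r6 = r**6
    denom_lj = alpha_lj * sig6 * s + r6
    a = sig6 / denom_lj          # (sig/r_soft)^6 analogue
    e_lj_core = 4.0 * np.asarray(epsilon) * (a * a - a)
    denom_c = alpha_c * s + r * r
    e_c_core = COULOMB_CONST * np.asarray(q_prod) / np.sqrt(denom_c)
    energy = w * (e_lj_core + e_c_core)

    # r-derivatives
    dlj_dr = 4.0 * np.asarray(epsilon) * (2.0 * a - 1.0) * (-sig6 / denom_lj**2) * 6.0 * r**5
    dc_dr = -COULOMB_CONST * np.asarray(q_prod) * r / denom_c**1.5
    de_dr = w * (dlj_dr + dc_dr)

    # lambda-derivatives: through the weight and through the softening
    dlj_ds = 4.0 * np.asarray(epsilon) * (2.0 * a - 1.0) * (-sig6 / denom_lj**2) * alpha_lj * sig6
    dc_ds = -0.5 * COULOMB_CONST * np.asarray(q_prod) * alpha_c / denom_c**1.5
    de_dlam = dw * (e_lj_core + e_c_core) + w * ds * (dlj_ds + dc_ds)
    return energy, de_dr, de_dlam


def softcore_nonbonded(
    r: float,
    lam: float,
    state: str,
    q_prod: float,
    sigma: float,
    epsilon: float,
    alpha_lj: float,
    alpha_c: float,
) -> float:
    """Soft-core pair energy (scalar convenience wrapper)."""
    e, _, _ = softcore_pair(r, lam, state, q_prod, sigma, epsilon, alpha_lj, alpha_c)
    return float(e)


def scaled_cross_nonbonded(
    config: Configuration,
    topo: SystemTopology,
    mols: Iterable[int],
    env_mols: Iterable[int],
    lam: float,
    state: str,
    cutoff: float = 1.4,
    alpha_lj: float = 0.0,
    alpha_c: float = 0.0,
) -> tuple[float, np.ndarray, float]:
    """Lambda-coupled nonbonded energy between an end-state molecule set and
    its environment.

    Returns (energy, forces, dE/dlambda).  With both alphas zero this is the
    plain linear coupling w * V_plain; with positive alphas the Beutler
    soft-core form.  The fully-coupled endpoint (w=1, s=0) recovers the plain
    potential exactly.
    """
    scope = InteractionScope.between(mols, env_mols)
    i, j = _nonbonded_pairs(topo, scope)
    forces = np.zeros((topo.n_atoms, 3))
    if len(i) == 0:
        return 0.0, forces, 0.0
    dvec, r = _pair_geometry(config.positions, config.box, i, j)
    within = r <= cutoff
    i, j, dvec, r = i[within], j[within], dvec[within], r[within]
    if len(i) == 0:
        return 0.0, forces, 0.0
    if np.any(r < _MIN_SEPARATION) and not (alpha_lj > 0 or alpha_c > 0):
        raise SingularityError("overlapping atoms in scaled nonbonded pair")
    sig = 0.5 * (topo.sigmas[i] + topo.sigmas[j])
    eps = np.sqrt(topo.epsilons[i] * topo.epsilons[j])
    qq = topo.charges[i] * topo.charges[j]
    e, de_dr, de_dlam = softcore_pair(r, lam, state, qq, sig, eps, alpha_lj, alpha_c)
    # shifted-potential truncation, consistent in the lambda-derivative
    e_c, _, dlam_c = softcore_pair(
        np.full_like(r, cutoff), lam, state, qq, sig, eps, alpha_lj, alpha_c
    )
    e = e - e_c
    de_dlam = de_dlam - dlam_c
    fpair = (-de_dr / r)[:, None] * dvec
    np.add.at(forces, j, fpair)
    np.add.at(forces, i, -fpair)
    return float(np.sum(e)), forces, float(np.sum(de_dlam))


def cluster_delta_baseline(
    config: Configuration,
    topo: SystemTopology,
    inner_idx: np.ndarray,
    buffer_idx: np.ndarray,
) -> tuple[float, np.ndarray]:
    """MM-level analogue of the delta energy V(I+Buf) - V(Buf).

    Buffer-internal terms cancel in the difference, leaving the inner
    region's bonded terms plus the plain LJ/Coulomb interactions of inner
    atoms with everything in the cluster (no cutoff; the same unwrapped
    cluster geometry the reference engine sees).  Used as the physical
    baseline for residual (delta-) learning: the regressor only has to
    learn the reference-minus-MM difference, and the MM walls bound the
    model surface far from the training data.

    Returns (energy, forces) with force rows ordered inner atoms first,
    then buffer atoms.
    """
    inner_idx = np.asarray(inner_idx, int)
    buffer_idx = np.asarray(buffer_idx, int)
    sub = np.concatenate([inner_idx, buffer_idx])
    m, ni = len(sub), len(inner_idx)
    ref = config.positions[sub[0]]
    pos = ref + minimum_image_displacements(config.positions[sub] - ref, config.box)
    local = {int(a): k for k, a in enumerate(sub)}
    forces = np.zeros((m, 3))
    energy = 0.0

    for bi, bj, r0, k in topo.bonds:
        if bi in local and bj in local and local[bi] < ni and local[bj] < ni:
            a, b = local[bi], local[bj]
            d = pos[b] - pos[a]
            r = float(np.linalg.norm(d))
            energy += 0.5 * k * (r - r0) ** 2
            f = -k * (r - r0) * d / r
            forces[b] += f
            forces[a] -= f
    for ai, aj, ak, th0, kth in topo.angles:
        if all(x in local and local[x] < ni for x in (ai, aj, ak)):
            a, j, c = local[ai], local[aj], local[ak]
            rij = pos[a] - pos[j]
            rkj = pos[c] - pos[j]
            nij, nkj = np.linalg.norm(rij), np.linalg.norm(rkj)
            cos_t = min(1.0, max(-1.0, float(np.dot(rij, rkj) / (nij * nkj))))
            theta = np.arccos(cos_t)
            energy += 0.5 * kth * (theta - th0) ** 2
            sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
            de = kth * (theta - th0)
            fi = de / (nij * sin_t) * (rkj / nkj - cos_t * rij / nij)
            fk = de / (nkj * sin_t) * (rij / nij - cos_t * rkj / nkj)
            forces[a] += fi
            forces[c] += fk
            forces[j] -= fi + fk

    if m >= 2 and ni >= 1:
        ii, jj = np.triu_indices(m, k=1)
        keep = (ii < ni) | (jj < ni)          # at least one inner atom
        ii, jj = ii[keep], jj[keep]
        keep2 = ~topo.excluded_mask(sub[ii], sub[jj])
        ii, jj = ii[keep2], jj[keep2]
        if len(ii):
            dvec = pos[jj] - pos[ii]
            r = np.linalg.norm(dvec, axis=1)
            if np.any(r < _MIN_SEPARATION):
                raise SingularityError("overlapping atoms in baseline cluster")
            gi, gj = sub[ii], sub[jj]
            sig = 0.5 * (topo.sigmas[gi] + topo.sigmas[gj])
            eps = np.sqrt(topo.epsilons[gi] * topo.epsilons[gj])
            qq = COULOMB_CONST * topo.charges[gi] * topo.charges[gj]
            inv_r = 1.0 / r
            sr6 = (sig * inv_r) ** 6
            energy += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6) + qq * inv_r))
            de_dr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv_r - qq * inv_r**2
            fpair = (-de_dr * inv_r)[:, None] * dvec
            np.add.at(forces, jj, fpair)
            np.add.at(forces, ii, -fpair)
    return energy, forces
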