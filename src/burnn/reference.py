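"""Reference ("QM") engine contract and the built-in analytic mock engine.

The buffer-region scheme needs two subset energies per configuration,
V(I+Buf) and V(Buf), whose difference is the delta-learning target.  A real
deployment would obtain them from a semiempirical or DFT code; here a
stateless analytic engine stands in so that training, dynamics and FEP are
exercisable offline.

The mock functional deliberately contains a nonadditive many-body term (an
embedding-density contribution, plus density-dependent charge scaling as a
crude polarization proxy) so that the delta energy is *not* reproducible by
any pairwise MM decomposition — the structural premise that makes the buffer
region and the delta model worth having.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .forcefield import COULOMB_CONST
from .system import Configuration, SystemTopology, minimum_image_displacements

__all__ = [
    "MockQMParams",
    "MockQMEngine",
    "ReferenceEngine",
    "ReferenceEvaluation",
    "ReferenceEngineError",
    "reference_energy",
    "delta_reference",
    "unwrap_subset",
]


class ReferenceEngineError(RuntimeError):
    """Engine failure; carries the offending subset for diagnosis."""


@dataclass
class ReferenceEvaluation:
    energy: float                  # kJ/mol
    forces: np.ndarray             # (m, 3) kJ/mol/nm, rows follow ``subset``
    subset: list[int]


class ReferenceEngine(Protocol):
    """Stateless subset-energy engine: cluster geometry in, energy/forces out."""

    def evaluate(
        self, positions: np.ndarray, atom_ids: Sequence[int]
    ) -> tuple[float, np.ndarray]: ...


@dataclass
class MockQMParams:
    """Parameters of the analytic mock engine.

    Bonded terms reuse the MM topology with shifted equilibrium values and
    stiffer force constants, mimicking a change in level of theory.  The
    density-dependent charge scaling and the embedding term provide the
    many-body "polarization" that distinguishes the reference from the MM
    description of the same geometry.
    """

    bond_r0_scale: float = 0.97
    bond_k_scale: float = 1.15
    angle_theta0_scale: float = 0.99
    angle_k_scale: float = 1.10
    charge_scale: float = 0.03      # dimensionless per unit density
    density_width: float = 0.35     # nm, Gaussian width of the local density
    embed_amplitude: float = -2.0   # kJ/mol, attractive embedding
    embed_eps: float = 0.05         # regularizer inside the square root
    rep_amplitude: float = 50000.0  # kJ/mol, Born-Mayer exchange repulsion
    rep_range: float = 0.025        # nm

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "MockQMParams":
        return cls(**d)


class MockQMEngine:
    """Analytic stand-in for a quantum-chemistry engine.

    Energy of an atom subset (treated as an isolated cluster, no periodicity):

    * harmonic bonds/angles of the MM topology whose atoms all lie in the
      subset, with scaled equilibrium values and force constants;
    * plain Lennard-Jones over non-excluded subset pairs;
    * a Born-Mayer exchange-repulsion core b exp(-r/rho0) on all non-excluded
      pairs (electrons repel everywhere — unlike an MM force field, no atom
      is a bare point charge at this level);
    * Coulomb with density-scaled charges q_i (1 + c rho_i);
    * an embedding term  A sum_i [sqrt(rho_i + e0) - sqrt(e0)]  with
      rho_i = sum_j exp(-r_ij^2 / w^2).

    All terms are exactly differentiable; forces are analytic.
    """

    name = "mock_qm"

    def __init__(self, topo: SystemTopology, params: MockQMParams | None = None):
        self.topo = topo
        self.params = params or MockQMParams()

    # -- main entry ------------------------------------------------------
    def evaluate(
        self, positions: np.ndarray, atom_ids: Sequence[int]
    ) -> tuple[float, np.ndarray]:
        if len(atom_ids) == 0:
            raise ReferenceEngineError("empty subset")
        pos = np.asarray(positions, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ReferenceEngineError(f"non-finite positions for subset {list(atom_ids)}")
        ids = np.asarray(atom_ids, dtype=int)
        m = len(ids)
        local = {int(a): k for k, a in enumerate(ids)}
        p = self.params
        forces = np.zeros((m, 3))
        energy = 0.0

        # bonded terms restricted to the subset
        for bi, bj, r0, k in self.topo.bonds:
            if bi in local and bj in local:
                a, b = local[bi], local[bj]
                d = pos[b] - pos[a]
                r = float(np.linalg.norm(d))
                r0s, ks = r0 * p.bond_r0_scale, k * p.bond_k_scale
                energy += 0.5 * ks * (r - r0s) ** 2
                f = -ks * (r - r0s) * d / r
                forces[b] += f
                forces[a] -= f
        for ai, aj, ak, th0, kth in self.topo.angles:
            if ai in local and aj in local and ak in local:
                a, j, c = local[ai], local[aj], local[ak]
                rij = pos[a] - pos[j]
                rkj = pos[c] - pos[j]
                nij, nkj = np.linalg.norm(rij), np.linalg.norm(rkj)
                cos_t = float(np.dot(rij, rkj) / (nij * nkj))
                cos_t = min(1.0, max(-1.0, cos_t))
                theta = np.arccos(cos_t)
                th0s, kths = th0 * p.angle_theta0_scale, kth * p.angle_k_scale
                energy += 0.5 * kths * (theta - th0s) ** 2
                sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
                de = kths * (theta - th0s)
                fi = de / (nij * sin_t) * (rkj / nkj - cos_t * rij / nij)
                fk = de / (nkj * sin_t) * (rij / nij - cos_t * rkj / nkj)
                forces[a] += fi
                forces[c] += fk
                forces[j] -= fi + fk

        if m >= 2:
            e_nb, f_nb = self._nonbonded_manybody(pos, ids, local)
            energy += e_nb
            forces += f_nb
        return energy, forces

    def _nonbonded_manybody(
        self, pos: np.ndarray, ids: np.ndarray, local: dict[int, int]
    ) -> tuple[float, np.ndarray]:
        p = self.params
        m = len(ids)
        ii, jj = np.triu_indices(m, k=1)
        dvec = pos[jj] - pos[ii]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-6):
            raise ReferenceEngineError("overlapping atoms in mock engine subset")

        # local Gaussian density (all pairs, including excluded ones)
        w2 = p.density_width**2
        phi = np.exp(-(r**2) / w2)
        rho = np.zeros(m)
        np.add.at(rho, ii, phi)
        np.add.at(rho, jj, phi)
        s = 1.0 + p.charge_scale * rho

        q = self.topo.charges[ids]
        sig_i = self.topo.sigmas[ids]
        eps_i = self.topo.epsilons[ids]
        incl = ~self.topo.excluded_mask(ids[ii], ids[jj])

        sig = 0.5 * (sig_i[ii] + sig_i[jj])
        eps = np.sqrt(eps_i[ii] * eps_i[jj])
        inv_r = 1.0 / r
        sr6 = (sig * inv_r) ** 6
        e_lj = np.where(incl, 4.0 * eps * (sr6 * sr6 - sr6), 0.0)
        e_rep = np.where(incl, p.rep_amplitude * np.exp(-r / p.rep_range), 0.0)
        qq = COULOMB_CONST * q[ii] * q[jj] * s[ii] * s[jj]
        e_c = np.where(incl, qq * inv_r, 0.0)

        e_embed = p.embed_amplitude * np.sum(
            np.sqrt(rho + p.embed_eps) - np.sqrt(p.embed_eps)
        )
        energy = float(np.sum(e_lj) + np.sum(e_rep) + np.sum(e_c)) + float(e_embed)

        # dE/drho_i: through charge scaling and through the embedding
        g = p.embed_amplitude * 0.5 / np.sqrt(rho + p.embed_eps)
        # charge-scaling channel: E_c = sum f q_a q_b s_a s_b / r_ab
        #   dE/ds_i = sum_j f q_i q_j s_j / r_ij  (over included pairs)
        ds = np.zeros(m)
        coul_base = np.where(incl, COULOMB_CONST * q[ii] * q[jj] * inv_r, 0.0)
        np.add.at(ds, ii, coul_base * s[jj])
        np.add.at(ds, jj, coul_base * s[ii])
        g = g + p.charge_scale * ds

        # radial derivatives per pair
        de_dr = np.where(
            incl,
            4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv_r
            - qq * inv_r**2
            - p.rep_amplitude / p.rep_range * np.exp(-r / p.rep_range),
            0.0,
        )
        dphi_dr = -2.0 * r / w2 * phi
        de_dr = de_dr + (g[ii] + g[jj]) * dphi_dr

        forces = np.zeros((m, 3))
        fpair = (-de_dr * inv_r)[:, None] * dvec
        np.add.at(forces, jj, fpair)
        np.add.at(forces, ii, -fpair)
        return energy, forces


def unwrap_subset(
    config: Configuration, subset: Sequence[int]
) -> np.ndarray:
    """Make a subset whole across periodic boundaries.

    Atoms are mapped to their minimum image relative to the first subset atom,
    which yields a consistent cluster geometry as long as the subset diameter
    stays below half the box length (true for inner+buffer clusters in the
    toy systems).
    """
    idx = np.asarray(subset, dtype=int)
    ref = config.positions[idx[0]]
    d = minimum_image_displacements(config.positions[idx] - ref, config.box)
    return ref + d


def reference_energy(
    config: Configuration,
    subset: Sequence[int],
    engine: ReferenceEngine,
) -> ReferenceEvaluation:
    """Reference (mock-QM) energy of an atom subset treated as a cluster.

    Depends only on the subset-internal geometry: the subset is unwrapped
    across periodic boundaries and evaluated without periodicity, so the
    result is invariant under rigid translation and rotation.
    """
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("reference_energy requires a nonempty subset")
    pos = unwrap_subset(config, subset)
    energy, forces = engine.evaluate(pos, subset)
    if not np.isfinite(energy):
        raise ReferenceEngineError(f"engine returned non-finite energy for {subset}")
    return ReferenceEvaluation(energy=float(energy), forces=forces, subset=subset)


def delta_reference(
    config: Configuration,
    inner_atoms: Sequence[int],
    buffer_atoms: Sequence[int],
    engine: ReferenceEngine,
) -> ReferenceEvaluation:
    """Delta energy V(I+Buf) - V(Buf) from two explicit engine calls.

    This is the ground truth the delta model is trained on.  Forces on inner
    atoms come from the first evaluation only; forces on buffer atoms are the
    difference of the two evaluations.  An empty inner set gives zero by
    definition; an empty buffer reduces to the plain inner-region energy.
    """
    inner_atoms = list(inner_atoms)
    buffer_atoms = list(buffer_atoms)
    if set(inner_atoms) & set(buffer_atoms):
        raise ValueError("inner and buffer atom sets must be disjoint")
    subset = inner_atoms + buffer_atoms
    if not inner_atoms:
        return ReferenceEvaluation(
            energy=0.0, forces=np.zeros((len(buffer_atoms), 3)), subset=buffer_atoms
        )
    ev_both = reference_energy(config, subset, engine)
    if not buffer_atoms:
        return ev_both
    ev_buf = reference_energy(config, buffer_atoms, engine)
    forces = ev_both.forces.copy()
    forces[len(inner_atoms):] -= ev_buf.forces
    return ReferenceEvaluation(
        energy=ev_both.energy - ev_buf.energy, forces=forces, subset=subset
    )
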