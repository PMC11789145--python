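"""MM terms: scoped energies, soft-core coupling, restraints, forces."""

import numpy as np
import pytest

import burnn
from burnn.forcefield import (
    COULOMB_CONST,
    InteractionScope,
    SingularityError,
    cluster_delta_baseline,
    distance_restraint_energy,
    mm_energy_forces,
    scaled_cross_nonbonded,
    softcore_nonbonded,
    softcore_pair,
)
from burnn.system import Atom, Configuration, SystemTopology, minimum_image_vector

BIG_CUTOFF = 1e3   # effectively no truncation (shift term vanishes)


def _two_atom_system(sigma=0.3, epsilon=0.5, q=(0.0, 0.0), r=0.4):
    topo = SystemTopology(
        atoms=[
            Atom(0, "X", 10.0, q[0], sigma, epsilon, molecule_id=0),
            Atom(1, "Y", 10.0, q[1], sigma, epsilon, molecule_id=1),
        ],
        inner_molecule_ids={0},
    )
    config = Configuration(
        positions=np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]]),
        box=np.array([10.0, 10.0, 10.0]),
    )
    return topo, config


class TestMMEnergy:
    def test_lj_minimum_is_minus_epsilon(self):
        r = 2 ** (1 / 6) * 0.3
        topo, config = _two_atom_system(r=r)
        res = mm_energy_forces(config, topo, InteractionScope.within({0, 1}), BIG_CUTOFF)
        assert res.lj == pytest.approx(-0.5, rel=1e-9)
        assert res.coulomb == 0.0

    def test_single_atom_scope_is_zero(self):
        topo, config = _two_atom_system()
        res = mm_energy_forces(config, topo, InteractionScope.within({0}), BIG_CUTOFF)
        assert res.total == 0.0

    def test_matches_naive_double_loop(self, toy_small):
        # oracle: independent naive sum over all pairs with the same physics
        topo, config = toy_small
        mols = set(topo.all_molecule_ids())
        cutoff = 0.9
        res = mm_energy_forces(config, topo, InteractionScope.within(mols), cutoff)
        e_naive = 0.0
        n = topo.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if topo.is_excluded(i, j):
                    continue
                d = np.linalg.norm(minimum_image_vector(
                    config.positions[i], config.positions[j], config.box))
                if d > cutoff:
                    continue
                sig = 0.5 * (topo.sigmas[i] + topo.sigmas[j])
                eps = np.sqrt(topo.epsilons[i] * topo.epsilons[j])
                sr6 = (sig / d) ** 6
                sr6c = (sig / cutoff) ** 6
                e_naive += 4 * eps * (sr6**2 - sr6) - 4 * eps * (sr6c**2 - sr6c)
                qq = COULOMB_CONST * topo.charges[i] * topo.charges[j]
                e_naive += qq * (1 / d - 1 / cutoff)
        assert res.lj + res.coulomb == pytest.approx(e_naive, rel=1e-9)

    def test_scope_additivity(self, toy_small):
        topo, config = toy_small
        mols = sorted(topo.all_molecule_ids())
        a, b = set(mols[: len(mols) // 2]), set(mols[len(mols) // 2 :])
        whole = mm_energy_forces(config, topo, InteractionScope.within(a | b), 0.9)
        pa = mm_energy_forces(config, topo, InteractionScope.within(a), 0.9)
        pb = mm_energy_forces(config, topo, InteractionScope.within(b), 0.9)
        cross = mm_energy_forces(config, topo, InteractionScope.between(a, b), 0.9)
        assert whole.total == pytest.approx(pa.total + pb.total + cross.total, abs=1e-9)

    def test_overlap_raises_singularity(self):
        topo, config = _two_atom_system(r=1e-8, q=(0.1, -0.1))
        with pytest.raises(SingularityError):
            mm_energy_forces(config, topo, InteractionScope.within({0, 1}), BIG_CUTOFF)

    def test_forces_match_finite_differences(self, toy_small):
        topo, config = toy_small
        scope = InteractionScope.within(set(topo.all_molecule_ids()))
        res = mm_energy_forces(config, topo, scope, 0.9)
        eps = 1e-6
        rng = np.random.default_rng(3)
        for a in rng.choice(topo.n_atoms, 4, replace=False):
            for c in range(3):
                p = config.copy(); p.positions[a, c] += eps
                m = config.copy(); m.positions[a, c] -= eps
                fd = -(mm_energy_forces(p, topo, scope, 0.9).total
                       - mm_energy_forces(m, topo, scope, 0.9).total) / (2 * eps)
                assert fd == pytest.approx(res.forces[a, c], rel=1e-5, abs=1e-4)


class TestSoftcore:
    def test_fully_coupled_endpoint_equals_plain(self):
        r, sig, eps, qq = 0.35, 0.3, 0.6, 0.1
        plain = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6) + COULOMB_CONST * qq / r
        got = softcore_nonbonded(r, 0.0, "A", qq, sig, eps, 0.5, 0.0025)
        assert got == pytest.approx(plain, rel=1e-12)
        got_b = softcore_nonbonded(r, 1.0, "B", qq, sig, eps, 0.5, 0.0025)
        assert got_b == pytest.approx(plain, rel=1e-12)

    def test_large_separation_vanishes(self):
        # LJ part decays as r^-6; the Coulomb part as 1/r
        assert abs(softcore_nonbonded(50.0, 0.3, "A", 0.0, 0.3, 0.6, 0.5, 0.0025)) < 1e-9
        assert abs(softcore_nonbonded(1e4, 0.3, "A", 0.1, 0.3, 0.6, 0.5, 0.0025)) < 2e-3

    def test_alpha_zero_reduces_to_linear_coupling(self):
        r, sig, eps, qq = 0.35, 0.3, 0.6, 0.1
        plain = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6) + COULOMB_CONST * qq / r
        got = softcore_nonbonded(r, 0.5, "A", qq, sig, eps, 0.0, 0.0)
        assert got == pytest.approx(0.5 * plain, rel=1e-12)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            softcore_nonbonded(0.3, 0.5, "A", 0.1, 0.3, 0.6, -0.1, 0.0)

    def test_lambda_derivative_matches_finite_difference(self):
        r, sig, eps, qq = np.array([0.3]), 0.31, 0.7, -0.05
        for lam in (0.2, 0.8):
            _, _, dl = softcore_pair(r, lam, "A", qq, sig, eps, 0.5, 0.0025)
            h = 1e-6
            ep, _, _ = softcore_pair(r, lam + h, "A", qq, sig, eps, 0.5, 0.0025)
            em, _, _ = softcore_pair(r, lam - h, "A", qq, sig, eps, 0.5, 0.0025)
            assert dl[0] == pytest.approx((ep[0] - em[0]) / (2 * h), rel=1e-5)

    def test_scaled_cross_forces_consistent(self, toy_small):
        topo, config = toy_small
        env = set(topo.all_molecule_ids()) - {0, 1}
        e0, forces, _ = scaled_cross_nonbonded(
            config, topo, {0}, env, 0.4, "A", 0.9, 0.5, 0.0025)
        eps = 1e-6
        for a in (0, 1, 2):
            for c in range(3):
                p = config.copy(); p.positions[a, c] += eps
                m = config.copy(); m.positions[a, c] -= eps
                fd = -(scaled_cross_nonbonded(p, topo, {0}, env, 0.4, "A", 0.9, 0.5, 0.0025)[0]
                       - scaled_cross_nonbonded(m, topo, {0}, env, 0.4, "A", 0.9, 0.5, 0.0025)[0]) / (2 * eps)
                assert fd == pytest.approx(forces[a, c], rel=1e-4, abs=1e-4)


class TestRestraints:
    def test_at_reference_distance_zero(self):
        config = Configuration(
            positions=np.array([[1.0, 1, 1], [1.3, 1, 1]]), box=np.array([5.0, 5, 5]))
        e, f = distance_restraint_energy(config, [(0, 1, 0.3, 1000.0)])
        assert e == pytest.approx(0.0, abs=1e-12) and np.allclose(f, 0.0, atol=1e-10)

    def test_half_k_dx_squared(self):
        config = Configuration(
            positions=np.array([[1.0, 1, 1], [1.4, 1, 1]]), box=np.array([5.0, 5, 5]))
        e, _ = distance_restraint_energy(config, [(0, 1, 0.3, 1000.0)])
        assert e == pytest.approx(0.5 * 1000.0 * 0.1**2)   # 5.0 kJ/mol

    def test_force_matches_finite_difference(self):
        rng = np.random.default_rng(1)
        config = Configuration(positions=rng.uniform(1, 2, (2, 3)), box=np.array([5.0, 5, 5]))
        restraints = [(0, 1, 0.25, 700.0)]
        _, f = distance_restraint_energy(config, restraints)
        eps = 1e-6
        for a in (0, 1):
            for c in range(3):
                p = config.copy(); p.positions[a, c] += eps
                m = config.copy(); m.positions[a, c] -= eps
                fd = -(distance_restraint_energy(p, restraints)[0]
                       - distance_restraint_energy(m, restraints)[0]) / (2 * eps)
                assert fd == pytest.approx(f[a, c], rel=1e-6, abs=1e-8)


def test_cluster_baseline_forces_consistent(toy_small):
    topo, config = toy_small
    inner = topo.molecule_atom_indices({0})
    buf = topo.molecule_atom_indices({2, 3})
    e0, f0 = cluster_delta_baseline(config, topo, inner, buf)
    sub = np.concatenate([inner, buf])
    eps = 1e-6
    for k, a in enumerate(sub[:5]):
        for c in range(3):
            p = config.copy(); p.positions[a, c] += eps
            m = config.copy(); m.positions[a, c] -= eps
            fd = -(cluster_delta_baseline(p, topo, inner, buf)[0]
                   - cluster_delta_baseline(m, topo, inner, buf)[0]) / (2 * eps)
            assert fd == pytest.approx(f0[k, c], rel=1e-4, abs=1e-4)
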