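"""Composed buffer-region and lambda-coupled Hamiltonians."""

import numpy as np
import pytest

import burnn
from burnn.forcefield import distance_restraint_energy
from burnn.hamiltonian import (
    BurnnEvaluator,
    InterpolatedEvaluator,
    MMPerturbedEvaluator,
    PerturbedBurnnEvaluator,
    burnn_energy,
    dH_dlambda,
    mm_burnn_interpolation,
)
from burnn.reference import MockQMEngine
from burnn.system import Atom, Configuration, SystemTopology


MM_CUTOFF = 1.0


@pytest.fixture(scope="module")
def burqm_setup(toy50, engine50):
    topo, config = toy50
    pe = PerturbedBurnnEvaluator(topo, 0.35, engine=engine50,
                                 buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF)
    return topo, config, engine50, pe


class TestBurnnEnergy:
    def test_component_sum_equals_total(self, burqm_setup):
        topo, config, engine, _ = burqm_setup
        res = burnn_energy(config, topo, engine=engine, mm_cutoff=MM_CUTOFF)
        assert res.total == pytest.approx(res.weighted_sum(), rel=1e-12)

    def test_empty_buffer_and_outer_reduces_to_inner_energy(self):
        spec = burnn.ToySystemSpec(n_solvent=0)
        topo, config = burnn.build_toy_system(spec, seed=0)
        engine = MockQMEngine(topo)
        res = burnn_energy(config, topo, engine=engine, mm_cutoff=MM_CUTOFF)
        from burnn.reference import delta_reference
        inner = topo.molecule_atom_indices(topo.inner_molecule_ids)
        expected = delta_reference(config, inner.tolist(), [], engine).energy
        e_r, _ = distance_restraint_energy(config, topo.restraints)
        assert res.total == pytest.approx(expected + e_r, abs=1e-10)

    def test_burqm_vs_burnn_within_model_error(self, toy50, trained_models):
        topo, _ = toy50
        engine = MockQMEngine(topo)
        models, start = trained_models
        reg = burnn.assign_regions(start, topo, 0.5)
        inner = topo.molecule_atom_indices({0})
        buf = topo.molecule_atom_indices(reg.buffer)
        from burnn.reference import delta_reference
        truth = delta_reference(start, inner.tolist(), buf.tolist(), engine).energy
        pred, _ = models["delta_A"].predict_config(start, topo, inner, buf)
        bound = 3.0 * max(max(models["delta_A"].holdout_rmse), 0.5)
        assert abs(pred - truth) < bound


class TestPerturbedHamiltonian:
    def test_endpoint_identity_lambda0(self, burqm_setup):
        topo, config, engine, _ = burqm_setup
        pe0 = PerturbedBurnnEvaluator(topo, 0.0, engine=engine,
                                      buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF)
        regions = pe0.assign(config)
        total = pe0.evaluate(config, regions=regions).total
        pure_a = BurnnEvaluator(topo, mode="burqm", engine=engine,
                                buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF,
                                inner_molecules={0})
        res_a = pure_a.evaluate(config, regions=regions)
        from burnn.reference import reference_energy
        intra_b = reference_energy(
            config, topo.molecule_atom_indices({1}).tolist(), engine).energy
        assert abs(total - (res_a.total + intra_b)) < 1e-10

    def test_dhdl_matches_central_difference(self, burqm_setup):
        topo, config, engine, pe = burqm_setup
        regions = pe.assign(config)
        analytic = pe.evaluate(config, regions=regions).dH_dlambda
        d = 1e-4
        ep = PerturbedBurnnEvaluator(topo, 0.35 + d, engine=engine,
                                     buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF
                                     ).evaluate(config, regions=regions).total
        em = PerturbedBurnnEvaluator(topo, 0.35 - d, engine=engine,
                                     buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF
                                     ).evaluate(config, regions=regions).total
        fd = (ep - em) / (2 * d)
        assert analytic == pytest.approx(fd, rel=1e-6)

    def test_dhdl_lambda_independent_for_linear_coupling(self, burqm_setup):
        topo, config, engine, _ = burqm_setup
        regions = PerturbedBurnnEvaluator(
            topo, 0.1, engine=engine, buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF
        ).assign(config)
        d1 = dH_dlambda(config, topo, regions=regions, lam=0.1, engine=engine,
                        buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF)
        d2 = dH_dlambda(config, topo, regions=regions, lam=0.9, engine=engine,
                        buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF)
        assert d1 == pytest.approx(d2, rel=1e-10)

    def test_identical_end_states_cancel(self):
        """With A and B identical molecules at identical coordinates the
        lambda-derivative vanishes and the coupled term is weight-balanced."""
        atoms = [
            Atom(0, "Q", 16.0, -0.2, 0.3, 0.6, molecule_id=0, dual_state="A"),
            Atom(1, "Q", 16.0, -0.2, 0.3, 0.6, molecule_id=1, dual_state="B"),
            Atom(2, "OW", 16.0, 0.2, 0.31, 0.65, molecule_id=2),
        ]
        topo = SystemTopology(
            atoms=atoms, inner_molecule_ids={0, 1}, exclusions={(0, 1)},
        )
        config = Configuration(
            positions=np.array([[2.0, 2, 2], [2.0, 2, 2.0 + 1e-12], [2.35, 2, 2]]),
            box=np.array([4.0, 4, 4]),
        )
        engine = MockQMEngine(topo)
        res = PerturbedBurnnEvaluator(
            topo, 0.5, engine=engine, buffer_cutoff=0.5, mm_cutoff=1.5
        ).evaluate(config)
        assert res.dH_dlambda == pytest.approx(0.0, abs=1e-6)
        # weights (1-lam) + lam sum to one: coupled value equals either end
        res0 = PerturbedBurnnEvaluator(
            topo, 0.0, engine=engine, buffer_cutoff=0.5, mm_cutoff=1.5
        ).evaluate(config)
        assert res.total == pytest.approx(res0.total, abs=1e-6)

    def test_missing_intra_model_raises(self, toy50):
        topo, _ = toy50
        with pytest.raises(ValueError, match="intra"):
            PerturbedBurnnEvaluator(topo, 0.5, models={"delta_A": None,
                                                       "delta_B": None})

    def test_model_forces_match_finite_differences(self, toy50, trained_models):
        topo, _ = toy50
        models, start = trained_models
        pe = PerturbedBurnnEvaluator(topo, 0.3, models=models,
                                     buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF)
        regions = pe.assign(start)
        res = pe.evaluate(start, regions=regions)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for a in rng.choice(topo.n_atoms, 3, replace=False):
            for c in range(3):
                p = start.copy(); p.positions[a, c] += eps
                m = start.copy(); m.positions[a, c] -= eps
                fd = -(pe.evaluate(p, regions=regions).total
                       - pe.evaluate(m, regions=regions).total) / (2 * eps)
                assert fd == pytest.approx(res.forces[a, c], rel=1e-3, abs=1e-3)


class TestInterpolation:
    def test_endpoints(self, toy50, engine50):
        topo, config = toy50
        mm = MMPerturbedEvaluator(topo, 0.0, mm_cutoff=MM_CUTOFF)
        bu = PerturbedBurnnEvaluator(topo, 0.0, engine=engine50,
                                     buffer_cutoff=0.5, mm_cutoff=MM_CUTOFF)
        e_mm = mm.evaluate(config).total
        e_bu = bu.evaluate(config).total
        assert InterpolatedEvaluator(mm, bu, 0.0).evaluate(config).total == pytest.approx(e_mm)
        assert InterpolatedEvaluator(mm, bu, 1.0).evaluate(config).total == pytest.approx(e_bu)
        res = InterpolatedEvaluator(mm, bu, 0.4).evaluate(config)
        assert res.dH_dlambda == pytest.approx(e_bu - e_mm)

    def test_single_configuration_ti_closed_form(self):
        # TI over mu on a frozen configuration is exactly H_burnn - H_mm
        mus = np.linspace(0, 1, 7)
        h_mm, h_bu = -12.0, -7.5
        vals = [mm_burnn_interpolation(None, m, h_mm, h_bu)[1] for m in mus]
        assert np.trapezoid(vals, mus) == pytest.approx(h_bu - h_mm)
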