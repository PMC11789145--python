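"""Curation, reference subtraction, committee training and QbC."""

import numpy as np
import pytest

from burnn.descriptors import DescriptorSpec
from burnn.mlp import (
    ALT_OUTLIER_THRESHOLD,
    DEFAULT_OUTLIER_THRESHOLD,
    CommitteeMember,
    CommitteeModel,
    CurationError,
    DeltaDataset,
    DeltaRecord,
    curate_dataset,
    predict_delta,
    subtract_reference,
    train_committee,
)


def _records(energies, rng=None, n_feat=4):
    rng = rng or np.random.default_rng(0)
    return [
        DeltaRecord(descriptor=rng.normal(size=n_feat), delta_energy=float(e))
        for e in energies
    ]


class TestCuration:
    def test_thresholds_match_stated_conversions(self):
        assert DEFAULT_OUTLIER_THRESHOLD == pytest.approx(439.32)
        assert ALT_OUTLIER_THRESHOLD == pytest.approx(690.36)

    def test_planted_outlier_removed_exactly(self):
        energies = [10.0] * 20 + [10.0 + 500.0]     # one point > mean + 439.3
        ds = curate_dataset(_records(energies))
        assert ds.n_removed == 1 and len(ds) == 20

    def test_all_equal_nothing_removed(self):
        ds = curate_dataset(_records([5.0] * 30))
        assert ds.n_removed == 0

    def test_planted_seven_of_hundred(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0.0, 5.0, 93).tolist()
        # plant seven records far above mean + threshold of the raw set
        energies = base + [2000.0] * 7
        ds = curate_dataset(_records(energies))
        assert len(ds) == 93 and ds.n_removed == 7

    def test_single_pass_mean_semantics(self):
        # the mean is taken over the raw set once: a point above the
        # *survivor* mean + threshold but below the raw mean + threshold stays
        energies = [0.0] * 10 + [430.0, 5000.0]
        raw_mean = np.mean(energies)
        assert 430.0 < raw_mean + DEFAULT_OUTLIER_THRESHOLD
        ds = curate_dataset(_records(energies))
        assert ds.n_removed == 1 and max(r.delta_energy for r in ds.records) == 430.0

    def test_empty_input_raises(self):
        with pytest.raises((CurationError, ValueError)):
            curate_dataset(_records([]), 1.0)


class TestSubtractReference:
    def test_mean_centering(self):
        ds = DeltaDataset(records=_records([10.0, 20.0]))
        out = subtract_reference(ds)
        assert out.reference_constant == pytest.approx(15.0)
        assert sorted(r.delta_energy for r in out.records) == [-5.0, 5.0]

    def test_single_record(self):
        out = subtract_reference(DeltaDataset(records=_records([7.0])))
        assert out.records[0].delta_energy == 0.0
        assert out.reference_constant == 7.0

    def test_round_trip_keeps_absolute_scale(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = 2.0 * X[:, 0] - X[:, 1] + 0.5 * X[:, 2] + 100.0
        recs = [DeltaRecord(descriptor=x, delta_energy=float(e)) for x, e in zip(X, y)]
        ds = subtract_reference(DeltaDataset(records=recs))
        model = train_committee(ds, seed=0, hyper={"ridge_alpha": 1e-8})
        e, _ = predict_delta(model, X[0])
        assert e == pytest.approx(y[0], abs=1e-3)


class TestCommittee:
    def test_identical_split_seeds_give_zero_disagreement(self):
        rng = np.random.default_rng(2)
        recs = _records(rng.normal(size=30))
        ds = subtract_reference(DeltaDataset(records=recs))
        model = train_committee(ds, seed=0, hyper={"split_seeds": [7, 7]})
        _, dis = predict_delta(model, recs[0].descriptor)
        assert dis == pytest.approx(0.0, abs=1e-12)

    def test_linear_function_learnable(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 5))
        y = X @ np.array([1.0, -2.0, 0.3, 0.0, 4.0])
        recs = [DeltaRecord(descriptor=x, delta_energy=float(e)) for x, e in zip(X, y)]
        ds = subtract_reference(DeltaDataset(records=recs))
        model = train_committee(ds, seed=1, hyper={"ridge_alpha": 1e-8})
        assert max(model.holdout_rmse) < 0.1

    def test_two_member_mean_and_population_sd(self):
        # members returning a and b -> mean (a+b)/2, disagreement |a-b|/2
        mean = np.zeros(2)
        scale = np.ones(2)
        m1 = CommitteeMember("ridge", mean, scale, coef=np.zeros(2), intercept=3.0)
        m2 = CommitteeMember("ridge", mean, scale, coef=np.zeros(2), intercept=7.0)
        model = CommitteeModel(
            members=[m1, m2], split_seeds=[0, 1], hyperparameters={},
            reference_constant=0.0, descriptor=DescriptorSpec(elements=("X",)),
        )
        e, dis = predict_delta(model, np.zeros(2))
        assert e == pytest.approx(5.0) and dis == pytest.approx(2.0)

    def test_member_exchange_symmetry(self):
        rng = np.random.default_rng(5)
        recs = _records(rng.normal(size=40))
        ds = subtract_reference(DeltaDataset(records=recs))
        model = train_committee(ds, seed=2)
        x = recs[0].descriptor
        e1 = model.member_energies(x).mean()
        model.members.reverse()
        e2 = model.member_energies(x).mean()
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(6)
        recs = _records(rng.normal(size=20))
        ds = subtract_reference(DeltaDataset(records=recs))
        model = train_committee(ds, seed=0)
        with pytest.raises(ValueError):
            predict_delta(model, np.zeros(11))

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        recs = _records(rng.normal(size=25))
        ds = subtract_reference(DeltaDataset(records=recs))
        m1 = train_committee(ds, seed=4)
        m2 = train_committee(ds, seed=4)
        assert np.allclose(m1.members[0].coef, m2.members[0].coef)
        assert m1.split_seeds == m2.split_seeds


class TestAdaptiveSampling:
    def test_below_threshold_returns_empty(self, toy_small, engine_small):
        from burnn.pipeline import fit_state_models, sample_mm_frames
        from burnn.mlp import adaptive_sample

        topo, config = toy_small
        frames = sample_mm_frames(topo, config, 0.0, 25, seed=11, cadence=4,
                                  mm_cutoff=0.9)
        committee, _ = fit_state_models(
            topo, frames, engine_small, "A", seed=5,
            include_minimization=False, adaptive_rounds=0,
        )
        inner = topo.molecule_atom_indices({0})
        picked = adaptive_sample(frames, committee, 1e9, topo, inner,
                                 region_molecules={0, 1})
        assert picked == []
        # with threshold zero every frame is a candidate (dedup off)
        picked_all = adaptive_sample(frames, committee, -1.0, topo, inner,
                                     region_molecules={0, 1})
        assert len(picked_all) == len(frames)
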