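"""Delta-energy committee models: curation, training, prediction, QbC.

The learning target is the delta energy V(I+Buf) - V(Buf) between the
reference level and nothing — delta learning against the reference engine.
A committee of identically configured regressors, differing only in their
random data splits, provides both the prediction (committee mean, with the
designated predictive member supplying forces) and an error proxy (the
committee spread, Query-by-Committee).

Two member architectures share the invariance contract of the
symmetry-function descriptor: a regularized linear model on standardized
features (the default — linear ML potentials in the SNAP/ACE tradition) and
an RBF kernel ridge regressor.  Forces come from differentiating the
predicted energy through the descriptor Jacobian, never from a separately
learned model, so the dynamics they drive are conservative between region
reassignments.

Training-set curation follows the reference-data workflow: outliers more
than a threshold above the raw-set mean are removed in a single pass, and a
constant reference value (the mean delta energy) is subtracted from all
targets and re-added at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

from .descriptors import DescriptorSpec
from .reference import ReferenceEngine, reference_energy
from .system import Configuration, SystemTopology

__all__ = [
    "KCAL_TO_KJ",
    "DEFAULT_OUTLIER_THRESHOLD",
    "ALT_OUTLIER_THRESHOLD",
    "DeltaRecord",
    "DeltaDataset",
    "CommitteeMember",
    "CommitteeModel",
    "CurationError",
    "curate_dataset",
    "subtract_reference",
    "train_committee",
    "predict_delta",
    "adaptive_sample",
    "train_intra_model",
    "IntraModel",
]

KCAL_TO_KJ = 4.184
#: default outlier-removal threshold, 105 kcal/mol above the raw-set mean
DEFAULT_OUTLIER_THRESHOLD = 105.0 * KCAL_TO_KJ   # 439.32 kJ/mol
#: alternative threshold for apolar solutes, 165 kcal/mol
ALT_OUTLIER_THRESHOLD = 165.0 * KCAL_TO_KJ       # 690.36 kJ/mol


class CurationError(ValueError):
    """Curation removed every record."""


@dataclass
class DeltaRecord:
    descriptor: np.ndarray
    delta_energy: float                 # kJ/mol (target scale of the dataset)
    forces: np.ndarray | None = None
    provenance: str = "md_snapshot"     # md_snapshot | minimization_step | adaptive
    positions: np.ndarray | None = None
    box: np.ndarray | None = None
    #: MM-level baseline value of the same delta; the regressor learns the
    #: residual delta_energy - baseline_energy (delta-learning around a
    #: physical baseline), and predictions re-add the baseline
    baseline_energy: float = 0.0
    # optional force-matching rows: gradient of the descriptor with respect
    # to a subsample of atom coordinates (n_rows x n_features) and the
    # corresponding reference gradient targets dE/dx (n_rows,)
    force_rows: np.ndarray | None = None
    force_targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.descriptor = np.asarray(self.descriptor, dtype=float)
        if not np.all(np.isfinite(self.descriptor)) or not np.isfinite(self.delta_energy):
            raise ValueError("non-finite record")


@dataclass
class DeltaDataset:
    records: list[DeltaRecord]
    reference_constant: float = 0.0
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
    n_removed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def X(self) -> np.ndarray:
        return np.stack([r.descriptor for r in self.records])

    @property
    def y(self) -> np.ndarray:
        return np.array([r.delta_energy for r in self.records])

    @property
    def baselines(self) -> np.ndarray:
        return np.array([r.baseline_energy for r in self.records])


def curate_dataset(
    raw: Sequence[DeltaRecord],
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> DeltaDataset:
    """Drop records whose delta energy exceeds mean(raw) + threshold.

    The mean is computed once on the raw set (single pass — survivors are
    not re-averaged), so exactly the records above the original mean +
    threshold are removed.
    """
    if len(raw) == 0:
        raise ValueError("cannot curate an empty record list")
    energies = np.array([r.delta_energy for r in raw])
    limit = float(np.mean(energies)) + threshold
    kept = [r for r, e in zip(raw, energies) if e <= limit]
    if not kept:
        raise CurationError("curation removed all records")
    return DeltaDataset(
        records=list(kept),
        outlier_threshold=threshold,
        n_removed=len(raw) - len(kept),
    )


def subtract_reference(ds: DeltaDataset) -> DeltaDataset:
    """Mean-center the learning targets, remembering the constant.

    The constant is the mean of the (baseline-subtracted) targets and is
    re-added at prediction time."""
    const = float(np.mean(ds.y - ds.baselines))
    shifted = [replace(r, delta_energy=r.delta_energy - const) for r in ds.records]
    return DeltaDataset(
        records=shifted,
        reference_constant=ds.reference_constant + const,
        outlier_threshold=ds.outlier_threshold,
        n_removed=ds.n_removed,
    )


# ---------------------------------------------------------------------------
# Committee members and the committee
# ---------------------------------------------------------------------------

@dataclass
class CommitteeMember:
    """One trained regressor plus its feature standardization."""

    kind: str                     # "ridge" | "krr"
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray | None = None          # ridge
    intercept: float = 0.0                  # ridge
    X_fit: np.ndarray | None = None         # krr (standardized)
    dual_coef: np.ndarray | None = None     # krr
    gamma: float = 1.0                      # krr

    @property
    def n_features(self) -> int:
        return len(self.scaler_mean)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(np.atleast_2d(X))
        if self.kind == "ridge":
            return Xs @ self.coef + self.intercept
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            - 2.0 * Xs @ self.X_fit.T
            + np.sum(self.X_fit**2, axis=1)[None, :]
        )
        return np.exp(-self.gamma * d2) @ self.dual_coef

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """dE/d(descriptor) at a single raw feature vector."""
        xs = self._standardize(x[None, :])[0]
        if self.kind == "ridge":
            return self.coef / self.scaler_scale
        diff = xs[None, :] - self.X_fit
        k = np.exp(-self.gamma * np.sum(diff**2, axis=1))
        grad_s = (self.dual_coef * k) @ (-2.0 * self.gamma * diff)
        return grad_s / self.scaler_scale


def _fit_member(
    X: np.ndarray, y: np.ndarray, train_idx: np.ndarray, hyper: dict,
    records: Sequence[DeltaRecord] | None = None,
) -> CommitteeMember:
    scaler = StandardScaler().fit(X[train_idx])
    Xs = scaler.transform(X[train_idx])
    if hyper["model"] == "ridge":
        wf = hyper.get("force_weight", 0.0)
        have_forces = (
            wf > 0
            and records is not None
            and all(records[k].force_rows is not None for k in train_idx)
        )
        if have_forces:
            # joint energy + gradient (force-matching) ridge solve:
            # the gradient rows are linear in the same weights, so the
            # normal equations stay closed-form
            y_c = y[train_idx] - y[train_idx].mean()
            n_feat = Xs.shape[1]
            N = Xs.T @ Xs
            rhs = Xs.T @ y_c
            G = np.concatenate(
                [records[k].force_rows for k in train_idx]
            ) / scaler.scale_[None, :]
            t = np.concatenate([records[k].force_targets for k in train_idx])
            N += wf**2 * (G.T @ G)
            rhs += wf**2 * (G.T @ t)
            N[np.diag_indices(n_feat)] += hyper["ridge_alpha"]
            coef = np.linalg.solve(N, rhs)
            return CommitteeMember(
                kind="ridge",
                scaler_mean=scaler.mean_,
                scaler_scale=scaler.scale_,
                coef=coef,
                intercept=float(y[train_idx].mean()),
            )
        m = Ridge(alpha=hyper["ridge_alpha"]).fit(Xs, y[train_idx])
        return CommitteeMember(
            kind="ridge",
            scaler_mean=scaler.mean_,
            scaler_scale=scaler.scale_,
            coef=m.coef_,
            intercept=float(m.intercept_),
        )
    m = KernelRidge(kernel="rbf", alpha=hyper["ridge_alpha"], gamma=hyper["gamma"])
    m.fit(Xs, y[train_idx])
    return CommitteeMember(
        kind="krr",
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        X_fit=m.X_fit_,
        dual_coef=np.asarray(m.dual_coef_).ravel(),
        gamma=hyper["gamma"],
    )


@dataclass
class CommitteeModel:
    """Identically configured regressors differing only in data split.

    ``members[0]`` is the designated predictive member (its gradient
    supplies forces); the others serve validation and the disagreement
    estimate.
    """

    members: list[CommitteeMember]
    split_seeds: list[int]
    hyperparameters: dict
    reference_constant: float
    descriptor: DescriptorSpec
    holdout_rmse: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def member_energies(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.stack([m.predict(X) for m in self.members])

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = self.member_energies(X)
        return e.mean(axis=0) + self.reference_constant, e.std(axis=0)

    def predict_config(
        self,
        config: Configuration,
        topo: SystemTopology,
        inner_atoms,
        buffer_atoms,
        with_forces: bool = False,
    ):
        """Energy (+disagreement, +forces) for an (inner, buffer) split.

        The energy is the *predictive* member's prediction (plus the
        reference constant); the other members only feed the disagreement.
        This keeps the Hamiltonian that drives dynamics exactly consistent
        with its forces, which come from the predictive member's analytic
        gradient chained through the descriptor Jacobian.
        """
        from .forcefield import cluster_delta_baseline

        inner = np.asarray(inner_atoms, int)
        buffer = np.asarray(buffer_atoms, int)
        use_baseline = self.meta.get("baseline") == "mm_cluster"
        if not with_forces:
            x = self.descriptor.features(config, topo, inner, buffer)
            e_all = self.member_energies(x)
            e = float(e_all[0, 0]) + self.reference_constant
            if use_baseline:
                e += cluster_delta_baseline(config, topo, inner, buffer)[0]
            return e, float(e_all.std(axis=0)[0])
        x, J, subset = self.descriptor.features_jacobian(config, topo, inner, buffer)
        e_all = self.member_energies(x)
        e = float(e_all[0, 0]) + self.reference_constant
        de_dx = self.members[0].gradient(x)
        forces = -np.einsum("f,fmc->mc", de_dx, J)
        if use_baseline:
            e_b, f_b = cluster_delta_baseline(config, topo, inner, buffer)
            e += e_b
            forces += f_b
        return e, float(e_all.std(axis=0)[0]), forces, subset


def train_committee(
    ds: DeltaDataset,
    n_members: int = 2,
    seed: int = 0,
    hyper: dict | None = None,
    descriptor: DescriptorSpec | None = None,
) -> CommitteeModel:
    """Train an n-member committee on random splits of a curated dataset.

    All members share hyperparameters; the only difference is the random
    train/holdout split (and hence the fitted coefficients).  Deterministic
    for a fixed seed.  Per-member held-out RMSE is recorded.
    """
    if n_members < 2:
        raise ValueError("a committee needs at least 2 members")
    if len(ds) < 4:
        raise ValueError("dataset too small to split")
    hyper = dict(hyper or {})
    hyper.setdefault("model", "ridge")
    hyper.setdefault("ridge_alpha", 1e-5)
    hyper.setdefault("force_weight", 0.03)
    train_fraction = hyper.setdefault("train_fraction", 0.85)
    X, y = ds.X, ds.y

    master = np.random.default_rng(seed)
    if hyper["model"] == "krr" and hyper.get("gamma") is None:
        hyper["gamma"] = _median_gamma(X, np.random.default_rng(seed))

    y = y - ds.baselines
    split_seeds = hyper.get("split_seeds")
    if split_seeds is None:
        split_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_members)]
    members, rmses = [], []
    n_train = max(2, int(round(train_fraction * len(X))))
    for s in split_seeds:
        rng = np.random.default_rng(s)
        perm = rng.permutation(len(X))
        tr, ho = perm[:n_train], perm[n_train:]
        member = _fit_member(X, y, tr, hyper, records=ds.records)
        members.append(member)
        if len(ho):
            pred = member.predict(X[ho])
            rmses.append(float(np.sqrt(np.mean((pred - y[ho]) ** 2))))
        else:
            rmses.append(float("nan"))
    if descriptor is None:
        descriptor = DescriptorSpec(elements=("X",))
    model = CommitteeModel(
        members=members,
        split_seeds=list(split_seeds),
        hyperparameters=hyper,
        reference_constant=ds.reference_constant,
        descriptor=descriptor,
        holdout_rmse=rmses,
    )
    if np.any(ds.baselines != 0.0):
        model.meta["baseline"] = "mm_cluster"
    return model


def _median_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """Median-distance heuristic for the RBF kernel width (standardized)."""
    sc = StandardScaler().fit(X)
    Xs = sc.transform(X)
    idx = rng.choice(len(Xs), size=min(len(Xs), 300), replace=False)
    sub = Xs[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices(len(sub), k=1)])
    return 1.0 / (2.0 * med) if med > 0 else 1.0


def predict_delta(
    model: CommitteeModel,
    descriptor: np.ndarray,
    reference_constant: float | None = None,
) -> tuple[float, float]:
    """Committee mean (+ reference constant) and population-sd disagreement."""
    x = np.atleast_2d(np.asarray(descriptor, float))
    if x.shape[1] != model.members[0].n_features:
        raise ValueError(
            f"descriptor dimension {x.shape[1]} does not match model "
            f"({model.members[0].n_features})"
        )
    e = model.member_energies(x)
    const = model.reference_constant if reference_constant is None else reference_constant
    return float(e.mean(axis=0)[0] + const), float(e.std(axis=0)[0])


def adaptive_sample(
    frames: Sequence[Configuration],
    model: CommitteeModel,
    disagreement_threshold: float,
    topo: SystemTopology,
    inner_atoms,
    buffer_cutoff: float = 0.5,
    min_descriptor_spacing: float = 0.0,
    region_molecules: set[int] | None = None,
) -> list[int]:
    """Frame indices where committee disagreement exceeds the threshold.

    High-disagreement frames are candidates for labeling and retraining
    (adaptive sampling).  Results are deduplicated greedily: a candidate is
    kept only if its descriptor is at least ``min_descriptor_spacing`` away
    from every already-kept candidate.
    """
    from .system import assign_regions

    kept: list[int] = []
    kept_desc: list[np.ndarray] = []
    inner = np.asarray(inner_atoms, int)
    inner_mols = (
        set(region_molecules)
        if region_molecules is not None
        else {topo.atoms[int(a)].molecule_id for a in inner}
    )
    saved = topo.inner_molecule_ids
    for k, cfg in enumerate(frames):
        topo.inner_molecule_ids = inner_mols
        try:
            regions = assign_regions(cfg, topo, buffer_cutoff)
        finally:
            topo.inner_molecule_ids = saved
        buf = topo.molecule_atom_indices(regions.buffer)
        x = model.descriptor.features(cfg, topo, inner, buf)
        _, dis = model.predict(x)
        if dis[0] <= disagreement_threshold:
            continue
        if min_descriptor_spacing > 0 and any(
            np.linalg.norm(x - xd) < min_descriptor_spacing for xd in kept_desc
        ):
            continue
        kept.append(k)
        kept_desc.append(x)
    return kept


# ---------------------------------------------------------------------------
# Intra-region model: inner-region energy alone, for the lambda-Hamiltonian
# ---------------------------------------------------------------------------

@dataclass
class IntraModel:
    """Committee trained to predict the reference energy of the inner region
    alone (empty buffer).  Needed by the perturbed Hamiltonian so that an
    alchemically decoupled molecule keeps its intramolecular forces."""

    committee: CommitteeModel
    inner_atoms: np.ndarray

    def predict_config(self, config: Configuration, topo: SystemTopology,
                       with_forces: bool = False):
        return self.committee.predict_config(
            config, topo, self.inner_atoms, np.empty(0, int), with_forces=with_forces
        )


def train_intra_model(
    configs: Sequence[Configuration],
    topo: SystemTopology,
    inner_atoms,
    engine: ReferenceEngine,
    n_members: int = 2,
    seed: int = 0,
    hyper: dict | None = None,
    descriptor: DescriptorSpec | None = None,
) -> IntraModel:
    """Train the separate inner-region-only model from inner configurations.

    Targets are reference energies of the inner region alone; the descriptor
    contract (translation/rotation/permutation invariance) is inherited from
    the delta model's fingerprint with an empty buffer.
    """
    inner = np.asarray(inner_atoms, int)
    if descriptor is None:
        descriptor = DescriptorSpec.from_topology(topo)
    records = []
    for cfg in configs:
        x, J, subset = descriptor.features_jacobian(cfg, topo, inner, np.empty(0, int))
        ev = reference_energy(cfg, inner.tolist(), engine)
        from .forcefield import cluster_delta_baseline

        e_b, f_b = cluster_delta_baseline(cfg, topo, inner, np.empty(0, int))
        records.append(
            DeltaRecord(
                descriptor=x,
                delta_energy=ev.energy,
                forces=ev.forces,
                baseline_energy=e_b,
                force_rows=J.reshape(len(x), -1).T.astype(np.float32),
                force_targets=(f_b - ev.forces).ravel(),
            )
        )
    ds = subtract_reference(DeltaDataset(records=records))
    committee = train_committee(
        ds, n_members=n_members, seed=seed, hyper=hyper, descriptor=descriptor
    )
    committee.meta["kind"] = "intra"
    return IntraModel(committee=committee, inner_atoms=inner)
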