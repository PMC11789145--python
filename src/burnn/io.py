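"""File formats: topology, extended XYZ configurations, datasets, models,
energy series and run configurations.

Topologies are a documented key-value (YAML) schema; configurations are
extended XYZ with the box on the comment line (``Lattice="..."``); datasets
and trained models live in HDF5 containers with an embedded schema version;
energy series are tidy CSV with named component columns.  Every writer
embeds the seeds/config hash needed to regenerate the file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .descriptors import DescriptorSpec
from .mlp import CommitteeModel, DeltaDataset, DeltaRecord
from .system import Atom, Configuration, SystemTopology

__all__ = [
    "RunConfig",
    "config_hash",
    "write_topology",
    "read_topology",
    "write_xyz",
    "read_xyz",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "write_energy_series",
    "read_energy_series",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Run-level knobs; serialized to YAML, hashed into every output."""

    mode: str = "mm"                 # mm | burqm | burnn | fep | vertical
    schedule: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0])
    buffer_cutoff: float = 0.5       # nm
    mm_cutoff: float = 1.2           # nm
    dt: float = 0.002                # ps
    n_steps: int = 1000
    temperature: float = 298.15      # K
    thermostat: str = "berendsen"
    seed: int = 0
    sample_every: int = 10
    alpha_lj: float = 0.0
    alpha_c: float = 0.0             # nm^2
    engine: str = "mock_qm"
    engine_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sched = sorted(float(s) for s in self.schedule)
        if sched and (sched[0] < 0.0 or sched[-1] > 1.0):
            raise ValueError("schedule values must lie in [0, 1]")
        self.schedule = sched

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def config_hash(obj) -> str:
    """Stable short hash of a run configuration or plain dict."""
    d = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def parse_schedule(text: str) -> list[float]:
    """Parse 'start:stop:count' or a comma-separated list of values."""
    if ":" in text:
        start, stop, count = text.split(":")
        return list(np.linspace(float(start), float(stop), int(count)))
    return [float(t) for t in text.split(",") if t.strip()]


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def write_topology(topo: SystemTopology, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "atoms": [
            {
                "id": int(a.id), "element": str(a.element), "mass": float(a.mass),
                "charge": float(a.charge), "lj_sigma": float(a.lj_sigma),
                "lj_epsilon": float(a.lj_epsilon),
                "molecule_id": int(a.molecule_id),
                "dual_state": str(a.dual_state),
            }
            for a in topo.atoms
        ],
        "bonds": [[int(b[0]), int(b[1]), float(b[2]), float(b[3])] for b in topo.bonds],
        "angles": [
            [int(a[0]), int(a[1]), int(a[2]), float(a[3]), float(a[4])]
            for a in topo.angles
        ],
        "constraints": [[int(c[0]), int(c[1]), float(c[2])] for c in topo.constraints],
        "restraints": [
            [int(r[0]), int(r[1]), float(r[2]), float(r[3])] for r in topo.restraints
        ],
        "inner_molecule_ids": sorted(int(m) for m in topo.inner_molecule_ids),
        "exclusions": sorted([int(e[0]), int(e[1])] for e in topo.exclusions),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path: str | Path) -> SystemTopology:
    doc = yaml.safe_load(Path(path).read_text())
    atoms = [Atom(**a) for a in doc["atoms"]]
    return SystemTopology(
        atoms=atoms,
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        angles=[tuple(a) for a in doc.get("angles", [])],
        constraints=[tuple(c) for c in doc.get("constraints", [])],
        restraints=[tuple(r) for r in doc.get("restraints", [])],
        inner_molecule_ids=set(doc.get("inner_molecule_ids", [])),
        exclusions={tuple(e) for e in doc.get("exclusions", [])},
    )


# ---------------------------------------------------------------------------
# Extended XYZ configurations
# ---------------------------------------------------------------------------

def write_xyz(
    config: Configuration, elements: list[str], path: str | Path, append: bool = False
) -> None:
    """Extended XYZ with an orthorhombic Lattice comment; nm units."""
    lines = [str(len(elements))]
    bx, by, bz = config.box
    props = "species:S:1:pos:R:3"
    has_v = config.velocities is not None
    if has_v:
        props += ":vel:R:3"
    lines.append(
        f'Lattice="{bx:.10f} 0.0 0.0 0.0 {by:.10f} 0.0 0.0 0.0 {bz:.10f}" '
        f"Properties={props} Time={config.time:.6f}"
    )
    for k, el in enumerate(elements):
        x, y, z = config.positions[k]
        row = f"{el} {x:.10f} {y:.10f} {z:.10f}"
        if has_v:
            vx, vy, vz = config.velocities[k]
            row += f" {vx:.10f} {vy:.10f} {vz:.10f}"
        lines.append(row)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[tuple[Configuration, list[str]]]:
    """Read all frames of an extended XYZ file."""
    out = []
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k].strip())
        comment = lines[k + 1]
        import re

        m = re.search(r'Lattice="([^"]+)"', comment)
        if not m:
            raise ValueError("missing Lattice field in extended XYZ comment")
        lat = np.array([float(t) for t in m.group(1).split()]).reshape(3, 3)
        box = np.diag(lat)
        tm = re.search(r"Time=([-\d.eE+]+)", comment)
        time = float(tm.group(1)) if tm else 0.0
        has_v = "vel" in comment
        elements, pos, vel = [], [], []
        for row in lines[k + 2 : k + 2 + n]:
            parts = row.split()
            elements.append(parts[0])
            pos.append([float(p) for p in parts[1:4]])
            if has_v:
                vel.append([float(p) for p in parts[4:7]])
        cfg = Configuration(
            positions=np.array(pos),
            box=box,
            velocities=np.array(vel) if has_v else None,
            time=time,
        )
        out.append((cfg, elements))
        k += 2 + n
    return out


# ---------------------------------------------------------------------------
# Datasets (HDF5)
# ---------------------------------------------------------------------------

def save_dataset(ds: DeltaDataset, path: str | Path, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["reference_constant"] = ds.reference_constant
        f.attrs["outlier_threshold"] = ds.outlier_threshold
        f.attrs["n_removed"] = ds.n_removed
        for k, v in (meta or {}).items():
            f.attrs[str(k)] = v
        f.create_dataset("descriptors", data=ds.X)
        f.create_dataset("delta_energies", data=ds.y)
        f.create_dataset(
            "provenance",
            data=np.array([r.provenance for r in ds.records], dtype="S24"),
        )
        with_pos = [r for r in ds.records if r.positions is not None]
        if len(with_pos) == len(ds.records):
            shapes = {r.positions.shape for r in ds.records}
            if len(shapes) == 1:
                f.create_dataset(
                    "positions", data=np.stack([r.positions for r in ds.records])
                )
                f.create_dataset("box", data=np.stack([r.box for r in ds.records]))


def load_dataset(path: str | Path) -> DeltaDataset:
    with h5py.File(path, "r") as f:
        X = f["descriptors"][...]
        y = f["delta_energies"][...]
        prov = [p.decode() for p in f["provenance"][...]]
        pos = f["positions"][...] if "positions" in f else None
        box = f["box"][...] if "box" in f else None
        records = [
            DeltaRecord(
                descriptor=X[k],
                delta_energy=float(y[k]),
                provenance=prov[k],
                positions=None if pos is None else pos[k],
                box=None if box is None else box[k],
            )
            for k in range(len(y))
        ]
        return DeltaDataset(
            records=records,
            reference_constant=float(f.attrs["reference_constant"]),
            outlier_threshold=float(f.attrs["outlier_threshold"]),
            n_removed=int(f.attrs["n_removed"]),
        )


# ---------------------------------------------------------------------------
# Models (HDF5)
# ---------------------------------------------------------------------------

def save_model(model: CommitteeModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["reference_constant"] = model.reference_constant
        f.attrs["split_seeds"] = model.split_seeds
        f.attrs["hyperparameters"] = json.dumps(
            {k: v for k, v in model.hyperparameters.items() if k != "split_seeds"}
        )
        f.attrs["holdout_rmse"] = model.holdout_rmse
        meta = {k: v for k, v in model.meta.items() if isinstance(v, (int, float, str))}
        f.attrs["meta"] = json.dumps(meta)
        d = model.descriptor
        f.attrs["descriptor"] = json.dumps(
            {
                "elements": list(d.elements),
                "n_radial": d.n_radial,
                "r_grid_inner": list(d.r_grid_inner),
                "r_grid_cross": list(d.r_grid_cross),
                "density_width": d.density_width,
                "embed_specs": [list(s) for s in d.embed_specs],
                "n_angular": d.n_angular,
            }
        )
        for k, m in enumerate(model.members):
            g = f.create_group(f"member_{k}")
            g.attrs["kind"] = m.kind
            g.create_dataset("scaler_mean", data=m.scaler_mean)
            g.create_dataset("scaler_scale", data=m.scaler_scale)
            if m.kind == "ridge":
                g.create_dataset("coef", data=m.coef)
                g.attrs["intercept"] = m.intercept
            else:
                g.create_dataset("X_fit", data=m.X_fit)
                g.create_dataset("dual_coef", data=m.dual_coef)
                g.attrs["gamma"] = m.gamma


def load_model(path: str | Path) -> CommitteeModel:
    from .mlp import CommitteeMember

    with h5py.File(path, "r") as f:
        members = []
        k = 0
        while f"member_{k}" in f:
            g = f[f"member_{k}"]
            kind = g.attrs["kind"]
            if kind == "ridge":
                m = CommitteeMember(
                    kind="ridge",
                    scaler_mean=g["scaler_mean"][...],
                    scaler_scale=g["scaler_scale"][...],
                    coef=g["coef"][...],
                    intercept=float(g.attrs["intercept"]),
                )
            else:
                m = CommitteeMember(
                    kind="krr",
                    scaler_mean=g["scaler_mean"][...],
                    scaler_scale=g["scaler_scale"][...],
                    X_fit=g["X_fit"][...],
                    dual_coef=g["dual_coef"][...],
                    gamma=float(g.attrs["gamma"]),
                )
            members.append(m)
            k += 1
        dd = json.loads(f.attrs["descriptor"])
        descriptor = DescriptorSpec(
            elements=tuple(dd["elements"]),
            n_radial=int(dd["n_radial"]),
            r_grid_inner=tuple(dd["r_grid_inner"]),
            r_grid_cross=tuple(dd["r_grid_cross"]),
            density_width=float(dd["density_width"]),
            embed_specs=tuple(tuple(s) for s in dd["embed_specs"]),
            n_angular=int(dd["n_angular"]),
        )
        return CommitteeModel(
            members=members,
            split_seeds=[int(s) for s in f.attrs["split_seeds"]],
            hyperparameters=json.loads(f.attrs["hyperparameters"]),
            reference_constant=float(f.attrs["reference_constant"]),
            descriptor=descriptor,
            holdout_rmse=[float(x) for x in f.attrs["holdout_rmse"]],
            meta=json.loads(f.attrs["meta"]),
        )


# ---------------------------------------------------------------------------
# Energy series
# ---------------------------------------------------------------------------

def write_energy_series(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    header = "".join(
        f"# {k} = {v}\n" for k, v in sorted((meta or {}).items())
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")


def read_energy_series(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta
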