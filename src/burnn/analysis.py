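"""Thermodynamic integration, cycle closure and structural observables.

Free energies come from trapezoidal TI over a lambda grid of
<dH/dlambda> averages with block-averaged standard errors; replicas are
combined by inverse-variance weighting.  Bidirectional exponential averaging
over the same per-frame dH/dlambda samples serves as an independent
estimator for cross-checks (linear coupling makes the perturbed energies to
neighboring lambda points exact post-processing).

Structural observables: radial distribution functions, geometric
hydrogen-bond counting, the signed angle between the C-O-H plane of the
solute and the C-O...HW plane of a donating water (tetrahedrality probe),
and bond-length power spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .md import KB, MDOptions, Trajectory, run_simulation
from .system import Configuration, SystemTopology, minimum_image_displacements

__all__ = [
    "TISeries",
    "CycleLeg",
    "ti_integrate",
    "block_standard_error",
    "ti_series_from_samples",
    "exp_averaging",
    "cycle_closure",
    "harmonic_fep_oracle",
    "HarmonicLambdaEvaluator",
    "rdf",
    "count_hbonds",
    "signed_plane_angle",
    "plane_angle_distribution",
    "bond_power_spectrum",
]

#: speed of light in cm/ps, for wavenumber conversion
C_CM_PER_PS = 0.0299792458


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------

@dataclass
class TISeries:
    lambdas: np.ndarray            # strictly increasing, in [0, 1]
    means: np.ndarray              # <dH/dlambda> per point, kJ/mol
    errors: np.ndarray             # block-averaged standard errors
    replicas: list[np.ndarray] = field(default_factory=list)
    samples: list[np.ndarray] = field(default_factory=list)  # raw per-point dH/dl

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, float)
        self.means = np.asarray(self.means, float)
        self.errors = np.asarray(self.errors, float)
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda points must be strictly increasing")
        if not (len(self.lambdas) == len(self.means) == len(self.errors)):
            raise ValueError("one mean and error per lambda point")


def block_standard_error(x: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averaging (>=10 blocks)."""
    x = np.asarray(x, float)
    n_blocks = min(n_blocks, len(x))
    if n_blocks < 2:
        return float("nan")
    blocks = np.array_split(x, n_blocks)
    bm = np.array([b.mean() for b in blocks])
    return float(bm.std(ddof=1) / np.sqrt(len(bm)))


def ti_series_from_samples(
    lambdas: Sequence[float],
    samples: Sequence[Sequence[np.ndarray]],
    n_blocks: int = 10,
) -> TISeries:
    """Build a TI series from per-lambda, per-replica dH/dlambda samples.

    Replica means are combined by inverse-variance weighting; with a single
    replica this reduces to the plain block-averaged mean and error.
    """
    means, errors, reps, raw = [], [], [], []
    for lam_samples in samples:
        ms = np.array([np.mean(r) for r in lam_samples])
        es = np.array([block_standard_error(np.asarray(r), n_blocks) for r in lam_samples])
        es = np.where(np.isfinite(es) & (es > 0), es, np.nanmax(es) if np.any(es > 0) else 1.0)
        w = 1.0 / es**2
        means.append(float(np.sum(w * ms) / np.sum(w)))
        errors.append(float(1.0 / np.sqrt(np.sum(w))))
        reps.append(ms)
        raw.append(np.concatenate([np.asarray(r) for r in lam_samples]))
    return TISeries(
        np.asarray(lambdas), np.array(means), np.array(errors), reps, raw
    )


def ti_integrate(series: TISeries) -> tuple[float, float]:
    """Trapezoidal TI: dG = int <dH/dlambda> dlambda, with RSS error.

    The error is propagated as the root-sum-square of the trapezoid-weighted
    per-point standard errors (points treated as independent).
    """
    lam, m, s = series.lambdas, series.means, series.errors
    if len(lam) < 2:
        raise ValueError("TI needs at least two lambda points")
    h = np.diff(lam)
    w = np.zeros_like(lam)
    w[:-1] += h / 2.0
    w[1:] += h / 2.0
    dG = float(np.sum(w * m))
    err = float(np.sqrt(np.sum((w * s) ** 2)))
    return dG, err


def exp_averaging(
    lambdas: Sequence[float],
    samples: Sequence[np.ndarray],
    temperature: float = 298.15,
) -> tuple[float, float]:
    """Bidirectional exponential averaging over a linear-coupling lambda grid.

    For linear coupling, H(lam') - H(lam) = (lam' - lam) dH/dlam frame by
    frame, so the forward and backward exponential averages per interval are
    exact post-processing of the recorded dH/dlambda samples.  The interval
    estimate is the mean of forward and backward; errors are propagated from
    block-averaged fluctuation of the per-block estimates.
    """
    lam = np.asarray(lambdas, float)
    beta = 1.0 / (KB * temperature)

    def _fe(u: np.ndarray) -> tuple[float, float]:
        """-kT ln <exp(-beta u)> with a block-spread standard error."""
        shift = u.min()     # overflow guard; exact up to the shift
        full = shift - np.log(np.mean(np.exp(-beta * (u - shift)))) / beta
        blocks = np.array_split(u, min(10, len(u)))
        vals = np.array(
            [
                b.min() - np.log(np.mean(np.exp(-beta * (b - b.min())))) / beta
                for b in blocks
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.inf
        return float(full), float(se)

    dG_total, var_total = 0.0, 0.0
    for i in range(len(lam) - 1):
        dlam = lam[i + 1] - lam[i]
        u_fwd = dlam * np.asarray(samples[i])          # H_{i+1}-H_i on i-ensemble
        u_bwd = -dlam * np.asarray(samples[i + 1])     # H_i-H_{i+1} on i+1-ensemble
        g_f, e_f = _fe(u_fwd)                          # dG(i -> i+1)
        g_b, e_b = _fe(u_bwd)                          # dG(i+1 -> i)
        dG_total += 0.5 * (g_f - g_b)
        var_total += 0.25 * (e_f**2 + e_b**2)
    return float(dG_total), float(np.sqrt(var_total))


# ---------------------------------------------------------------------------
# Thermodynamic cycle closure
# ---------------------------------------------------------------------------

@dataclass
class CycleLeg:
    label: str
    dG: float
    error: float
    direction: int = 1            # +1 traversed forward, -1 reversed
    start: str | None = None      # optional node labels for topology checks
    end: str | None = None

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("leg error must be non-negative")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


def cycle_closure(legs: Sequence[CycleLeg]) -> tuple[float, float]:
    """Signed sum of free-energy legs around a closed cycle.

    If the legs carry node labels, the oriented edges must chain into a
    closed walk; an inconsistent orientation raises.  The propagated error
    is the root-sum-square of the leg errors.
    """
    if len(legs) < 1:
        raise ValueError("empty cycle")
    if all(l.start is not None and l.end is not None for l in legs):
        node = legs[0].start if legs[0].direction == 1 else legs[0].end
        current = node
        for l in legs:
            a, b = (l.start, l.end) if l.direction == 1 else (l.end, l.start)
            if a != current:
                raise ValueError(
                    f"open cycle: leg {l.label!r} starts at {a!r}, expected {current!r}"
                )
            current = b
        if current != node:
            raise ValueError("open cycle: walk does not return to start")
    closure = float(sum(l.direction * l.dG for l in legs))
    err = float(np.sqrt(sum(l.error**2 for l in legs)))
    return closure, err


# ---------------------------------------------------------------------------
# Harmonic oracle for the full TI pipeline
# ---------------------------------------------------------------------------

class HarmonicLambdaEvaluator:
    """H(lam) = 1/2 k(lam) sum over active dimensions of (x - c)^2 with
    k(lam) = (1-lam) k_A + lam k_B; dH/dlam = 1/2 (k_B - k_A) |x - c|^2."""

    def __init__(self, k_A: float, k_B: float, lam: float, center: np.ndarray,
                 dims: int = 1):
        self.k_A, self.k_B, self.lam = k_A, k_B, lam
        self.center = np.asarray(center, float)
        self.dims = dims

    def evaluate(self, config: Configuration, regions=None):
        from .hamiltonian import EnergyResult

        k = (1.0 - self.lam) * self.k_A + self.lam * self.k_B
        d = config.positions - self.center[None, :]
        d[:, self.dims:] = 0.0
        e = 0.5 * k * float(np.sum(d**2))
        f = -k * d
        dH = 0.5 * (self.k_B - self.k_A) * float(np.sum(d**2))
        return EnergyResult(total=e, components={"harmonic": e}, forces=f,
                            dH_dlambda=dH)


def harmonic_fep_oracle(
    k_A: float,
    k_B: float,
    temperature: float = 298.15,
    n_lambdas: int = 11,
    n_steps: int = 20000,
    dt: float = 0.005,
    mass: float = 16.0,
    dims: int = 1,
    seed: int = 0,
    sample_every: int = 20,
    equil_fraction: float = 0.2,
) -> tuple[float, float, float]:
    """Run the full perturbed-simulation + TI stack on a harmonic toy system.

    A single particle in a harmonic well whose force constant interpolates
    linearly from k_A to k_B is propagated at each lambda point with the
    BAOAB Langevin (canonical) integrator; TI over the grid is compared
    against the closed form dims * (kT/2) ln(k_B/k_A).

    Returns (dG_TI, dG_TI_error, dG_analytic).
    """
    if k_A <= 0 or k_B <= 0:
        raise ValueError("force constants must be positive")
    from .system import Atom, SystemTopology

    box = np.array([50.0, 50.0, 50.0])
    center = box / 2.0
    topo = SystemTopology(
        atoms=[Atom(0, "X", mass, 0.0, 0.0, 0.0, molecule_id=0)],
        inner_molecule_ids={0},
    )
    mask = np.zeros((1, 3), dtype=bool)
    mask[0, :dims] = True
    lambdas = np.linspace(0.0, 1.0, n_lambdas)
    samples = []
    for i, lam in enumerate(lambdas):
        ev = HarmonicLambdaEvaluator(k_A, k_B, lam, center, dims=dims)
        opts = MDOptions(
            dt=dt, n_steps=n_steps, temperature=temperature,
            thermostat="langevin", seed=seed * 1009 + i, sample_every=sample_every,
            remove_com=False, dof_override=dims, velocity_mask=mask, wrap=False,
        )
        init = Configuration(positions=center[None, :].copy(), box=box.copy())
        traj = run_simulation(topo, init, ev, opts)
        d = traj.energy_series["dH_dlambda"].to_numpy()
        skip = int(equil_fraction * len(d))
        samples.append([d[skip:]])
    series = ti_series_from_samples(lambdas, samples)
    dG, err = ti_integrate(series)
    dG_exact = dims * 0.5 * KB * temperature * float(np.log(k_B / k_A))
    return dG, err, dG_exact


# ---------------------------------------------------------------------------
# Structural observables
# ---------------------------------------------------------------------------

def _frames(traj) -> list[Configuration]:
    return traj.frames if isinstance(traj, Trajectory) else list(traj)


def rdf(
    traj,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
    r_max: float,
    n_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two atom selections.

    Normalized with the shell volume and the partner density so that
    g(r) -> 1 for uncorrelated particles.  r_max must not exceed half the
    smallest box length.
    """
    frames = _frames(traj)
    sel_a = np.asarray(sel_a, int)
    sel_b = np.asarray(sel_b, int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    box = frames[0].box
    if r_max > min(box) / 2.0 + 1e-12:
        raise ValueError("r_max exceeds half the smallest box length")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    same = set(sel_a.tolist()) == set(sel_b.tolist())
    n_pairs_per_frame = 0.0
    for cfg in frames:
        if same:
            ii, jj = np.triu_indices(len(sel_a), k=1)
            d = minimum_image_displacements(
                cfg.positions[sel_a[jj]] - cfg.positions[sel_a[ii]], cfg.box
            )
        else:
            a, b = np.meshgrid(sel_a, sel_b, indexing="ij")
            d = minimum_image_displacements(
                cfg.positions[b.ravel()] - cfg.positions[a.ravel()], cfg.box
            )
        r = np.linalg.norm(d, axis=1)
        hist += np.histogram(r, bins=edges)[0]
    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n_ideal = len(sel_a) * (len(sel_a) - 1) / 2.0 * shell / volume
    else:
        n_ideal = len(sel_a) * len(sel_b) * shell / volume
    g = hist / (len(frames) * n_ideal)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, g


def count_hbonds(
    traj,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_max: float = 0.25,
    angle_min: float = 135.0,
) -> tuple[np.ndarray, dict[int, int], float]:
    """Geometric hydrogen-bond count per frame.

    A donor (D, H) and an acceptor A form a hydrogen bond when the H...A
    distance is at most ``d_max`` and the D-H...A angle (at the hydrogen;
    180 deg = linear) is at least ``angle_min``.  Returns per-frame counts,
    an occurrence histogram and the mean count.
    """
    frames = _frames(traj)
    counts = np.zeros(len(frames), dtype=int)
    for k, cfg in enumerate(frames):
        n = 0
        for d_idx, h_idx in donors:
            for a_idx in acceptors:
                if a_idx == d_idx or a_idx == h_idx:
                    continue
                ha = minimum_image_displacements(
                    cfg.positions[a_idx] - cfg.positions[h_idx], cfg.box
                )
                r_ha = float(np.linalg.norm(ha))
                if r_ha > d_max:
                    continue
                hd = minimum_image_displacements(
                    cfg.positions[d_idx] - cfg.positions[h_idx], cfg.box
                )
                cos_t = float(np.dot(hd, ha) / (np.linalg.norm(hd) * r_ha))
                angle = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
                if angle >= angle_min:
                    n += 1
        counts[k] = n
    hist: dict[int, int] = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    return counts, hist, float(counts.mean())


def signed_plane_angle(
    pos_c: np.ndarray,
    pos_o: np.ndarray,
    pos_h: np.ndarray,
    pos_hw: np.ndarray,
    box: np.ndarray,
) -> float:
    """Signed angle (deg) between the C-O-H plane and the C-O...HW plane.

    Both planes share the C-O axis; the angle is the dihedral-like rotation
    of the O->HW direction relative to the O->H direction about that axis,
    in (-180, 180].  Raises for collinear C-O-H geometry.
    """
    u = minimum_image_displacements(pos_o - pos_c, box)
    u = u / np.linalg.norm(u)
    a = minimum_image_displacements(pos_h - pos_o, box)
    b = minimum_image_displacements(pos_hw - pos_o, box)
    a_perp = a - np.dot(a, u) * u
    b_perp = b - np.dot(b, u) * u
    if np.linalg.norm(a_perp) < 1e-8:
        raise ValueError("collinear C-O-H geometry: plane undefined")
    if np.linalg.norm(b_perp) < 1e-8:
        raise ValueError("HW lies on the C-O axis: plane undefined")
    x = float(np.dot(a_perp, b_perp))
    y = float(np.dot(np.cross(a_perp, b_perp), u))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def plane_angle_distribution(
    traj,
    c_idx: int,
    o_idx: int,
    h_idx: int,
    water_donors: Sequence[tuple[int, int]],
    d_max: float = 0.25,
    angle_min: float = 135.0,
    n_bins: int = 72,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Histogram of the tetrahedrality plane angle over a trajectory.

    For every frame, each water donor (OW, HW) currently hydrogen-bonding to
    the solute oxygen contributes one signed plane angle.
    """
    frames = _frames(traj)
    angles: list[float] = []
    for cfg in frames:
        for ow, hw in water_donors:
            ha = minimum_image_displacements(
                cfg.positions[o_idx] - cfg.positions[hw], cfg.box
            )
            r_ha = float(np.linalg.norm(ha))
            if r_ha > d_max:
                continue
            hd = minimum_image_displacements(
                cfg.positions[ow] - cfg.positions[hw], cfg.box
            )
            cos_t = float(np.dot(hd, ha) / (np.linalg.norm(hd) * r_ha))
            ang_dha = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
            if ang_dha < angle_min:
                continue
            angles.append(
                signed_plane_angle(
                    cfg.positions[c_idx], cfg.positions[o_idx],
                    cfg.positions[h_idx], cfg.positions[hw], cfg.box,
                )
            )
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist = np.histogram(angles, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist, angles


def bond_power_spectrum(
    series: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of a uniformly sampled bond-length series.

    The mean-removed autocorrelation is Hann-windowed and Fourier
    transformed; the frequency axis is returned in wavenumbers (cm^-1).
    A constant series yields zero power at all nonzero frequencies.
    """
    x = np.asarray(series, float)
    if x.ndim != 1 or len(x) < 64:
        raise ValueError("need a 1-D series of length >= 64")
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = x - x.mean()
    n = len(x)
    # autocorrelation via FFT (biased estimator)
    fx = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(fx * np.conj(fx))[:n] / n
    window = np.hanning(2 * n)[n:]
    spec = np.abs(np.fft.rfft(acf * window))
    freq = np.fft.rfftfreq(n, d=dt)          # 1/ps
    wavenumber = freq / C_CM_PER_PS          # cm^-1
    return wavenumber, spec
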