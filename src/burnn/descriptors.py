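"""Invariant symmetry-function descriptors for the delta-energy regressors.

The feature vector combines, per (region-pair group, element pair) channel:

* Gaussian radial basis values summed over pairs (smooth fingerprint),
* physics-motivated radial bases r, r^2 and softened Coulomb/dispersion
  forms 1/(r+d), 1/(r+d)^2, (s^2/(r^2+d^2))^3, (s^2/(r^2+d^2))^6 (the
  functional families of harmonic, Coulomb and Lennard-Jones terms, as used
  by linear ML potentials of the SNAP/ACE family; the softening keeps the
  features bounded when a decoupled particle is approached closely),
* local-density-weighted Coulomb channels (rho_i + rho_j)/(r+d) and
  (rho_i rho_j)/(r+d), which linearize polarization-like many-body couplings,

plus angle features over inner-region triples and embedding-style
sum-of-sqrt(local density) features per element at several widths.  For
buffer-buffer channels the density weights enter as *differences* between
the full-cluster and buffer-only densities, mirroring the structure of the
delta target V(I+Buf) - V(Buf) in which plain buffer-internal terms cancel.

Groups: ``II`` (inner-inner pairs), ``IB`` (inner-buffer), ``BB``
(buffer-buffer).  All features are invariant under global translation,
rotation and permutation of identical atoms, and smooth in the coordinates
(up to the inherent discontinuity when a molecule enters or leaves the
buffer).  The analytic Jacobian with respect to atom positions supports
force prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .system import Configuration, SystemTopology, minimum_image_displacements

__all__ = ["DescriptorSpec", "build_descriptor"]

_GROUPS = ("II", "IB", "BB")


@dataclass
class DescriptorSpec:
    """Channel layout and basis parameters of the symmetry-function set."""

    elements: tuple[str, ...]
    n_radial: int = 16
    r_grid_inner: tuple[float, float] = (0.08, 0.5)    # nm, II Gaussian grid
    r_grid_cross: tuple[float, float] = (0.1, 1.5)     # nm, IB/BB Gaussian grid
    density_width: float = 0.35                        # nm, weighting density
    embed_specs: tuple[tuple[float, float], ...] = (
        (0.35, 0.05), (0.25, 0.1), (0.5, 0.02)
    )                                                   # (width nm, eps)
    n_angular: int = 4
    r_soften: float = 0.04      # nm, short-range softening of the soft variants
    _N_PHYS = 12        # r, r^2, 1/r, 1/r^2, r^-6, r^-12, softened variants,
                        # and two Born-Mayer decays exp(-r/0.025), exp(-r/0.05)
    _N_DENS = 2         # (rho_i+rho_j)/r and rho_i*rho_j/r

    def __post_init__(self) -> None:
        self.elements = tuple(sorted(set(self.elements)))
        self.pairs = list(combinations_with_replacement(self.elements, 2))
        self.block = self.n_radial + self._N_PHYS + self._N_DENS
        self.n_pair_features = len(_GROUPS) * len(self.pairs) * self.block
        self.n_embed = 2 * len(self.embed_specs) * len(self.elements)
        self._grids = {}
        for g in _GROUPS:
            lo, hi = self.r_grid_inner if g == "II" else self.r_grid_cross
            centers = np.linspace(lo, hi, self.n_radial)
            width = 1.2 * (centers[1] - centers[0])
            self._grids[g] = (centers, width)
        self._pair_index = {
            (g, a, b): k
            for k, (g, (a, b)) in enumerate(
                (g, p) for g in _GROUPS for p in self.pairs
            )
        }

    @property
    def n_features(self) -> int:
        return self.n_pair_features + self.n_angular + self.n_embed

    @classmethod
    def from_topology(cls, topo: SystemTopology, **kwargs) -> "DescriptorSpec":
        return cls(elements=tuple(a.element for a in topo.atoms), **kwargs)

    # ------------------------------------------------------------------
    def features(self, config, topo, inner_atoms, buffer_atoms) -> np.ndarray:
        x, _, _ = self._impl(config, topo, inner_atoms, buffer_atoms, False)
        return x

    def features_jacobian(self, config, topo, inner_atoms, buffer_atoms):
        """Features, Jacobian (n_features, m, 3) and the subset atom list."""
        return self._impl(config, topo, inner_atoms, buffer_atoms, True)

    # ------------------------------------------------------------------
    def _impl(self, config, topo, inner_atoms, buffer_atoms, want_jac):
        inner = np.asarray(inner_atoms, int)
        buffer = np.asarray(buffer_atoms, int)
        if len(inner) == 0:
            raise ValueError("descriptor requires a nonempty inner set")
        sub = np.concatenate([inner, buffer])
        m, ni = len(sub), len(inner)
        elems = np.array([topo.atoms[int(a)].element for a in sub])

        # featurize the same unwrapped cluster geometry the reference engine
        # sees: make the subset whole relative to its first atom, then use
        # plain (non-periodic) pair vectors
        ref = config.positions[sub[0]]
        pos = minimum_image_displacements(
            config.positions[sub] - ref, config.box
        )
        dv = pos[None, :, :] - pos[:, None, :]  # dv[i, j] = r_j - r_i
        r = np.linalg.norm(dv, axis=-1)
        np.fill_diagonal(r, np.inf)
        inv_r_mat = 1.0 / r
        unit = dv * inv_r_mat[:, :, None]

        x = np.zeros(self.n_features)
        J = np.zeros((self.n_features, m, 3)) if want_jac else None

        # weighting densities at the primary width
        w0 = self.density_width
        phi0 = np.exp(-((r / w0) ** 2))
        with np.errstate(invalid="ignore"):
            dphi0 = -2.0 * r / w0**2 * phi0
        np.fill_diagonal(dphi0, 0.0)
        rho_f = phi0.sum(axis=1)
        rho_b = np.zeros(m)
        if m > ni:
            rho_b[ni:] = phi0[ni:, ni:].sum(axis=1)

        # accumulators: dF/drho for density-coupled features
        dens_cpl: list[tuple[int, np.ndarray, np.ndarray]] = []  # (feat, g_f, g_b)

        idx = np.arange(m)
        group_pairs = []
        if ni >= 2:
            ii, jj = np.triu_indices(ni, k=1)
            group_pairs.append(("II", ii, jj))
        if ni and m > ni:
            A, B = np.meshgrid(idx[:ni], idx[ni:], indexing="ij")
            group_pairs.append(("IB", A.ravel(), B.ravel()))
        if m - ni >= 2:
            ii, jj = np.triu_indices(m - ni, k=1)
            group_pairs.append(("BB", idx[ni:][ii], idx[ni:][jj]))

        for g, A, B in group_pairs:
            centers, width = self._grids[g]
            rr = r[A, B]
            ea, eb = elems[A], elems[B]
            swap = ea > eb
            lo = np.where(swap, eb, ea)
            hi = np.where(swap, ea, eb)
            if g == "BB":
                w1 = (rho_f[A] + rho_f[B]) - (rho_b[A] + rho_b[B])
                w2 = rho_f[A] * rho_f[B] - rho_b[A] * rho_b[B]
            else:
                w1 = rho_f[A] + rho_f[B]
                w2 = rho_f[A] * rho_f[B]
            for (e1, e2) in self.pairs:
                sel = (lo == e1) & (hi == e2)
                if not np.any(sel):
                    continue
                base = self._pair_index[(g, e1, e2)] * self.block
                rs = rr[sel]
                As, Bs = A[sel], B[sel]
                delta = self.r_soften
                inv = 1.0 / rs
                inv6 = (0.3 * inv) ** 6
                inv_s = 1.0 / (rs + delta)          # softened 1/r
                s2 = rs**2 + delta**2
                lj6 = (0.3**2 / s2) ** 3            # softened r^-6 analogue
                # Gaussian radial block
                diff = rs[:, None] - centers[None, :]
                G = np.exp(-0.5 * (diff / width) ** 2)
                x[base : base + self.n_radial] += G.sum(axis=0)
                # physics radial block: exact short-range forms (repulsive
                # wall, Coulomb) plus bounded softened variants
                bm1 = np.exp(-rs / 0.025)
                bm2 = np.exp(-rs / 0.05)
                p_vals = np.stack(
                    [rs, rs**2, inv, inv**2, inv6, inv6**2,
                     inv_s, inv_s**2, lj6, lj6**2, bm1, bm2]
                )
                pb = base + self.n_radial
                x[pb : pb + self._N_PHYS] += p_vals.sum(axis=1)
                # density-weighted block (exact Coulomb kernel)
                db = pb + self._N_PHYS
                x[db] += float(np.sum(w1[sel] * inv))
                x[db + 1] += float(np.sum(w2[sel] * inv))
                if want_jac:
                    dG = -diff / width**2 * G
                    d_phys = np.stack(
                        [
                            np.ones_like(rs),
                            2 * rs,
                            -(inv**2),
                            -2 * inv**3,
                            -6 * 0.3**6 * inv**7,
                            -12 * 0.3**12 * inv**13,
                            -(inv_s**2),
                            -2 * inv_s**3,
                            -6 * rs * 0.3**6 / s2**4,
                            -12 * rs * 0.3**12 / s2**7,
                            -bm1 / 0.025,
                            -bm2 / 0.05,
                        ]
                    )
                    u = unit[As, Bs]
                    # radial derivative contributions: dF/dr per pair
                    for k in range(self.n_radial):
                        contrib = dG[:, k][:, None] * u
                        np.add.at(J[base + k], Bs, contrib)
                        np.add.at(J[base + k], As, -contrib)
                    for k in range(self._N_PHYS):
                        contrib = d_phys[k][:, None] * u
                        np.add.at(J[pb + k], Bs, contrib)
                        np.add.at(J[pb + k], As, -contrib)
                    # density channels: direct 1/r part
                    for k, w in ((0, w1[sel]), (1, w2[sel])):
                        contrib = (-w * inv**2)[:, None] * u
                        np.add.at(J[db + k], Bs, contrib)
                        np.add.at(J[db + k], As, -contrib)
                    # density channels: dF/drho vectors
                    g_f1 = np.zeros(m)
                    np.add.at(g_f1, As, inv)
                    np.add.at(g_f1, Bs, inv)
                    g_f2 = np.zeros(m)
                    np.add.at(g_f2, As, rho_f[Bs] * inv)
                    np.add.at(g_f2, Bs, rho_f[As] * inv)
                    if g == "BB":
                        g_b1 = -g_f1.copy()
                        g_b2 = np.zeros(m)
                        np.add.at(g_b2, As, -rho_b[Bs] * inv)
                        np.add.at(g_b2, Bs, -rho_b[As] * inv)
                    else:
                        g_b1 = np.zeros(m)
                        g_b2 = np.zeros(m)
                    dens_cpl.append((db, g_f1, g_b1))
                    dens_cpl.append((db + 1, g_f2, g_b2))

        # propagate density gradients through all pairs
        if want_jac and dens_cpl:
            ai, bj = np.triu_indices(m, k=1)
            dphi_pairs = dphi0[ai, bj]
            u_pairs = unit[ai, bj]
            in_buf = np.zeros(m, bool)
            in_buf[ni:] = True
            buf_pair = in_buf[ai] & in_buf[bj]
            for feat, g_f, g_b in dens_cpl:
                wpair = g_f[ai] + g_f[bj]
                if np.any(g_b):
                    wpair = wpair + np.where(buf_pair, g_b[ai] + g_b[bj], 0.0)
                contrib = (wpair * dphi_pairs)[:, None] * u_pairs
                np.add.at(J[feat], bj, contrib)
                np.add.at(J[feat], ai, -contrib)

        # angle features over inner triples (vertex j)
        abase = self.n_pair_features
        for j in range(ni):
            for i in range(ni):
                if i == j:
                    continue
                for k in range(i + 1, ni):
                    if k == j:
                        continue
                    vij = dv[j, i]
                    vkj = dv[j, k]
                    nij, nkj = r[j, i], r[j, k]
                    c = float(np.dot(vij, vkj) / (nij * nkj))
                    c = min(1.0, max(-1.0, c))
                    theta = np.arccos(c)
                    vals = np.array(
                        [theta, theta**2, np.cos(theta), np.cos(2 * theta)]
                    )
                    x[abase : abase + self.n_angular] += vals[: self.n_angular]
                    if want_jac:
                        sin_t = np.sqrt(max(1.0 - c * c, 1e-12))
                        dth_i = -(vkj / nkj - c * vij / nij) / (nij * sin_t)
                        dth_k = -(vij / nij - c * vkj / nkj) / (nkj * sin_t)
                        dvals = np.array(
                            [1.0, 2 * theta, -np.sin(theta), -2 * np.sin(2 * theta)]
                        )[: self.n_angular]
                        for a, dth in ((i, dth_i), (k, dth_k), (j, -(dth_i + dth_k))):
                            J[abase : abase + self.n_angular, a] += (
                                dvals[:, None] * dth[None, :]
                            )

        # embedding features: per (width, eps) and element,
        # sum over subset of sqrt(rho_full + eps) minus the buffer-only sum,
        # plus the corresponding linear density difference
        ebase = self.n_pair_features + self.n_angular
        f = ebase
        for w, eps in self.embed_specs:
            phw = np.exp(-((r / w) ** 2))
            with np.errstate(invalid="ignore"):
                dphw = -2.0 * r / w**2 * phw
            np.fill_diagonal(dphw, 0.0)
            rf = phw.sum(axis=1)
            rb = np.zeros(m)
            if m > ni:
                rb[ni:] = phw[ni:, ni:].sum(axis=1)
            for e in self.elements:
                sel = elems == e
                selb = sel & (np.arange(m) >= ni)
                sq_f = np.sqrt(rf + eps)
                sq_b = np.sqrt(rb + eps)
                x[f] += float(sq_f[sel].sum() - sq_b[selb].sum())
                x[f + 1] += float(rf[sel].sum() - rb[selb].sum())
                if want_jac:
                    g_f_sq = np.where(sel, 0.5 / sq_f, 0.0)
                    g_b_sq = np.where(selb, -0.5 / sq_b, 0.0)
                    g_f_lin = sel.astype(float)
                    g_b_lin = -selb.astype(float)
                    ai, bj = np.triu_indices(m, k=1)
                    in_buf = np.arange(m) >= ni
                    buf_pair = in_buf[ai] & in_buf[bj]
                    for ftarget, gf, gb in ((f, g_f_sq, g_b_sq), (f + 1, g_f_lin, g_b_lin)):
                        wpair = gf[ai] + gf[bj] + np.where(
                            buf_pair, gb[ai] + gb[bj], 0.0
                        )
                        contrib = (wpair * dphw[ai, bj])[:, None] * unit[ai, bj]
                        np.add.at(J[ftarget], bj, contrib)
                        np.add.at(J[ftarget], ai, -contrib)
                f += 2

        subset = [int(a) for a in sub]
        if want_jac:
            return x, J, subset
        return x, None, subset


def build_descriptor(
    config: Configuration,
    topo: SystemTopology,
    inner_atoms,
    buffer_atoms,
    cutoff: float = 1.5,
    spec: DescriptorSpec | None = None,
) -> np.ndarray:
    """Invariant feature vector for (inner, buffer) atom sets."""
    if spec is None:
        spec = DescriptorSpec.from_topology(topo, r_grid_cross=(0.1, cutoff))
    return spec.features(
        config, topo, np.asarray(inner_atoms, int), np.asarray(buffer_atoms, int)
    )
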