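# Methods

## The three-region Hamiltonian

The system is split per molecule into an inner region I (the solutes of
interest), a buffer Buf (solvent within a cutoff of I, default 0.5 nm,
reassigned every step by minimum atom–atom distance), and an outer region O.
The total energy is

    V = [V_ref(I+Buf) − V_ref(Buf)] + V_MM(Buf) + V_MM(O)
        + V_MM(Buf↔O) + V_MM(I↔O) + restraints

The bracketed *delta* term carries the reference-level (QM-like) physics of
the inner region and its polarizable surroundings; everything else is
classical.  Two interchangeable sources provide the delta: two explicit
reference-engine calls ("burqm" mode) or a trained committee model ("burnn"
mode).  Because buffer-internal plain terms cancel in the difference, the
delta decays with distance from the inner region and is learnable.

### Alchemical coupling

For a dual-topology pair (A, B) the perturbed Hamiltonian is

    V(λ) = intra_A + intra_B
           + (1−λ)[Δ_A(I_A,Buf) − intra_A] + λ[Δ_B(I_B,Buf) − intra_B]
           + V_MM(Buf) + V_MM(O) + V_MM(Buf↔O)
           + (1−λ) V_MM(I_A↔O) + λ V_MM(I_B↔O) + restraints

Separate inner-only models (`intra_A`, `intra_B`) keep the decoupled
molecule's intramolecular surface alive at all λ — without them the
vanishing molecule would lose the forces that maintain its conformation.
At λ=0 this is exactly the unperturbed Hamiltonian of solvated A plus the
spectator intra_B term (checked to 1e-10 kJ/mol); the linear coupling makes
∂H/∂λ configuration-dependent but λ-independent, which also makes
exponential-averaging cross-checks exact post-processing of recorded
∂H/∂λ samples.  A↔B cross interactions are excluded at all λ; the
harmonic distance restraint holding the pair together is λ-independent and
cancels around thermodynamic cycles.

The MM↔model "vertical" legs interpolate H(μ) = (1−μ)H_MM + μH_model at a
fixed end state with dH/dμ = H_model − H_MM.

## The mock reference engine

A stateless analytic engine stands in for a quantum-chemistry code.  On an
unwrapped cluster it evaluates: harmonic bonds/angles with shifted
equilibria and stiffened force constants (a change of level of theory),
plain LJ, a Born-Mayer exchange-repulsion core b·exp(−r/ρ₀) on all
non-excluded pairs (electrons repel everywhere; unlike a force field no
atom is a bare point charge), Coulomb with density-scaled charges
q_i(1 + c·ρ_i), and an embedding term A·Σ_i[√(ρ_i+ε) − √ε] with Gaussian
local densities ρ_i.  The last two are genuinely many-body: the delta is
provably not pairwise decomposable (a test exhibits the violation), which
is the premise that makes a buffer region and a learned delta worthwhile.
Defaults (c = 0.03, A = −2 kJ/mol, w = 0.35 nm, b = 5·10⁴ kJ/mol,
ρ₀ = 0.025 nm) were chosen for physically modest polarization and a
realistic repulsive wall; stronger first guesses caused an unphysical
polarization collapse of the water cluster.  All terms are exactly
differentiable and forces are analytic.

## Descriptors and the committee

The descriptor is a Behler-Parrinello/SNAP-style symmetry-function vector
over the *unwrapped* inner+buffer cluster (the same geometry the engine
sees): per (group ∈ {II, IB, BB}, element pair) channel it sums Gaussian
radial basis values, physics-motivated radial bases (r, r², 1/r, 1/r²,
r⁻⁶, r⁻¹², softened variants, two Born-Mayer decays) and local-density-
weighted Coulomb channels (ρ_i+ρ_j)/r and ρ_iρ_j/r; for BB channels the
density weights are *differences* between full-cluster and buffer-only
densities, mirroring the cancellation structure of the delta.  Angle
features over inner triples and per-element embedding-style density sums
complete the vector.  Everything is invariant under translation, rotation
and permutation of identical atoms, smooth in the coordinates (up to the
inherent buffer-membership discontinuity), and carries an analytic
Jacobian.

Committee members are identically configured regressors differing only in
their random train/holdout splits.  The default member is a ridge model on
standardized features whose fit includes force-matching rows (reference
gradients are linear in the same weights, so the normal equations stay
closed-form; weight 0.03, ~20 gradient components per record).  An RBF
kernel-ridge member is available as an option.  Crucially the model learns
the *residual* between the reference delta and its exact MM-level analogue
(`cluster_delta_baseline`): the MM baseline supplies physically correct
walls and asymptotics everywhere, so the learned correction stays bounded
off-distribution.  Energies are the predictive member's output plus the
recorded reference constant plus the baseline; forces are its exact
analytic gradient (energy-conservative between region reassignments);
the committee spread is the Query-by-Committee error proxy.

Training data are MD snapshots labeled by the engine: classical and
reference-level runs at λ ∈ {0, ½, 1}, optional steepest-descent
minimization intermediates, one-sided outlier curation at
mean + 439.32 kJ/mol (105 kcal/mol; 690.36 kJ/mol selectable), mean
subtraction of the targets (the reference constant), adaptive QbC rounds
over the pool, and `refine_models` rounds over model-driven FEP
trajectories (label high-disagreement frames, retrain) — the loop that
supplies exactly the configurations initial data do not cover.

## Sampling and estimation

Leapfrog with SHAKE (numba-accelerated Gauss-Seidel; velocity projection
for constrained velocity resampling), Berendsen weak coupling (default,
τ = 0.1 ps), an Andersen collision thermostat (canonical; used for FEP
legs), and a BAOAB-family Langevin integrator for unconstrained systems
(used wherever averages are compared against closed forms — leapfrog +
Andersen showed a ~4 % configurational bias on a stiff oscillator).
Default timesteps: 0.5 fs unconstrained, 2 fs with constraints; velocities
start from a seeded Maxwell-Boltzmann draw.  Nonbonded MM interactions use
shifted-potential truncation (default cutoff 1.0 nm on the 2.1 nm toy box):
subtracting V(r_c) keeps the energy continuous as pairs cross the cutoff;
an abrupt cutoff injected hundreds of kJ/mol of spurious energy per ps.
The soft-core form is Beutler-style (softened r⁶/r² denominators) with the
shift handled consistently in ∂H/∂λ; at each molecule's fully coupled
endpoint it reduces to the plain potential exactly, and at α = 0 to linear
coupling.

Free energies are trapezoidal TI over the λ grid with block-averaged
(≥10 blocks) standard errors, replicas combined by inverse variance.
Bidirectional exponential averaging over the same ∂H/∂λ samples is the
test-only independent estimator.  Cycle closure is the signed leg sum with
root-sum-square error and an oriented-walk topology check.

## The toy world

The standard fixture is a dual-topology pair — a 3-site polar solute
(united CH₃, O, H; SPC-like water parameters for the solvent) as state A
and a single apolar united-atom site as state B — restrained together
(d₀ = 0, k = 5000 kJ/mol/nm²; the overlap means the coupled molecule's
excluded volume shields the decoupled one, which is why soft-core is
optional), in 50 rigid 3-site waters in a 2.1 nm box.  The box is chosen so
that the inner+buffer cluster diameter stays below half the box length
(required for consistent unwrapping); at 50 waters this puts the solvent at
roughly a quarter of liquid density.  Consequences: the buffer holds ~3–6
waters rather than a full shell, H-bond statistics are sparser than liquid
water, and absolute solvation free energies are not comparable to
experiment — none of which the self-consistency checks (endpoint
identities, closed forms, cycle closure, estimator agreement) depend on.

## What the tests do and do not establish

Green tests establish: the Hamiltonian algebra is self-consistent
(endpoints, ∂H/∂λ, forces as exact gradients), the sampling stack recovers
closed-form harmonic free energies within statistical error, the four-leg
cycle closes within its propagated error (a state-function check that holds
for *any* self-consistent surrogate, independent of its accuracy), the
committee reaches sub-0.5 kJ/mol held-out RMSE on the fixture and its
disagreement ranks errors, and the analysis operators reproduce geometric
and spectral constructions.  They do not establish ns-scale converged free
energies, liquid-density solvation structure, or transferability of the
surrogate beyond the sampled ensembles.

## Known limitations

* Region reassignment makes the Hamiltonian piecewise-smooth; energy is
  conserved only between crossings (the delta's distance decay keeps the
  jumps small, but strict NVE tests freeze the region assignment by using
  a cluster whose molecules never leave the buffer).
* Surrogate-driven trajectories can rarely blow up in unexplored regions;
  FEP legs truncate the crashed tail and re-run the point with fresh
  velocities on a deterministic retry schedule, which slightly biases
  sampling toward well-modeled regions.  More refinement rounds reduce the
  incidence.
* Committee disagreement underestimates force errors (members agree on
  energies more than on gradients); force matching mitigates this.
* Exponential averaging needs a dense λ grid (Δλ·σ(∂H/∂λ) ≲ k_BT); the
  cross-check uses 11 points.
* No Ewald/reaction field, no pressure coupling, no triclinic boxes.
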