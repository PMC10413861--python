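# Methods

## The model

`bdhi` propagates a system of `N` spherical beads with the Ermak–McCammon
Brownian dynamics algorithm including pairwise hydrodynamic interactions
(HIs). One step of length Δt displaces the 3N coordinate vector **R** by

    ΔR = (Δt / kBT) · D·F  +  (∇·D) Δt  +  √(2Δt) · S·U

where **D** is the configuration-dependent diffusion tensor, **F** the
systematic forces, **S** the lower Cholesky factor of **D** (so the random
term satisfies the fluctuation–dissipation theorem, cov = 2 D Δt), **U**
i.i.d. standard normals, and ∇·D the divergence drift that appears whenever
the tensor varies with configuration.

Two tensor models are implemented for beads of one shared radius `a`:

* **full RPY** — the Rotne–Prager–Yamakawa pair tensor. For r ≥ 2a the
  3×3 block is (kBT/8πηr)[(1 + 2a²/3r²) I + (1 − 2a²/r²) r̂r̂ᵀ]; for
  overlapping beads (r < 2a) the regularized form
  (kBT/6πηa)[(1 − 9r/32a) I + (3r/32a) r̂r̂ᵀ], which reaches the
  Stokes–Einstein self term kBT/6πηa at r = 0. The two branches agree at
  r = 2a, the assembled tensor is positive definite for any configuration,
  and its divergence is identically zero.

* **OA-RPY** — the orientational average of the same blocks at fixed
  distance: cross terms vanish (⟨xy/r²⟩ = 0) and the diagonal collapses to
  one scalar per pair (⟨x²/r²⟩ = 1/3),

      D_rr(r) = kBT / (6πηr)              for r ≥ 2a
      D_rr(r) = kBT/(6πηa) · (1 − r/4a)   for r < 2a.

  Both D_rr and its first derivative are continuous at r = 2a (the far-field
  and overlap derivatives coincide there at −kBT/24πηa²), so no junction
  convention is needed. The tensor reduces to an N×N coefficient matrix `C`;
  the dense form is C ⊗ I₃, an average of positive-definite tensors and
  hence positive definite. Because C depends on configuration, the drift is
  non-zero: bead i receives Σ_{j≠i} D_rr′(r_ij) (r_j − r_i)/r_ij, which
  points away from every partner (D_rr′ < 0) — omitting it biases every pair
  inward and collapses flexible chains (see the ablation below).

All OA products exploit the N×N structure: D·F applies `C` to each Cartesian
force component, and the correlated noise is chol(C)·U per component. Both
are algebraically identical to the expanded 3N×3N route (chol(C ⊗ I₃) =
chol(C) ⊗ I₃ with bead-major ordering); the test suite asserts this to
machine precision. Counting scalar multiplications gives 9N² (full) vs 3N²
(OA) for D·F and a (3N)³/N³ = 27-fold ratio for the decomposition.

## Units and solvent

Internal units are Å, ps, kcal/mol; kB = 0.0019872 kcal/mol/K. Solvent
conditions default to water at 25 °C (T = 298.15 K, η = 0.89 cP ≈ 0.1281
kcal·ps/mol/Å³), both configurable through `HydroEnvironment`. All claims
checked here are ratios or relative comparisons and do not depend on this
choice. The default time step is 25 fs, tensor/drift/Cholesky refresh every
100 steps (cached and reused in between; the drift displacements are added
unchanged at every step), neighbor-list refresh every 100 steps, frames
saved every 100 ps. A per-step displacement above 10 Å aborts the run with
a checkpoint.

## Force field

A structure-based (Gō-type) residue-level potential:

* bonds k_b (r − r_eq)², k_b = 20 kcal/mol/Å²;
* angles k_a (θ − θ_eq)², k_a = 10 kcal/mol/rad²;
* dihedrals k_d1 [1 + cos(φ − φ₁)] + k_d3 [1 + cos(3φ − φ₃)], half-heights
  k_d1 = 0.5 and k_d3 = 0.25 kcal/mol. Phases are set per dihedral from the
  native conformation so the native φ minimizes both terms (maxima at
  φ_native + 180° and 3φ_native + 180°);
* native contacts: 12-10 attraction ε[5(σ_eq/r)¹² − 6(σ_eq/r)¹⁰] with the
  5/6 normalization putting the minimum at exactly −ε at r = σ_eq. Contacts
  join residue pairs with any interatomic distance below 5.5 Å in the
  native structure; σ_eq is the native bead–bead distance. ε = 1.0 kcal/mol
  keeps molecules folded; ε = 0.05 kcal/mol emulates unfolded states;
* steric repulsion ε_rep (σ/r)¹² with σ = 4 Å between all other nonbonded
  pairs. The prefactor ε_rep defaults to 1 kcal/mol (a genuinely open
  choice; it only sets the softness of rare close approaches);
* nonbonded terms use a 35 Å cutoff list; bonded (1-2), angle (1-3) and
  dihedral (1-4) pairs are excluded, and native pairs found inside the
  exclusion range are dropped so the two term classes stay disjoint.

Equilibrium bond/angle/dihedral values are taken from the native structure
(the conventional Gō construction; the equivalent choice is not otherwise
determined). Analytic forces for every term are validated against central
finite differences at 1e-6 relative, and the compiled (numba) kernels are
cross-checked against the plain-NumPy reference implementation.

## Model builders and fixtures

Residue-level models place one bead per residue at the Cα (proteins, radius
5.3 Å) or P (RNA, radius 5.5 Å) atom; first model, first chain, altloc A.
Very-coarse-grained models place beads by K-means on residue coordinates
(scikit-learn, seeded restarts), add harmonic bonds (k = 20 kcal/mol/Å²)
between closest pairs until every bead has at least four, and calibrate the
shared bead radius by bisection so the rigid-body Kirkwood short-time
estimate D_trans ≈ (1/3N²) Σ_ij tr(D_ij) matches a target (a desk-scale
stand-in for calibrating against long simulations; it reduces to
Stokes–Einstein for one bead and is monotone in the radius).

Synthetic fixtures make every test self-contained:

* `grid2d` — planar lattice (5.3 Å spacing) for displacement-field demos;
* `chain` — a self-avoiding 3.8 Å bead-spring chain whose generated
  conformation serves as the "native" structure (bonds, angles, dihedrals,
  and weak contacts between beads within 8 Å — at the bead level this
  stands in for the atom-level 5.5 Å criterion, which needs all-atom
  coordinates the fixture does not have);
* `compact_cluster` — the same chain generated under spherical confinement,
  giving a folded-like globule with dense contacts;
* `rigid_cluster` — beads sampled in an ellipsoid (default 40 beads,
  long-axis extent ≈ 38 Å, minimum separation 4.5 Å) joined by a braced
  elastic network with harmonic bonds at native distances and no
  angles/dihedrals/nonbonded terms: all pairs within 14 Å (generic
  rigidity — a bare minimum-degree-4 bond set leaves floppy hinge modes
  with several Å of internal RMSD that decorrelate axis vectors far faster
  than rigid-body rotation) plus bonds from each bead to its 8 farthest
  partners (bracing the soft collective bending modes that a pure cutoff
  network leaves at ~0.5 Å amplitude).

  The spring constant of this network matters for the integrator, not just
  the shape: the explicit Euler step is stable only while
  Δt < 2 / λ_max((D/kBT)·H), with H the Hessian. Because orientational
  averaging removes the strong near-field displacement correlations that
  damp stiff collective modes under the full tensor, the OA critical step
  is roughly half the full-RPY one on dense networks, and at k = 20
  kcal/mol/Å² it falls right at the 25 fs production step (an unstable run
  heats the bond energy by three orders of magnitude without triggering
  the blow-up guard). The rotation benchmark therefore drives the braced
  network with k = 1.5 kcal/mol/Å²: OA critical steps of 85–94 fs across
  fixture seeds (a 3.5× margin) with every internal mode at or below
  ~0.35 Å thermal amplitude. With this class of fixture the simulated
  per-axis D_rot for both tensor kinds matches the rigid-body Kirkwood
  friction-projection prediction for the same bead cluster (verified to
  1–2% on a small fast-rotating cluster sampled for ~750 correlation
  times).

What the fixtures do not emulate: real residue packing, sequence-specific
interactions, solvent-quality effects, or atom-level contact geometry.
Passing tests therefore validate the propagator, tensors and estimators —
not the biophysical realism of any particular molecule.

## Observables

* R_gyr² = (1/N) Σ |r_i − r_mean|² (unweighted).
* D_trans from the Einstein relation ⟨r²⟩ = 6 D δt on center-of-geometry
  displacements at a fixed lag, all (overlapping) origins by default.
* D_rot per principal axis: the structure is aligned to its inertia axes
  (uniform masses); for each axis, among bead pairs whose separation along
  the axis is ≥ 75% of the maximum, the pair with the smallest combined
  perpendicular distance to the axis is selected. θ(δt) = ⟨e(t+δt)·e(t)⟩ of
  the normalized interbead vector is fit by exp(−δt/τ) (unweighted
  least squares on ln θ through the origin, lags with θ > 0.05), and
  D_rot = 1/(2τ).
* Block errors: 1% burn-in, three equal blocks, sample (n−1) standard
  deviation — the 0.1–3.4/3.4–6.7/6.7–10 μs convention applied relatively.

## Scaled problem sizes

Desk-scale runs stand in for the 10 μs production simulations:

* Rotational-deficit benchmark: the 40-bead rigid cluster, 1 μs per tensor
  kind (4×10⁷ steps), D updated every 100 steps, divergence on for the OA
  run. At this length the slowest axis decorrelates ~45 times, so per-axis
  D_rot carries sampling noise of several percent; the fit horizon is 10 ns
  and D_trans uses a 1 ns observation interval (shorter than the 10 ns used
  for 10 μs trajectories, trading a negligible short-time bias for ~10×
  more independent windows). Rigid-body theory (friction projection of the
  assembled tensors onto the rotation modes) predicts a 26–28% OA deficit
  and a D_trans ratio of 1.02 for this cluster, so the simulation estimate
  is expected in the 15–35% band.
* Divergence ablation: unfolded-preset 60-mer chain, three replicas × 20 ns
  per condition (full, OA with drift, OA without drift), R_gyr averaged
  over the second half of each run. The collapse without the drift is an
  order-σ effect well inside this window; the full vs OA-with-drift
  comparison is made at matched, not fully equilibrated, run lengths and is
  asserted within replicate scatter.

## Numerical choices

* Cholesky failure is reported when a pivot² falls below 1e-12 × the
  largest diagonal entry, naming the leading minor.
* Collinear angles are clamped (sin θ floored at 1e-6); degenerate
  dihedrals (collinear b2 or zero-area planes) contribute no force.
* K-means empty clusters are re-initialized internally by scikit-learn.
* Radius calibration bisects on [0.05, 60] Å at 1e-4 relative tolerance.
* The stochastic term can be zeroed through a config flag (`zero_noise`)
  for deterministic checks; it is off by default.
* Trajectories are plain-text XYZ; systems/topologies serialize to JSON.

## Known limitations

* Equal bead radii only (unequal radii are rejected up front).
* No periodic boundaries, Ewald-summed HIs, or wall corrections; no
  Chebyshev/Krylov approximate noise — the exact Cholesky route is the
  point of comparison here, so condition numbers are reported only as a
  diagnostic for such methods.
* The Euler–Maruyama discretization carries O(Δt) bias relative to the
  stiffest retained mode; at the default 25 fs step the bond-relaxation
  bias is at the percent level and shared by both tensor models.
* Rotational estimates on ~1 μs trajectories carry several percent
  sampling noise; production-scale 10 μs runs would tighten them ~3×.
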