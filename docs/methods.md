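# Methods

This note documents the models, algorithms, parameter choices, and
limitations of `polyff` in one place. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
imported from external data.

## Scope and design

The package implements a charge-recursive neural-network (QRNN) potential
and its surrounding workflow for ethylene-glycol-type polymers at desk
scale: structure generation, cluster sampling, labeling, multitask
training, query-by-committee active learning, molecular dynamics, and the
property estimators used to judge a polymer force field (density,
self-diffusivity, heat capacity, torsion statistics, chain size, RDFs).
Reference electronic-structure labeling is out of scope; an analytic
**reference oracle** (below) plays that role so the entire loop is
verifiable against known ground truth.

Units are fixed globally: Å, kcal/mol, kcal/mol/Å, elementary charge e, fs,
K, g/cm³; the Coulomb constant is k_e = 332.0637 kcal·Å/(mol·e²) and
k_B = 1.9872041×10⁻³ kcal/(mol·K). Atom indexing is 0-based; dihedrals are
IUPAC-signed in (−180°, 180°].

## Automatic differentiation

No tensor framework is used; `polyff.autodiff` is a ~500-line reverse-mode
engine over numpy arrays whose vector-Jacobian products are themselves
expressed in engine operations, so `grad(..., create_graph=True)` yields
graphs that can be differentiated again. This gives (a) forces as exact
analytic gradients of the total energy, differentiated **through the
constrained Qeq linear solve** (vjp of `solve(A, b)`: solve against Aᵀ),
and (b) the mixed second-order derivatives ∂²E/∂w∂x that force-matching
losses require. First- and second-order correctness is finite-difference
checked in the suite, including through the linear-solve primitive.

Unless a caller keeps the graph, a backward pass dismantles it afterwards
(the vjp closures form reference cycles that otherwise accumulate for the
cyclic collector — measured 3–4× step-time jitter before this change).

## Descriptors

ANI-style atomic environment vectors: per neighbor element, radial terms
Σ_j exp(−η_R(r_ij − μ_R)²) f_c(r_ij); per unordered element pair, angular
terms 2^{1−ζ}(1 + cos(θ − θ_s))^ζ exp(−η_A((r_ij+r_ik)/2 − μ_A)²)
f_c(r_ij) f_c(r_ik), with the cosine cutoff f_c(r) = ½(cos(πr/r_c)+1). The
angle is taken as arccos of the scaled cosine (factor 0.95) to keep the
derivative finite at collinearity, following common ANI practice.

Defaults (`DescriptorConfig()`): radial cutoff 5.2 Å, 16 shifts on
[0.8, 5.2) Å, η_R = 16 Å⁻²; angular cutoff 3.5 Å, 4 shifts × 8 sections,
η_A = 8 Å⁻², ζ = 32. The reference architecture publishes no AEV
hyperparameters, so these follow the ANI-1x lineage it builds on. The
desk-scale preset keeps full radial resolution (it is cheap and bond-length
resolution matters for the stiff bonded terms) and trims the angular block
to 4 shifts × 4 sections with widths matched to the coarser spacing
(η_A = 2 Å⁻², ζ = 16).

The **charge-weighted radial AEV** multiplies each neighbor's radial
contribution by the neighbor's partial charge; it is exactly linear
(degree-1 homogeneous) in the charges, which the suite asserts. Only the
radial block is charge-weighted, matching the architecture's wording.

## The QRNN potential

Per-element feed-forward networks (weight-normalized linear layers,
w = g·v/‖v‖, CELU activations with α = 1) are used twice:

- **Electronegativity head** χ(AEV, qAEV), output scaled by
  `chi_scale` = 50 kcal/mol/e. Iteration 1 sees a zero charge-weighted
  block; iteration 2 sees the charge-weighted AEV of the first charges.
  Two iterations total (the recursion that names the model); a single
  iteration reproduces a plain Qeq solve exactly, and zeroing the
  charge-feature weights makes iteration 2 a fixed point — both asserted.
- **Energy head** E_i(AEV, q_i, qAEV), output scaled by
  `energy_scale` = 5 kcal/mol, plus a trainable per-element offset e₀.
  The output scales start optimization at the right order of magnitude
  (per-atom residuals after composition regression are a few kcal/mol);
  without them desk-length runs spend their budget growing weights.

**Charge equilibration** solves the (N+1) linear KKT system of
min_q Σᵢ(χᵢqᵢ + ½Jᵢqᵢ²) + Σ_{i<j} k_e qᵢqⱼ erf(r_ij/(√2 γ_ij))/r_ij s.t.
Σq = Q, with per-element trainable hardness J = exp(logJ) (init 250
kcal/mol/e²) and Gaussian width γ = exp(logγ) (init 0.8 Å);
γ_ij = (γ_i² + γ_j²)^½. A `local` mode drops the off-diagonal Coulomb
coupling — the most literal reading of a "simplified" Qeq — and is used in
closed-form tests. Charge conservation |Σq − Q| is asserted below 1e-10 e
after every solve.

**Energy assembly.** E_total = Σᵢ Eᵢ + E_coulomb(q) + E_dispersion, summed
exactly (the breakdown is asserted additive to the bit). By default
E_coulomb uses the same smeared kernel as the Qeq functional — the charges
are then the minimizer of the energy actually summed, and the kernel is
finite as r → 0. The bare k_e qᵢqⱼ/r form required of the standalone
`coulomb_energy` operation is available via `coulomb_kernel="bare"`; with
it, desk-scale training showed loss spikes traced to the 1/r divergence at
bonded distances. Periodic systems use a Wolf damped-shifted sum (α = 0.2
Å⁻¹, cutoff 10 Å) — a deliberate, documented approximation of Ewald
summation at these cell sizes. No short-range exclusion is applied to the
Coulomb term; the atomic networks are free to compensate (the alternative —
screening out bonded pairs — is noted as a variant we did not take).

**Dispersion** is pairwise −C₆/r⁶ with the damping [1 + a(r/R₀)⁻¹²]⁻¹,
a = 6; per-element C₆ (kcal·Å⁶/mol: H 33.5, C 418.2, O 167.3) combined
geometrically and R₀ (Å: 1.001, 1.452, 1.342) by sum — table values, not
hard-coded, converted from a standard per-element dispersion set.

Model bundles (descriptor config + networks + Qeq + dispersion + units) are
single JSON files.

## Batched evaluation

Training and committee scoring concatenate a batch of clusters into flat
atom/pair/triple index arrays and run one graph. Qeq becomes a padded
stacked solve: one (n_b+1)×(n_b+1) system per cluster in a (B, m, m)
batched `np.linalg.solve`, so charge never flows between samples. The
batched path is regression-tested against the per-system path to ~1e-13.
Scatter-adds go through `np.bincount` on raveled indices (≈4× faster than
`np.add.at` at these sizes).

## Trainer

Adam (fixed learning rate, no schedule), decoupled weight decay applied to
the weight-norm parameters (v, g) of the networks only. Task losses:
L_E = mean over structures of ((E_pred − E_ref)/N_atoms)²;
L_g = per-component mean squared force error; L_q = mean squared per-atom
charge error (`atomic_charges` mode) or per-component mean squared dipole
error (`dipole` mode). σ's are trained as log σ from σ = 1; when a batch
carries no force task, σ_g is frozen rather than left to drift on its
log-penalty. Gradients are clipped at global norm 10 (early training can
produce transient Qeq-driven outliers). Fresh models initialize the
per-element offsets e₀ by least squares of training energies on elemental
composition — standard practice that removes the large constant part of
the target before optimization starts.

Reference-protocol defaults are preserved in `TrainConfig()`: α = 1e-3,
weight decay 1e-4, batches 256/1024, 500 epochs of 200,000 samples, 90/10
split (committee members: 60/40). `TrainConfig.desk_scale()` ships the
sizes actually run here: 50 epochs, epoch size 2,000, batch 32–96,
energy+charge tasks. Transfer learning is a warm start from an existing
model (e₀ re-initialization skipped).

## Reference oracle

The oracle labels structures with an analytic force field: harmonic bonds
(O-H 520/0.96, C-O 320/1.43, C-C 310/1.54, C-H 340/1.09 kcal/mol/Å², Å)
and angles (50 kcal/mol/rad², 109.5°), a k(1+cos 3φ) backbone O-C-C-O
torsion (k = 0.5 kcal/mol), Lennard-Jones (ε: H 0.03, C 0.07, O 0.17
kcal/mol; σ: 2.5, 3.5, 3.1 Å, Lorentz–Berthelot) and Coulomb over
role-based charges (hydroxyl O −0.45, hydroxyl H +0.30, ether O −0.30,
C +0.15, methylene H 0), with 1-2/1-3/1-4 exclusions. These parameters are
shipped constants chosen to be *representable* by the learned model's
functional class; they make no claim of chemical realism — which is the
point: they define a ground truth the workflow can provably recover.

Charge labels add a bounded bond-strain response,
qᵢ = q_base,i + λΣ_{j∈bonds(i)}(r₀/r_ij − 1) (λ = 0.1 e, clipped at ±0.3 e,
re-centered per molecule so neutrality is exact), emulating
conformation-dependent tight-binding charges. The oracle's Coulomb *energy*
uses the fixed base charges, keeping its forces exactly analytic.

Chain generation grows the H(OCH₂CH₂)ₙOH backbone by a self-avoiding
random walk over gauche/trans torsion basins (±12° jitter), placing each
carbon's methylene hydrogens as soon as its successor is known so that
steric rejection sees the whole chain, with 5-atom backtracking on dead
ends and a short deterministic L-BFGS-free relaxation (steepest descent) to
relieve residual soft contacts. Liquid cells insert independently generated
chains at random orientations into a cubic box sized for the target
density (default 0.5 g/cm³, ≈1500 atoms in the classical-benchmark preset,
≈8000 in the long-chain preset), rejecting inter-chain contacts < 1.2 Å.

**What the oracle does not emulate:** electronic polarization beyond the
bond-strain response, reactivity, many-body dispersion, realistic torsional
multi-term profiles, and quantum nuclear effects. Tests passing against the
oracle therefore demonstrate that the *workflow* recovers a ground truth in
its representable class — not that the trained models are chemically
accurate for real polyethylene glycol.

## Cluster sampling

Pools are drawn from trajectory frames as N-molecule clusters (center
molecule plus nearest neighbors by minimum-image COM distance, unwrapped
whole, COM at origin), capped by oligomer size (monomer 8, dimer 6, trimer
4). Conformational perturbations apply torsion rotations (±60°) and a
random 30% subset of angle bends (±15°) first — both length-preserving —
then bond stretches (±0.15 Å), then a COM density scaling drawn from
[0.85, 1.15]; the bond-length change is therefore bounded exactly.
Decomposed samples stretch 1–2 random bonds to 1.5–3× their length by
displacing the smaller fragment (atom count preserved; a delete-fragment
variant exists behind a flag). Candidates with nonbonded contacts below
1.4 Å are redrawn: thermal ensembles do not visit such contacts, and a
single deep LJ overlap otherwise dominates any squared-error objective.

## Active learning

Committees hold exactly five models trained on per-member 60/40 splits.
ρ^f sums the per-atom, per-component **population variance** of the five
force predictions and divides by √N_a; reading σ(f) as a standard
deviation instead is available via `statistic="std"` (the formula's σ is
ambiguous; the accompanying text says "variance", which is the default).
Selection takes the top-K by ρ^f with ties broken by pool index, plus K
uniform draws from the remainder (presets 40,000+40,000 for round one,
30,000+30,000 for round two, which scores extracted clusters directly). A
failed labeling aborts the round with nothing appended; appended samples
carry their round id.

## Molecular dynamics

Velocity-Verlet core; NVT via the implicit Nosé–Hoover velocity-Verlet
splitting with thermostat mass Q = g·k_B·T·τ² (τ = 50 fs default); NPT adds
isotropic Berendsen-type cell scaling (τ_p = 2.5 ps, compressibility
4.5e-5 atm⁻¹, scaling clamped to ±2% per step) driven by a central-
difference strain-derivative virial pressure. This barostat is an explicit
approximation: extended-Lagrangian barostats (MTK/Parrinello–Rahman) are
not reproduced, as they serve only as equilibration machinery here.
Production presets follow the reference protocol (dt 0.5 fs, 1 ns,
sampling every 0.5 ps); tests integrate hundreds to thousands of steps.
Initial velocities are Maxwell–Boltzmann at the target temperature with the
COM drift removed, seeded. Per-atom image offsets are carried through
wrapping (and rescaled by the barostat), so unwrapped coordinates and hence
MSDs are exact.

NVE conservation is verified at O(dt²): drift < 1e-3 kcal/mol/atom over
1000 steps at dt 0.25 fs, and halving dt reduces drift ≥ 3×.

## Estimators

- **Density**: mass/volume averaged over the trailing 80% of the run by
  default (the 800-of-1000-ps convention).
- **Diffusivity**: MSD over all time origins at ≤ 512 distinct lags,
  averaged over molecules (or atoms), D = slope/6 by least squares on a lag
  window. Default window 20–80% of the maximum lag; the Brownian-recovery
  tests fit 1–10%, where a memoryless walk has no ballistic regime and the
  long-lag statistical error (relative sd ≈ √(2τ/T/n_walkers)) is smallest.
  Recovery is within 10% for a 64-walker, 10⁴-step seeded generator.
- **Heat capacity**: c_p = (⟨E²⟩ − ⟨E⟩²)/(k_B T²) with population moments
  over the *total-energy* series exactly as the fluctuation formula is
  printed; an enthalpy-based variant is available but non-default (the
  textbook NPT formula uses H = E + PV; at 1 atm and these volumes the PV
  fluctuation term is negligible relative to E fluctuations).
- **RDF**: shell-normalized minimum-image pair histogram averaged over
  frames; same-species pairs counted once and normalized with N(N−1)/V.
- **Radius of gyration**: mass-weighted, per frame, with the variance
  across frames reported (a chain-stiffness diagnostic).
- **Dihedral distributions**: signed angles histogrammed over (−180°,
  180°]; collinear geometries are skipped and counted.

All estimators are pure functions of the trajectory.

## Validation scans

Pair scans extract a molecule and its nearest neighbor, then rigidly
translate one along the COM–COM line over [0.75·d_COM, 3.0·d_COM] on an
endpoint-inclusive grid of n_steps = 500 points (300 in the tetramer
preset), evaluating every supplied calculator per step; failures flag the
step and the scan continues. Fractions > 1 move the molecules apart.
Curves are reported relative to their own minima; minima locations and
(for torsion scans: rigid rotation of the distal fragment over 360°, 5°
steps → 72 configurations) barrier heights (local max minus preceding
local min on the periodic curve) are attached.

## Problem sizes used in the checks

The end-to-end generalization check trains on ≈2,000 oracle-labeled
monomer/dimer/trimer clusters for 50 epochs (desk preset, batch 64–96,
energy+charge tasks) and evaluates held-out tetramer clusters; the measured
per-atom tetramer MAE is ≈1.3× the trimer-validation MAE, within the 2×
bound asserted. The committee experiment uses ≈250 base samples, a ≈300-
sample candidate pool, five members, and three seeds per selection arm.
These sizes are the package's desk-scale study conditions; the
reference-protocol presets (200k-sample epochs, 1 ns MD, 40k selections) are
preserved as configuration defaults and never run by the suite.
`scripts/acceptance.py` re-runs the same pipeline at slightly smaller sizes
(1,200 training samples over 30 epochs; 200-sample committee base) and
records the problem size alongside every quantity it writes.

## Known limitations

- Wolf summation instead of Ewald for periodic electrostatics; Berendsen-
  type barostat instead of MTK; both switchable in principle but the only
  implemented options.
- Brute-force neighbor enumeration (O(N²) per frame): fine to a few
  thousand atoms, not intended beyond.
- Three elements (H, C, O); no reactivity, no spin, no third Qeq iteration.
- The desk-scale trained models are demonstrations of workflow correctness
  on oracle ground truth, not production force fields.
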