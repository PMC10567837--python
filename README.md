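# polyff

Charge-recursive neural-network (QRNN) force fields for polymer simulation,
at desk scale: the complete workflow — descriptor construction, charge
equilibration, multitask training, committee-based active learning,
molecular dynamics, and property analysis — validated end-to-end against a
built-in analytic reference oracle that stands in for the electronic-
structure labeler.

## Who this is for

Researchers developing or studying machine-learned interatomic potentials
for polymers (the reference system is ethylene glycol and its oligomers,
H(OCH₂CH₂)ₙOH), who want a transparent, dependency-light implementation of
the full training-and-validation loop that runs on a laptop.

## The model

Energies are decomposed per atom in the high-dimensional neural-network
potential (HDNNP) tradition, with charges made explicit:

1. Each atom *i* is encoded as an **atomic environment vector** (AEV):
   radial Gaussian shells Σⱼ exp(−η_R (r_ij − μ)²) f_c(r_ij) per neighbor
   element plus ANI-style angular terms, under a cosine cutoff
   f_c(r) = ½(cos(πr/r_c) + 1).
2. Per-element networks map AEVs to **electronegativities** χᵢ; charge
   equilibration (Qeq) minimizes
   E(q) = Σᵢ(χᵢqᵢ + ½Jᵢqᵢ²) + Σ_{i<j} k_e qᵢqⱼ erf(r_ij/√2γ_ij)/r_ij
   subject to Σq = Q, as one linear solve with a Lagrange multiplier.
3. The charges are fed back as a **charge-weighted radial AEV** and the
   electronegativity pass repeats — the charge recursion, fixed at two
   iterations.
4. Final charges join the AEV as inputs to per-element **atomic energy
   networks**; the total energy adds the long-range Coulomb energy of the
   equilibrated charges and a damped −C₆/r⁶ dispersion term,
   f(r) = [1 + a(r/R₀)⁻¹²]⁻¹.
5. Forces are the exact analytic gradient, differentiated through the Qeq
   solve (a small reverse-mode autodiff engine, `polyff.autodiff`, supports
   the second-order gradients force-loss training needs).

Training minimizes the multitask objective

    L = L_E/(2σ_E²) + L_g/(2σ_g²) + L_q/(2σ_q²) + log(σ_E σ_g σ_q)

with trainable task uncertainties σ, where L_q is either the squared dipole
error or the squared per-atom reference-charge error. Active learning
trains a committee of five models on 60/40 splits and scores candidate
clusters by the weight-averaged force variance

    ρ^f = Σᵢ Σ_{x,y,z} σ(f) / √N_a ,

selecting the top-K plus K random samples each round.

Units throughout: Å, kcal/mol, elementary charge, fs, K.

## Worked example

```bash
# a periodic liquid cell of 8 ethylene-glycol monomers at 0.5 g/cm³
polyff gencell --n 1 --chains 8 --density 0.5 --seed 1 --out cell.xyz

# sample a labeled training pool of perturbed clusters from it
echo '{"n_conformational": 60, "n_decomposed": 12}' > plan.json
polyff sample --traj cell.xyz --plan plan.json --seed 1 --out pool.h5

# train a desk-scale QRNN on reference atomic charges (smoke scale:
# one minute of CPU; real runs use thousands of clusters, see below)
echo '{"epochs": 20, "epoch_size": 72, "batch_train": 24}' > train.json
polyff train --dataset pool.h5 --config train.json --desk \
             --label-mode atomic_charges --out model.json
```

The training log streams one record per epoch and ends with

```
epoch=20 train_loss=678.3745980824299 val_energy_mae=582.5170962569929 val_energy_mae_per_atom=32.20186526632962 sigma_E=1.0597201364586728 sigma_g=1.0 sigma_q=0.9656655151670733
model -> model.json (final val MAE 582.5171 kcal/mol)
```

`val_energy_mae` is the held-out total-energy error in kcal/mol (here over
7 validation clusters of ~20 atoms — at this smoke scale the number mostly
demonstrates the plumbing; the end-to-end check in the test suite trains on
≈2,000 clusters, asserts that the per-atom validation error falls by more
than a quarter and that accuracy carries over to unseen tetramer clusters
within 2× of the trimer-validation error). The σ values are the trainable
task uncertainties of the multitask loss. Short NVT dynamics with
the analytic oracle as the calculator, followed by the property estimators:

```bash
polyff md --in cell.xyz --calculator oracle --ensemble NVT --steps 2000 \
          --sample-interval 0.05 --seed 1 --out traj.xyz
polyff props --traj traj.xyz --frame-interval 0.05 --out props.tsv
```

`props.tsv` then contains, for this trajectory,

```
# property	value
density_g_cm3	0.500000
diffusivity_cm2_s	2.327920e-04
cp_kcal_mol_K	8.886017e+02
dihedral_samples	168
```

— the density of the fixed NVT cell, the Einstein diffusivity, the energy-
fluctuation heat capacity, and the number of backbone O-C-C-O torsion
samples in the histogram. (A 1 ps equilibration trajectory is far too short
for converged transport numbers; the values demonstrate the estimators,
which the test suite validates against generators with known answers.)
Pair-separation and torsion scans compare any set of calculators on one
grid:

```bash
polyff pairscan --in cell.xyz --calculators oracle model.json \
                --nsteps 500 --out scan.tsv
polyff torsionscan --in chain.xyz --calculators oracle model.json --out tors.tsv
```

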