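# Methods

This note records the modelling and numerical choices behind the
package, in the spirit of a methods appendix: what the model computes,
which constants and conventions were fixed where more than one
reasonable option existed, what the synthetic data does and does not
emulate, and the known limitations.

## Representation conventions

Features are grouped into irrep blocks `(channel n, rotation order ℓ,
parity p)`. Components within a block are ordered `m = -ℓ..ℓ`; negative
`m` carries the sine-type real harmonic, positive `m` the cosine type,
without the Condon–Shortley phase. The harmonics are *component
normalized*: the `ℓ` block of `Y(u)` for a unit vector has squared norm
`2ℓ+1`, so `Y_0 = 1` and `Y_1 = √3·(y, z, x)`. This keeps every block's
per-component variance near 1 under isotropic directions, which is the
premise of the variance-preserving initialization below.

Real-basis Wigner 3j tensors are obtained from the complex-basis closed
form (evaluated exactly by sympy) through a numerically calibrated
unitary change of basis between the standard complex harmonics and the
package's real harmonics; the residual imaginary part (zero to
~1e-14) is asserted away and the result cached per `(ℓ1, ℓ2, ℓ3)`.
Each tensor-product path output is multiplied by
`sqrt(2ℓ_out+1)/‖C‖_F`, which restores unit variance for
component-normalized inputs and makes the scalar-scalar path an exact
elementwise product.

Two symmetry modes exist. In **E(3) mode** every rotation order carries
both parities and all parity bookkeeping is enforced; this is the mode
used by the inversion tests. In **SE(3) mode** the parity index is
omitted entirely — one block per `ℓ` — which simplifies the layer and
matches the reference model configurations whose printed sizes this
package reproduces. (A strictly even-parity feature set with `ℓ_max=1`
cannot hold the odd-parity `ℓ=1` harmonics under E(3); the SE(3)
reading is the one consistent with the published parameter counts, and
it is the one adopted for those presets.)

Rotation matrices `D_ℓ(R)` for the tests are solved from the harmonics
themselves on a fixed direction sample (`Y(Ru) = D Y(u)` is an exact
linear relation), so they are exact in the package's own component
convention rather than imported from an external phase convention.

## Architecture fixings

The MLP dimension lists (`two_body_dims`, `latent_dims`) are the output
widths of consecutive **bias-free** linear layers; SiLU is applied
between layers and not after the last. A one-entry latent list is
therefore a single matrix, i.e. an effectively linear latent update —
this is what the reference configurations' parameter totals imply, and
it is also the configuration under which the finite-body-order probe
must pass. Environment-embedding projections are single bias-free
matrices (one per layer **plus one** for the initial pair features).
The output MLP is two stacked linear maps (one hidden width, no
nonlinearity).

The scalar inputs to each layer's latent MLP are the *raw* scalar path
outputs of the tensor product (one `n_equivariant`-wide group per
scalar path), concatenated after the previous latent vector. The
equivariant mixing is one learned matrix per output irrep over all
`(path, channel)` combinations landing there. The **final** layer
computes and mixes only scalar-output paths: nothing downstream
consumes higher-order features of the last layer. The residual scalar
update is `x_new = (x_old + MLP(...)·u(r)) / √2` — the
variance-preserving additive form; widths always match because both
MLPs end at the latent width.

With these fixings the parameter counts of the three reference
configurations come out at 9058, 7 375 237 and 17 926 533 exactly (the
two large molecular presets additionally carry trainable per-species
energy shifts, 5 scalars, appropriate for their composition-varying
training targets; the fixed-composition presets keep shift and scale as
data-derived constants). `count_parameters` returns an itemized
breakdown so any alternative fixing can be diagnosed component by
component.

## Internal normalization

All learned linear maps scale by `1/sqrt(fan_in)` at application time,
with weights drawn from a uniform distribution of unit variance
(`U(-√3, √3)`), so activations start near unit variance. Neighbor sums
— the environment embedding and the per-atom energy — divide by
`sqrt(⟨|N(i)|⟩)`, the square root of the dataset-average neighbor
count. Path mixing divides by the square root of its number of
contributing path-channel terms. The radial basis (Bessel functions
times the polynomial envelope) is affinely rescaled per function to
zero mean and unit variance under `r ~ U(0, r_c]`, computed once by
fixed 2^16-point midpoint quadrature (seedless and deterministic); the
exact reference normalization is not public, so variance targeting is
the reproduced *intent*, and no tested quantity depends on its details.

## Targets, losses, training

For fixed-composition datasets, `μ_Z` is the mean per-atom energy over
training frames (identical across species) and `σ_Z` the RMS force
component — the size-extensive choice. For varying composition, `μ_Z`
solves the least-squares system of frame energies against species
counts (minimum-norm solution with a warning when the composition
matrix is rank deficient). The joint loss is a batch MSE on total
energies (optionally divided per atom before squaring, appropriate for
a size-extensive target under MSE) plus a mean squared force-component
error; forces inside the loss are exact gradients, and the loss
gradient therefore uses second-order automatic differentiation.
Optimization is Adam (β = 0.9/0.999, ε = 1e-8, no weight decay) with an
on-plateau scheduler on the validation loss and an exponential moving
average of the weights (decay 0.99) used for validation and as the
final model. Data are re-shuffled every epoch with a per-epoch derived
seed; the whole loop is bit-deterministic given the seed. Checkpoints
store config + normalization + flat parameter arrays (HDF5); optimizer
state is not serialized, so resuming re-runs the loop rather than
continuing it bit-for-bit.

## Synthetic data

The generators produce what the tests need and nothing more: dimer
scans, seeded random liquids with minimum-distance rejection sampling,
and simple-cubic/FCC lattices with optional vacancy and jitter, all
labelled by pairwise Lennard-Jones or Morse energies with analytic
forces. The toy potentials are smoothly truncated with the same
polynomial envelope family as the model's radial basis, so the
reference labels are themselves strictly local and learnable to low
error by a local model — which is what makes the learning smoke test
meaningful. What this does **not** emulate: many-body reference
physics (the labels are pairwise), long-range electrostatics, label
noise, and chemically realistic energy scales. Passing tests therefore
demonstrate correctness and trainability of the machinery, not accuracy
on quantum-mechanical data.

Problem sizes used by the test suite were chosen to keep the whole
suite a desk-scale run: the learning smoke test uses 200 frames of 6
atoms with the small production-shaped configuration (latent width 64,
`ℓ_max=1`, 1 channel) for up to 500 epochs; symmetry and oracle checks
use 4–6-atom clusters; the MD conservation check integrates 1000 NVE
steps at dt = 0.01 fs from a bound low-energy frame (the timestep sits
far below the stiffest vibration period, so the residual drift measures
force consistency rather than integrator error).

## Oracles

Three independent reference computations guard the implementation:

1. **ACE correspondence.** Projections `A_{z,n,ℓ}` of the neighbor
   density onto a radial–chemical–angular basis (the model's Bessel
   basis times a species indicator) are tensor-multiplied into
   body-ordered scalars two ways — products of the summed `A` (the
   density trick) and explicit neighbor-tuple sums — and must agree to
   1e-10. Coupling chains are enumerated over all intermediate irreps;
   both routes share the radial basis, so the check is
   convention-independent.
2. **Recursion–expansion equality.** The layer recursion's pair
   features are recomputed as explicit sums over neighbor tuples
   `(k_1..k_L)` with plain numpy loops, using the environment weights
   the model itself computed; equality to 1e-9 for `L ≤ 2` and ≤ 4
   neighbors. The tuple-index convention (`k_0 = j` is the pair
   partner; each layer contributes one independent neighbor sum) is the
   one under which the expansion reproduces the recursion.
   Budgets are hard errors, never silent truncation.
3. **Body-order probe.** Scaling every neighbor's environment
   contribution by `t` makes the pair energy a polynomial in `t` of
   bounded degree when latent and embedding maps are linear (degree 3
   for two layers); polynomial fits over `t ∈ [-3, 3]` must hit
   residuals at machine precision (tol 1e-12). A SiLU latent track
   fails every fixed degree by many orders of magnitude — the wide `t`
   range is deliberate, so a smooth nonlinearity cannot hide inside a
   low-degree Taylor window.

## Molecular dynamics and observables

Velocity Verlet in eV/Å/fs/amu units (1 eV/Å/amu =
9.648533e-3 Å/fs²), NVE or Berendsen velocity rescaling (production
thermostats such as Nosé–Hoover are out of scope). The RDF estimator
histograms directed pair distances per frame and normalizes by the
ideal-gas shell count at the frame's density (`(N-1)/V`), averaged over
frames; bin width defaults to 0.05 Å, and `r_max` beyond the
minimum-image radius is an error. For open boundaries the reference
volume is the configuration's bounding sphere (a nominal but
rotation-invariant choice). The ADF selects unordered neighbor pairs
within a cutoff of each (optionally species-filtered) central atom —
each triplet counted once, a convention recorded here because both
single- and double-counting conventions appear in the literature — and
is normalized to integrate to 1 over [0°, 180°]. The MSD averages over
selected atoms and multiple time origins on unwrapped coordinates (the
integrator never wraps, so its trajectories are unwrapped by
construction; externally supplied wrapped trajectories without image
flags are the caller's responsibility).

## Known limitations

* Pure-numpy execution: practical for hundreds of atoms and toy
  training runs, not for production simulation.
* The radial-basis normalization reproduces a variance-targeting intent,
  not a published formula; models trained here are not weight-compatible
  with other implementations.
* SE(3)-mode models are not inversion-symmetric by construction (that is
  the point of the mode); use E(3) mode when parity matters.
* Optimizer state is not checkpointed; training resumption restarts the
  optimizer.
* The per-species-pair scale `σ_{Z_i Z_j}` is supported (default 1,
  non-trainable) but no fitting rule is provided for it.
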