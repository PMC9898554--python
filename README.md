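# equipair

Strictly local, E(3)-equivariant, many-body interatomic potentials of the
Allegro family — implemented as a desk-scale scientific Python library
with training, force evaluation, molecular dynamics, and a verification
harness built on the model's own body-order expansion.

## Who this is for

Researchers and students in atomistic simulation who want a transparent,
fully inspectable implementation of a modern equivariant machine-learning
interatomic potential (MLIP): every tensor, coupling coefficient and
gradient is a numpy array you can print. The package trades the raw speed
of GPU frameworks for complete visibility, exact 64-bit arithmetic, and a
suite of independent oracles that *prove* the implementation's symmetry
and body-order properties rather than assume them.

## The model

The total energy of a configuration is decomposed into per-atom and then
per-ordered-pair terms,

```
E_system = Σ_i σ_Z(i) E_i + μ_Z(i),      E_i = (Σ_{j ∈ N(i)} σ_Z(i)Z(j) E_ij) / sqrt(⟨|N(i)|⟩)
```

where `N(i)` is the set of neighbors within a fixed cutoff `r_c` and the
per-species shift/scale `μ_Z, σ_Z` are fitted to the training targets.
Each directed pair `(i, j)` carries two latent tracks updated over
`N_layer` tensor-product layers:

* a **scalar track** `x^{ij,L}`, initialized from a two-body MLP of the
  species one-hots and a Bessel radial basis with a smooth polynomial
  cutoff envelope `u(r)`;
* an **equivariant track** `V^{ij,L}_{n,ℓ,p}` of irrep blocks
  (rotation order `ℓ ≤ ℓ_max`, optional parity `p`), initialized as
  learned weights times the real spherical harmonics `Y_ℓ(r̂_ij)`.

Each layer embeds the central atom's environment as a learned weighted
sum of neighbor harmonics `Σ_k w^{ik,L} Y_ℓ(r̂_ik)`, couples it to
`V^{ij,L-1}` through a Wigner-3j tensor product over all admissible
paths `|ℓ1-ℓ2| ≤ ℓ_out ≤ ℓ1+ℓ2` (capped at `ℓ_max`), feeds the scalar
path outputs back into the scalar track (residually, enveloped by
`u(r_ij)`), and linearly mixes the equivariant path outputs per output
irrep. A final MLP reads the scalar track out as the pair energy
`E_ij`; forces are the exact negative gradient, computed by the
package's own reverse-mode autodiff engine (which also supports the
second-order gradients needed to train on forces).

Because `E_ij` depends only on atoms inside one cutoff sphere, the
receptive field does not grow with depth — unlike message passing, where
it grows as `N_layer · r_c` — which is what makes this family of models
parallelizable to very large systems.

## Worked example

Train a small potential on synthetic Lennard-Jones data and verify it:

```python
import numpy as np
from equipair import AllegroPotential
from equipair.synthetic import GeneratorSpec, ToyPotentialSpec, generate

pot_spec = ToyPotentialSpec("lennard_jones", {"eps": 0.5, "sigma": 1.8},
                            r_cut=4.0, smooth=True, envelope_p=6)
frames = generate(GeneratorSpec(n_frames=200, n_atoms=6, box=5.0,
                                min_distance=1.5, seed=42), pot_spec)

model = AllegroPotential(r_cut=4.0, n_layers=1, ell_max=1,
                         two_body_dims=(32, 64), latent_dims=(64,),
                         output_hidden=32, max_epochs=200, seed=0)
model.fit(frames)
print("parameters:", model.n_parameters_)
print("initial val force MAE:", model.history_[0]["val_force_mae"])
print("final   val force MAE:", model.history_[-1]["val_force_mae"])
print("energy of first frame:", model.predict(frames[:1])[0],
      "reference:", frames[0].energy)
```

Output from one run of this exact script:

```
parameters: 8930
initial val force MAE: 4.319630684822567
final   val force MAE: 0.08460378679012229
energy of first frame: 1.8855460338401175 reference: 1.8558309249729033
```

The validation force error falls from ~4.3 eV/Å (after the first epoch)
to ~0.08 eV/Å within 200 epochs, and the predicted total energy of a
training frame matches its analytic label to ~30 meV. The `verify` command runs the oracle
battery (equivariance, finite-difference forces, strict locality, size
extensivity, recursion-vs-expansion) on any saved checkpoint:

```
equipair count-params --preset li3po4   # itemized parameter count: 9058
equipair verify --model model.h5
```

## Layout

| module | contents |
| --- | --- |
| `equipair.irreps` | real spherical harmonics, real-basis Wigner 3j, tensor products, rotation operators |
| `equipair.radial` | Bessel basis + polynomial cutoff envelope + normalization |
| `equipair.system` | `AtomicSystem`, periodic neighbor lists, extended-XYZ I/O |
| `equipair.model` | the architecture, energy/force evaluation, parameter counting, checkpoints |
| `equipair.training` | losses, target normalization, Adam + scheduler + EMA loop |
| `equipair.synthetic` | Lennard-Jones / Morse toy labels and seeded generators |
| `equipair.ace` | atomic-cluster-expansion and neighbor-tuple-expansion oracles, body-order probe |
| `equipair.md` | velocity-Verlet MD, RDF/ADF/MSD, receptive-field arithmetic |
| `equipair.estimator` | scikit-learn style `AllegroPotential` |
| `equipair.autodiff` | the minimal reverse-mode engine (double-backward capable) |

See `docs/methods.md` for the modelling choices, normalization scheme,
and known limitations.
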