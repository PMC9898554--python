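"""Oracle battery for a concrete model: symmetry, gradients, locality.

Used by the ``verify`` CLI command and convenient in notebooks; the test
suite exercises the same properties at fixed tolerances.
"""

from __future__ import annotations

import numpy as np

from .irreps import RotationOp
from .model import AllegroModel, make_graph
from .system import AtomicSystem


def _random_fixture(model: AllegroModel, rng, n_atoms=6):
    syms = list(rng.choice(model.config.species, size=n_atoms))
    # cluster with pair distances spread around half the cutoff
    pos = rng.uniform(0, 0.8 * model.config.r_cut, size=(n_atoms, 3))
    return AtomicSystem(syms, pos)


def verification_battery(model: AllegroModel, seed: int = 0, n_ops: int = 20):
    """Dict of named checks ``name -> (passed, detail)``."""
    rng = np.random.default_rng(seed)
    report = {}
    system = _random_fixture(model, rng)
    ref = model.predict(system)

    # symmetry
    worst = 0.0
    use_inv = model.config.use_parity
    for k in range(n_ops):
        rot = RotationOp.random(rng, inversion=use_inv and bool(k % 2))
        moved = AtomicSystem(system.symbols, rot.apply_points(system.positions))
        out = model.predict(moved)
        scale = max(1.0, abs(ref.total_energy))
        worst = max(worst, abs(out.total_energy - ref.total_energy) / scale)
        worst = max(worst, np.abs(out.forces - rot.apply_points(ref.forces)).max())
    ops = "rotations+inversions" if use_inv else "rotations (SE(3) mode)"
    report["equivariance"] = (worst < 1e-9, f"worst deviation {worst:.2e} over {ops}")

    # forces vs finite differences
    h = 1e-5
    worst = 0.0
    for i in range(min(3, system.n_atoms)):
        for a in range(3):
            p = system.positions.copy()
            p[i, a] += h
            ep = model.predict(AtomicSystem(system.symbols, p)).total_energy
            p[i, a] -= 2 * h
            em = model.predict(AtomicSystem(system.symbols, p)).total_energy
            worst = max(worst, abs(-(ep - em) / (2 * h) - ref.forces[i, a]))
    report["force_gradient"] = (worst < 1e-6, f"max FD deviation {worst:.2e} eV/A")

    # strict locality
    far = system.positions.mean(axis=0) + np.array([10 * model.config.r_cut, 0, 0])
    syms2 = system.symbols + [model.config.species[0]]
    base = np.vstack([system.positions, far])
    g1 = make_graph(AtomicSystem(syms2, base), model.species_map, model.config.r_cut)
    e1 = model.forward_graph(g1)["pair_energies"].data
    moved = base.copy()
    moved[-1] += rng.normal(scale=0.5, size=3)
    g2 = make_graph(AtomicSystem(syms2, moved), model.species_map, model.config.r_cut)
    e2 = model.forward_graph(g2)["pair_energies"].data
    n = system.n_atoms
    identical = np.array_equal(e1[g1.centers < n], e2[g2.centers < n])
    report["strict_locality"] = (
        identical, "pair energies bit-identical under far perturbation"
        if identical else "pair energies changed",
    )

    # size extensivity on a random periodic cell
    a = 1.2 * model.config.r_cut
    cell = np.eye(3) * a
    syms3 = list(rng.choice(model.config.species, size=3))
    pos3 = rng.uniform(0, a, size=(3, 3))
    unit = AtomicSystem(syms3, pos3, cell, [True] * 3)
    e_unit = model.predict(unit).total_energy
    reps = []
    for ix in range(2):
        for iy in range(2):
            for iz in range(2):
                reps.append(pos3 + np.array([ix, iy, iz]) @ cell)
    sup = AtomicSystem(syms3 * 8, np.vstack(reps), cell * 2, [True] * 3)
    e_sup = model.predict(sup).total_energy
    rel = abs(e_sup - 8 * e_unit) / max(1e-12, abs(8 * e_unit))
    report["size_extensivity"] = (rel < 1e-9, f"2x2x2 supercell rel. err {rel:.2e}")

    # recursion vs tuple expansion, when the budget allows
    from .ace import _MAX_EXPANSION_LAYERS, allegro_expand

    small = AtomicSystem(
        list(rng.choice(model.config.species, size=4)),
        rng.uniform(0, 0.6 * model.config.r_cut, size=(4, 3)),
    )
    g = make_graph(small, model.species_map, model.config.r_cut)
    if model.config.n_layers <= _MAX_EXPANSION_LAYERS:
        out = model.forward_graph(g, return_state=True)
        worst = 0.0
        for layer in range(1, model.config.n_layers + 1):
            exp = allegro_expand(model, g, edge=0, layer=layer)
            v = out["states"][layer].V
            for k, (_, ir) in enumerate(v.layout.blocks):
                if ir in exp:
                    worst = max(worst, np.abs(exp[ir] - v.blocks[k].data[0]).max())
        report["recursion_expansion"] = (
            worst < 1e-9, f"max deviation {worst:.2e}"
        )
    else:
        report["recursion_expansion"] = (True, "skipped: model deeper than budget")
    return report
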