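"""Loss arithmetic, target normalization, and the optimization loop."""

import numpy as np
import pytest

from equipair import autodiff as ad
from equipair.model import AllegroConfig, AllegroModel, make_graph
from equipair.synthetic import GeneratorSpec, ToyPotentialSpec, generate
from equipair.system import AtomicSystem, SpeciesMap
from equipair.training import (
    LossConfig,
    TrainConfig,
    fit_norm_composition_regression,
    fit_norm_fixed_composition,
    joint_loss,
    train,
)


class TestJointLoss:
    def test_zero_when_predictions_equal_labels(self, rng):
        f = rng.normal(size=(4, 3))
        loss = joint_loss(np.array([1.0, 2.0]), f, [1.0, 2.0], f, [2, 2],
                          LossConfig(1.0, 1.0))
        assert float(loss.data) == 0.0

    def test_hand_computed_value(self):
        # 1 frame, 2 atoms: energy residual 0.5, force residuals fixed
        f_pred = np.array([[0.1, 0, 0], [0, -0.2, 0]])
        f_ref = np.zeros((2, 3))
        cfg = LossConfig(lambda_e=2.0, lambda_f=3.0)
        loss = joint_loss(np.array([1.5]), f_pred, [1.0], f_ref, [2], cfg)
        expected = 2.0 * 0.25 + 3.0 / (3 * 2) * (0.01 + 0.04)
        assert float(loss.data) == pytest.approx(expected, rel=1e-12)

    def test_per_atom_variant_divides_energy_residual(self):
        cfg = LossConfig(1.0, 0.0, per_atom=True)
        loss = joint_loss(np.array([4.0]), np.zeros((5, 3)), [0.0],
                          np.zeros((5, 3)), [5], cfg)
        assert float(loss.data) == pytest.approx((4.0 / 5) ** 2)

    def test_variants_agree_for_single_atom_frames(self, rng):
        e_pred = rng.normal(size=3)
        e_ref = rng.normal(size=3)
        f_pred = rng.normal(size=(3, 3))
        f_ref = rng.normal(size=(3, 3))
        a = joint_loss(e_pred, f_pred, e_ref, f_ref, [1, 1, 1], LossConfig(1, 1, False))
        b = joint_loss(e_pred, f_pred, e_ref, f_ref, [1, 1, 1], LossConfig(1, 1, True))
        assert float(a.data) == pytest.approx(float(b.data), rel=1e-12)

    def test_per_atom_loss_invariant_under_replication(self, rng):
        # an exactly extensive model predicts m-fold energies on m-fold systems
        e_pred, e_ref = np.array([2.0]), np.array([1.6])
        f_pred = rng.normal(size=(3, 3))
        f_ref = rng.normal(size=(3, 3))
        base = joint_loss(e_pred, f_pred, e_ref, f_ref, [3], LossConfig(1, 1, True))
        m = 4
        rep = joint_loss(m * e_pred, np.tile(f_pred, (m, 1)), m * e_ref,
                         np.tile(f_ref, (m, 1)), [3 * m], LossConfig(1, 1, True))
        assert float(rep.data) == pytest.approx(float(base.data), rel=1e-12)

    def test_reference_force_weighting_preset(self):
        cfg = LossConfig.molecular_forces()
        assert cfg.lambda_f == 1000.0 and cfg.lambda_e == 1.0 and not cfg.per_atom

    def test_validation(self):
        with pytest.raises(ValueError):
            LossConfig(0.0, 0.0)
        with pytest.raises(ValueError):
            joint_loss(np.ones(2), np.zeros((3, 3)), np.ones(3),
                       np.zeros((3, 3)), [1, 1, 1], LossConfig())


class TestNormalization:
    def test_fixed_composition_mean_per_atom_energy(self):
        s = AtomicSystem(["A"] * 5, np.random.default_rng(0).uniform(0, 8, (5, 3)))
        s.energy = 10.0
        s.forces = np.zeros((5, 3))
        norm = fit_norm_fixed_composition([s], 2, 4.0, sigma_floor=1.0)
        assert np.allclose(norm.shift, 2.0)
        assert np.allclose(norm.scale, 1.0)  # floored

    def test_zero_forces_without_floor_raises(self):
        s = AtomicSystem(["A"], [[0, 0, 0]])
        s.energy, s.forces = 1.0, np.zeros((1, 3))
        with pytest.raises(ValueError):
            fit_norm_fixed_composition([s], 1, 4.0)

    def test_two_frame_moments(self, rng):
        frames = []
        for e in (4.0, 8.0):
            s = AtomicSystem(["A", "A"], rng.uniform(0, 6, (2, 3)))
            s.energy = e
            s.forces = np.ones((2, 3)) * (e / 4)
            frames.append(s)
        norm = fit_norm_fixed_composition(frames, 1, 3.0)
        assert norm.shift[0] == pytest.approx((2.0 + 4.0) / 2)
        assert norm.scale[0] == pytest.approx(np.sqrt((6 * 1 + 6 * 4) / 12))

    def test_regression_recovers_exact_linear_composition(self, rng):
        sm = SpeciesMap(["A", "B"])
        mu_true = np.array([-3.0, 5.0])
        frames = []
        for _ in range(6):
            na, nb = rng.integers(1, 5, size=2)
            syms = ["A"] * na + ["B"] * nb
            s = AtomicSystem(syms, rng.uniform(0, 20, (na + nb, 3)))
            s.energy = na * mu_true[0] + nb * mu_true[1]
            frames.append(s)
        norm = fit_norm_composition_regression(frames, sm, 3.0)
        assert np.abs(norm.shift - mu_true).max() < 1e-10

    def test_regression_with_noise_stays_close(self, rng):
        sm = SpeciesMap(["A", "B"])
        mu_true = np.array([-3.0, 5.0])
        frames = []
        for _ in range(200):
            na, nb = rng.integers(1, 6, size=2)
            s = AtomicSystem(["A"] * na + ["B"] * nb,
                             rng.uniform(0, 50, (na + nb, 3)))
            s.energy = na * mu_true[0] + nb * mu_true[1] + rng.normal(scale=0.1)
            frames.append(s)
        norm = fit_norm_composition_regression(frames, sm, 3.0)
        assert np.abs(norm.shift - mu_true).max() < 0.1

    def test_rank_deficient_composition_warns(self, rng):
        sm = SpeciesMap(["A", "B"])
        frames = []
        for _ in range(4):  # always 1:1 composition -> rank 1
            s = AtomicSystem(["A", "B"], rng.uniform(0, 9, (2, 3)))
            s.energy = 2.0
            frames.append(s)
        with pytest.warns(UserWarning):
            norm = fit_norm_composition_regression(frames, sm, 3.0)
        assert np.allclose(norm.shift.sum(), 2.0, atol=1e-8)

    def test_single_species_regression_reduces_to_mean(self, rng):
        sm = SpeciesMap(["A"])
        frames = []
        for e in (3.0, 5.0):
            s = AtomicSystem(["A", "A"], rng.uniform(0, 9, (2, 3)))
            s.energy = e
            frames.append(s)
        norm = fit_norm_composition_regression(frames, sm, 3.0)
        assert norm.shift[0] == pytest.approx(2.0)


class TestLossGradient:
    def test_parameter_gradient_matches_finite_differences(self):
        cfg = AllegroConfig(
            species=["X"], n_layers=1, ell_max=0, parity="se3",
            n_equivariant=1, two_body_dims=(1,), latent_dims=(1,),
            output_hidden=1, n_basis=1, avg_num_neighbors=2.0, seed=4,
        )
        model = AllegroModel(cfg)
        s = AtomicSystem(["X", "X", "X"], [[0, 0, 0], [0, 0, 1.8], [0, 1.6, 0]])
        s.energy, s.forces = 0.3, np.array([[0.1, 0, 0], [0, -0.1, 0], [0, 0, 0.05]])
        graph = make_graph(s, model.species_map, cfg.r_cut)
        loss_cfg = LossConfig(1.0, 1.0)

        def compute_loss():
            out = model.forward_graph(graph)
            e = out["frame_energies"]
            forces = -ad.grad(e.sum(), out["positions"], create_graph=True)
            return joint_loss(e, forces, [s.energy], s.forces, [3], loss_cfg)

        loss = compute_loss()
        names = list(model.params)
        grads = ad.grad(loss, [model.params[k] for k in names])
        h = 1e-6
        for name, g in zip(names, grads):
            p = model.params[name]
            for idx in np.ndindex(*p.shape):
                orig = p.data[idx]
                p.data[idx] = orig + h
                lp = float(compute_loss().data)
                p.data[idx] = orig - h
                lm = float(compute_loss().data)
                p.data[idx] = orig
                num = (lp - lm) / (2 * h)
                assert abs(num - g.data[idx]) < 1e-6 * max(1.0, abs(num)), name


class TestTrainingLoop:
    @pytest.fixture(scope="class")
    def tiny_run(self, lj_frames):
        cfg = AllegroConfig(
            species=["X"], r_cut=4.0, n_layers=1, ell_max=1, parity="se3",
            n_equivariant=1, two_body_dims=(8, 16), latent_dims=(16,),
            output_hidden=8, envelope_p=6, seed=0,
        )
        norm = fit_norm_fixed_composition(lj_frames, 1, cfg.r_cut)
        cfg.avg_num_neighbors = norm.avg_num_neighbors

        def run():
            model = AllegroModel(cfg, norm)
            log = train(
                model, lj_frames,
                TrainConfig(learning_rate=5e-3, batch_size=12, max_epochs=15, seed=1),
                LossConfig.per_atom_forces(),
            )
            return model, log

        return run

    def test_loss_decreases_on_toy_problem(self, tiny_run):
        _, log = tiny_run()
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_training_is_deterministic_under_seed(self, tiny_run):
        m1, log1 = tiny_run()
        m2, log2 = tiny_run()
        assert log1[-1]["val_loss"] == log2[-1]["val_loss"]
        assert all(
            np.array_equal(m1.params[k].data, m2.params[k].data) for k in m1.params
        )

    def test_energy_only_training_runs(self, lj_frames):
        cfg = AllegroConfig(
            species=["X"], r_cut=4.0, n_layers=1, ell_max=0, parity="se3",
            n_equivariant=1, two_body_dims=(8, 16), latent_dims=(16,),
            output_hidden=8, envelope_p=6, seed=0, avg_num_neighbors=3.0,
        )
        model = AllegroModel(cfg)
        log = train(
            model, lj_frames,
            TrainConfig(learning_rate=5e-3, batch_size=12, max_epochs=5, seed=1),
            LossConfig(lambda_e=1.0, lambda_f=0.0),
        )
        assert len(log) == 5 and np.isfinite(log[-1]["train_loss"])

    def test_metrics_log_written_as_csv(self, tmp_path, lj_frames):
        cfg = AllegroConfig(
            species=["X"], r_cut=4.0, n_layers=1, ell_max=0, parity="se3",
            n_equivariant=1, two_body_dims=(4, 8), latent_dims=(8,),
            output_hidden=4, envelope_p=6, avg_num_neighbors=3.0,
        )
        model = AllegroModel(cfg)
        path = tmp_path / "log.csv"
        train(model, lj_frames,
              TrainConfig(batch_size=12, max_epochs=2, seed=0),
              LossConfig.per_atom_forces(), log_csv=path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("epoch,") and len(lines) == 3
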