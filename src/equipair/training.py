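"""Loss functions, target normalization and the training loop.

The joint loss is a batch MSE on total energies plus a component MSE on
forces::

    L = lambda_E / B * sum_b (E_hat_b - E_b)^2
      + lambda_F / (3 B N) * sum_{i,a} (F_hat_{i,a} - F_{i,a})^2

with the optional per-atom variant dividing each energy residual by the
frame's atom count before squaring (appropriate because the energy is
size-extensive while the loss is an MSE).  Forces inside the loss are
exact gradients, so minimizing it requires second-order differentiation,
which the autodiff engine supports.

Optimization is Adam with an on-plateau learning-rate scheduler and an
exponential moving average (EMA) of the weights used for validation and
for the final model.
"""

from __future__ import annotations

import csv
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import AllegroModel, Graph, NormStats, make_graph
from .system import average_neighbor_count


@dataclass
class LossConfig:
    lambda_e: float = 1.0
    lambda_f: float = 1.0
    per_atom: bool = False

    def __post_init__(self):
        if self.lambda_e < 0 or self.lambda_f < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_e == 0 and self.lambda_f == 0:
            raise ValueError("at least one loss weight must be positive")

    @staticmethod
    def molecular_forces() -> "LossConfig":
        """Total-energy + force loss with force weight 1000."""
        return LossConfig(lambda_e=1.0, lambda_f=1000.0, per_atom=False)

    @staticmethod
    def per_atom_forces() -> "LossConfig":
        """Per-atom energy MSE + force MSE, both weighted 1."""
        return LossConfig(lambda_e=1.0, lambda_f=1.0, per_atom=True)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 500
    max_wall_time: float | None = None  # seconds
    patience: int = 1000  # early stop on stale validation
    scheduler_patience: int = 25
    scheduler_factor: float = 0.5
    lr_floor: float = 1e-5
    lr_stop: float = 0.0  # stop when the lr decays below this (0 disables)
    ema_decay: float = 0.99
    val_fraction: float = 0.1
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        for name in ("scheduler_factor", "ema_decay"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def joint_loss(pred_energy, pred_forces, ref_energy, ref_forces,
               n_atoms_per_frame, cfg: LossConfig):
    """The joint energy/force loss as a differentiable scalar Tensor."""
    pred_energy = ad.astensor(pred_energy)
    pred_forces = ad.astensor(pred_forces)
    ref_energy = np.asarray(ref_energy, dtype=float)
    ref_forces = np.asarray(ref_forces, dtype=float)
    n_atoms = np.asarray(n_atoms_per_frame, dtype=float)
    b = len(ref_energy)
    if pred_energy.shape != (b,) or pred_forces.shape != ref_forces.shape:
        raise ValueError("prediction/label shape mismatch")
    e_res = pred_energy - Tensor(ref_energy)
    if cfg.per_atom:
        e_res = e_res * Tensor(1.0 / n_atoms)
    loss = (e_res ** 2).sum() * (cfg.lambda_e / b)
    if cfg.lambda_f > 0:
        f_res = pred_forces - Tensor(ref_forces)
        loss = loss + (f_res ** 2).sum() * (cfg.lambda_f / (3.0 * ref_forces.shape[0]))
    return loss


# ---------------------------------------------------------------------------
# target normalization
# ---------------------------------------------------------------------------

def _force_rms(systems) -> float:
    comps = np.concatenate([s.forces.ravel() for s in systems])
    return float(np.sqrt(np.mean(comps ** 2)))


def fit_norm_fixed_composition(systems, n_species: int, r_cut: float,
                               sigma_floor: float | None = None) -> NormStats:
    """Normalization for fixed-composition datasets.

    mu_Z (identical for all species) is the mean per-atom energy over
    frames; sigma_Z is the root-mean-square force component.  Degenerate
    all-zero forces raise unless ``sigma_floor`` is configured.
    """
    systems = list(systems)
    if not systems or any(s.energy is None or s.forces is None for s in systems):
        raise ValueError("labelled systems required")
    mu = float(np.mean([s.energy / s.n_atoms for s in systems]))
    sigma = _force_rms(systems)
    if sigma < 1e-12:
        if sigma_floor is None:
            raise ValueError("force RMS is zero; provide sigma_floor")
        sigma = sigma_floor
    return NormStats(
        np.full(n_species, mu), np.full(n_species, sigma),
        None, average_neighbor_count(systems, r_cut),
    )


def fit_norm_composition_regression(systems, species_map, r_cut: float,
                                    sigma_floor: float | None = None) -> NormStats:
    """Per-species shifts from least squares of frame energies on composition.

    Solves ``[N_config,Z] mu = [E_config]``; a rank-deficient composition
    matrix falls back to the pseudo-inverse (minimum-norm) solution with a
    warning.  sigma_Z is the force RMS when forces are present, else 1.
    """
    systems = list(systems)
    if not systems or any(s.energy is None for s in systems):
        raise ValueError("labelled systems required")
    s_count = len(species_map)
    counts = np.zeros((len(systems), s_count))
    energies = np.array([s.energy for s in systems])
    for k, s in enumerate(systems):
        for sym in s.symbols:
            counts[k, species_map.index(sym)] += 1
    rank = np.linalg.matrix_rank(counts)
    if rank < s_count:
        warnings.warn(
            "composition matrix is rank-deficient; "
            "using the minimum-norm least-squares solution",
            stacklevel=2,
        )
    mu, *_ = np.linalg.lstsq(counts, energies, rcond=None)
    if all(s.forces is not None for s in systems):
        sigma = _force_rms(systems)
        if sigma < 1e-12:
            if sigma_floor is None:
                raise ValueError("force RMS is zero; provide sigma_floor")
            sigma = sigma_floor
    else:
        sigma = 1.0
    return NormStats(
        mu, np.full(s_count, sigma), None,
        average_neighbor_count(systems, r_cut),
    )


# ---------------------------------------------------------------------------
# optimizer / scheduler / EMA
# ---------------------------------------------------------------------------

class Adam:
    """Adam over the model's flat parameter dict (no weight decay)."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros(t.shape) for k, t in params.items()}
        self.v = {k: np.zeros(t.shape) for k, t in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k].data[...] = self.params[k].data - self.lr * mhat / (
                np.sqrt(vhat) + self.eps
            )


class ReduceOnPlateau:
    def __init__(self, lr, patience, factor, floor):
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.floor = floor
        self.best = np.inf
        self.stale = 0

    def update(self, metric) -> float:
        if metric < self.best - 1e-12:
            self.best = metric
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.lr = max(self.lr * self.factor, self.floor)
                self.stale = 0
        return self.lr


class EMA:
    """Exponential moving average of the parameters."""

    def __init__(self, params: dict, decay: float):
        self.decay = decay
        self.shadow = {k: t.data.copy() for k, t in params.items()}

    def update(self, params: dict):
        d = self.decay
        for k, t in params.items():
            self.shadow[k] = d * self.shadow[k] + (1 - d) * t.data

    def copy_to(self, params: dict):
        for k in params:
            params[k].data[...] = self.shadow[k]

    def swapped(self, params: dict):
        return _SwapContext(self, params)


class _SwapContext:
    def __init__(self, ema, params):
        self.ema, self.params = ema, params

    def __enter__(self):
        self.backup = {k: t.data.copy() for k, t in self.params.items()}
        self.ema.copy_to(self.params)

    def __exit__(self, *exc):
        for k, t in self.params.items():
            t.data[...] = self.backup[k]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _concat_graphs(graphs: list[Graph]) -> Graph:
    base_atoms = np.cumsum([0] + [len(g.species_idx) for g in graphs])
    return Graph(
        np.concatenate([g.species_idx for g in graphs]),
        np.concatenate([g.positions for g in graphs]),
        np.concatenate([g.centers + b for g, b in zip(graphs, base_atoms)]).astype(np.intp),
        np.concatenate([g.neighbors + b for g, b in zip(graphs, base_atoms)]).astype(np.intp),
        np.concatenate([g.offsets for g in graphs]),
        np.concatenate(
            [g.frame_of_atom + f for g, f in
             zip(graphs, np.cumsum([0] + [g.n_frames for g in graphs]))]
        ),
        sum(g.n_frames for g in graphs),
        np.concatenate([g.n_atoms_per_frame for g in graphs]),
    )


def _evaluate(model, graphs, systems, loss_cfg):
    """Loss and MAEs on a fixed set (no parameter graph needed)."""
    e_err, f_err, losses = [], [], []
    for g, s in zip(graphs, systems):
        out = model.forward_graph(g)
        e = out["frame_energies"]
        forces = -ad.grad(e.sum(), out["positions"])
        loss = joint_loss(
            e, forces, [s.energy], s.forces, [s.n_atoms], loss_cfg
        )
        losses.append(float(loss.data))
        e_err.append(abs(float(e.data[0]) - s.energy) / s.n_atoms)
        f_err.append(np.abs(forces.data - s.forces).mean())
    return float(np.mean(losses)), float(np.mean(e_err)), float(np.mean(f_err))


def train(model: AllegroModel, dataset, train_cfg: TrainConfig,
          loss_cfg: LossConfig, log_csv=None, callback=None):
    """Train in place; returns the per-epoch metrics log (list of dicts).

    The dataset (labelled systems) is split into train/validation by a
    seeded shuffle and re-shuffled every epoch with a per-epoch derived
    seed.  Validation and the final weights use the EMA of the
    parameters.  Divergence (non-finite loss) aborts with a RuntimeError.
    """
    dataset = list(dataset)
    rng = np.random.default_rng(train_cfg.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(train_cfg.val_fraction * len(dataset))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("dataset too small for the requested split")

    r_cut = model.config.r_cut
    graphs = [make_graph(s, model.species_map, r_cut) for s in dataset]
    train_systems = [dataset[i] for i in train_idx]
    val_systems = [dataset[i] for i in val_idx]
    val_graphs = [graphs[i] for i in val_idx]

    opt = Adam(model.params, train_cfg.learning_rate,
               train_cfg.beta1, train_cfg.beta2, train_cfg.eps)
    sched = ReduceOnPlateau(train_cfg.learning_rate, train_cfg.scheduler_patience,
                            train_cfg.scheduler_factor, train_cfg.lr_floor)
    ema = EMA(model.params, train_cfg.ema_decay)
    log = []
    best_val = np.inf
    stale = 0
    t_start = time.time()
    names = list(model.params)

    for epoch in range(train_cfg.max_epochs):
        ep_rng = np.random.default_rng(train_cfg.seed * 100003 + epoch)
        perm = ep_rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(perm), train_cfg.batch_size):
            batch_idx = perm[start: start + train_cfg.batch_size]
            g = _concat_graphs([graphs[i] for i in batch_idx])
            out = model.forward_graph(g)
            e = out["frame_energies"]
            need_force_graph = loss_cfg.lambda_f > 0
            forces = -ad.grad(e.sum(), out["positions"],
                              create_graph=need_force_graph)
            loss = joint_loss(
                e, forces,
                [dataset[i].energy for i in batch_idx],
                np.concatenate([dataset[i].forces for i in batch_idx]),
                [dataset[i].n_atoms for i in batch_idx],
                loss_cfg,
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss); "
                    f"last-good parameters retained on the model"
                )
            grads = ad.grad(loss, [model.params[k] for k in names])
            opt.lr = sched.lr
            opt.step({k: g_.data for k, g_ in zip(names, grads)})
            ema.update(model.params)
            epoch_loss += float(loss.data)
            n_batches += 1

        with ema.swapped(model.params):
            val_loss, e_mae, f_mae = _evaluate(model, val_graphs, val_systems, loss_cfg)
        lr = sched.update(val_loss)
        entry = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(1, n_batches),
            "val_loss": val_loss,
            "val_energy_mae": e_mae,
            "val_force_mae": f_mae,
            "lr": lr,
        }
        log.append(entry)
        if callback is not None:
            callback(entry)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
        if stale > train_cfg.patience:
            break
        if train_cfg.lr_stop > 0 and lr < train_cfg.lr_stop:
            break
        if train_cfg.max_wall_time and time.time() - t_start > train_cfg.max_wall_time:
            break

    ema.copy_to(model.params)
    if log_csv is not None and log:
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0]))
            writer.writeheader()
            writer.writerows(log)
    return log
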