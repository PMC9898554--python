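"""Scikit-learn style front end.

``AllegroPotential`` wraps configuration, target normalization, model
construction and training behind the familiar ``fit``/``predict``
estimator interface so the potential composes with sklearn model
selection.  ``X`` is a list of :class:`~equipair.system.AtomicSystem`;
for ``fit`` the systems carry their own energy/force labels, so ``y`` is
accepted only for API compatibility and must be ``None``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import AllegroConfig, AllegroModel
from .system import AtomicSystem, SpeciesMap
from .training import (
    LossConfig,
    TrainConfig,
    fit_norm_composition_regression,
    fit_norm_fixed_composition,
    train,
)


class AllegroPotential(BaseEstimator):
    """Strictly local equivariant interatomic potential as an estimator.

    Parameters mirror :class:`~equipair.model.AllegroConfig` and
    :class:`~equipair.training.TrainConfig`; fitted state lives in
    trailing-underscore attributes (``model_``, ``norm_``, ``history_``,
    ``n_parameters_``).

    Examples
    --------
    >>> pot = AllegroPotential(r_cut=4.0, max_epochs=100, seed=0)
    >>> pot.fit(labelled_systems)           # doctest: +SKIP
    >>> energies = pot.predict(new_systems) # doctest: +SKIP
    """

    def __init__(self, species=None, r_cut=4.0, n_layers=1, ell_max=1,
                 parity="se3", n_equivariant=1, two_body_dims=(32, 64),
                 latent_dims=(64,), output_hidden=32, n_basis=8,
                 envelope_p=6, latent_nonlinearity="silu",
                 norm_mode="fixed", learning_rate=5e-3, batch_size=10,
                 max_epochs=200, ema_decay=0.99, scheduler_patience=25,
                 scheduler_factor=0.5, val_fraction=0.1,
                 lambda_e=1.0, lambda_f=1.0, per_atom_loss=True, seed=0):
        self.species = species
        self.r_cut = r_cut
        self.n_layers = n_layers
        self.ell_max = ell_max
        self.parity = parity
        self.n_equivariant = n_equivariant
        self.two_body_dims = two_body_dims
        self.latent_dims = latent_dims
        self.output_hidden = output_hidden
        self.n_basis = n_basis
        self.envelope_p = envelope_p
        self.latent_nonlinearity = latent_nonlinearity
        self.norm_mode = norm_mode
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.ema_decay = ema_decay
        self.scheduler_patience = scheduler_patience
        self.scheduler_factor = scheduler_factor
        self.val_fraction = val_fraction
        self.lambda_e = lambda_e
        self.lambda_f = lambda_f
        self.per_atom_loss = per_atom_loss
        self.seed = seed

    # -- sklearn protocol --------------------------------------------------
    def fit(self, X, y=None):
        if y is not None:
            raise ValueError("labels are carried on the systems; pass y=None")
        X = list(X)
        if not X or not isinstance(X[0], AtomicSystem):
            raise ValueError("X must be a non-empty list of AtomicSystem")
        species = self.species or SpeciesMap.from_dataset(X).symbols
        if self.norm_mode == "fixed":
            norm = fit_norm_fixed_composition(X, len(species), self.r_cut)
        elif self.norm_mode == "regression":
            norm = fit_norm_composition_regression(X, SpeciesMap(species), self.r_cut)
        else:
            raise ValueError("norm_mode must be 'fixed' or 'regression'")
        config = AllegroConfig(
            species=list(species), r_cut=self.r_cut, n_layers=self.n_layers,
            ell_max=self.ell_max, parity=self.parity,
            n_equivariant=self.n_equivariant,
            two_body_dims=tuple(self.two_body_dims),
            latent_dims=tuple(self.latent_dims),
            output_hidden=self.output_hidden, n_basis=self.n_basis,
            envelope_p=self.envelope_p,
            latent_nonlinearity=self.latent_nonlinearity,
            avg_num_neighbors=norm.avg_num_neighbors, seed=self.seed,
        )
        self.model_ = AllegroModel(config, norm)
        self.norm_ = norm
        self.n_parameters_, self.parameter_breakdown_ = self.model_.count_parameters()
        self.history_ = train(
            self.model_, X,
            TrainConfig(
                learning_rate=self.learning_rate, batch_size=self.batch_size,
                max_epochs=self.max_epochs, ema_decay=self.ema_decay,
                scheduler_patience=self.scheduler_patience,
                scheduler_factor=self.scheduler_factor,
                val_fraction=self.val_fraction, seed=self.seed,
            ),
            LossConfig(self.lambda_e, self.lambda_f, self.per_atom_loss),
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    def predict(self, X):
        """Total potential energies (eV), one per system."""
        self._check_fitted()
        return np.array([self.model_.predict(s).total_energy for s in X])

    def predict_forces(self, X):
        """Force arrays (eV/Angstrom), one (N, 3) array per system."""
        self._check_fitted()
        return [self.model_.predict(s).forces for s in X]

    def predict_breakdown(self, X):
        """Full energy decompositions (pair/atom/total energies + forces)."""
        self._check_fitted()
        return [self.model_.predict(s) for s in X]

    def score(self, X, y=None):
        """Negative mean absolute force-component error (higher is better)."""
        self._check_fitted()
        errs = [
            np.abs(self.model_.predict(s).forces - s.forces).mean()
            for s in X
            if s.forces is not None
        ]
        if not errs:
            raise ValueError("scoring requires force labels")
        return -float(np.mean(errs))
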