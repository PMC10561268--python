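"""scikit-learn-style estimator facade.

:class:`PredictiveCodingNetwork` packages the training paradigms and the
frozen-weight inference as an unsupervised transformer: ``fit`` runs the
chosen paradigm on a stimulus dataset, ``transform`` maps frames to
converged area representations, and ``inverse_transform`` runs the
generative top-down cascade back to image space.  It composes with sklearn
model selection and pipelines (params via get_params/set_params, fitted
attributes with trailing underscores).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import NetworkConfig
from .core import WeightSet, init_weights
from .representation import RepresentationMatrix, infer_representations
from .stimuli import Dataset, StimulusSequence
from .training import train_continuous, train_static

__all__ = ["PredictiveCodingNetwork"]


class PredictiveCodingNetwork(BaseEstimator, TransformerMixin):
    """Hierarchical predictive-coding network as an unsupervised transformer.

    Parameters mirror :class:`~hpcnet.config.NetworkConfig` plus the
    training paradigm.  ``fit(X)`` expects a :class:`~hpcnet.stimuli.Dataset`
    (or list of sequences); labels are never used.

    Attributes
    ----------
    weights_ : WeightSet
        Learned inter-area weight matrices.
    history_ : TrainingHistory
        Per-epoch record of the summed squared prediction error.
    config_ : NetworkConfig
        The resolved configuration used for training and inference.
    """

    def __init__(
        self,
        area_sizes=(784, 2000, 500, 30),
        inference_rate: float = 0.05,
        learning_rate: float = 0.01,
        activation_offset: float = -2.0,
        inference_steps_per_cycle: int = 10,
        cycles_per_frame: int = 100,
        reset_rate: float = 0.1,
        convergence_tol: float = 1e-4,
        max_convergence_steps: int = 5000,
        reset_per_repetition: bool = False,
        paradigm: str = "continuous",
        epochs: int = 10,
        repetitions: int = 10,
        random_state: int = 0,
    ):
        self.area_sizes = area_sizes
        self.inference_rate = inference_rate
        self.learning_rate = learning_rate
        self.activation_offset = activation_offset
        self.inference_steps_per_cycle = inference_steps_per_cycle
        self.cycles_per_frame = cycles_per_frame
        self.reset_rate = reset_rate
        self.convergence_tol = convergence_tol
        self.max_convergence_steps = max_convergence_steps
        self.reset_per_repetition = reset_per_repetition
        self.paradigm = paradigm
        self.epochs = epochs
        self.repetitions = repetitions
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_config(self) -> NetworkConfig:
        return NetworkConfig(
            area_sizes=tuple(self.area_sizes),
            inference_rate=self.inference_rate,
            learning_rate=self.learning_rate,
            activation_offset=self.activation_offset,
            inference_steps_per_cycle=self.inference_steps_per_cycle,
            cycles_per_frame=self.cycles_per_frame,
            reset_rate=self.reset_rate,
            seed=self.random_state,
            convergence_tol=self.convergence_tol,
            max_convergence_steps=self.max_convergence_steps,
            reset_per_repetition=self.reset_per_repetition,
        )

    @staticmethod
    def _as_dataset(X) -> Dataset:
        if isinstance(X, Dataset):
            return X
        seqs = list(X)
        if not all(isinstance(s, StimulusSequence) for s in seqs):
            raise TypeError("X must be a Dataset or an iterable of StimulusSequence")
        n_classes = max(s.object_label for s in seqs) + 1
        return Dataset(
            sequences=seqs, n_classes=n_classes, image_shape=seqs[0].image_shape
        )

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "PredictiveCodingNetwork":
        """Train the network on a stimulus dataset (unsupervised)."""
        dataset = self._as_dataset(X)
        config = self._make_config()
        if self.paradigm == "continuous":
            trainer = train_continuous
        elif self.paradigm == "static":
            trainer = train_static
        else:
            raise ValueError("paradigm must be 'continuous' or 'static'")
        self.weights_, self.history_ = trainer(
            dataset,
            config,
            epochs=self.epochs,
            seed=self.random_state,
            repetitions=self.repetitions,
        )
        self.config_ = config
        return self

    def initialize(self) -> "PredictiveCodingNetwork":
        """Install freshly initialized (untrained) weights without fitting."""
        self.config_ = self._make_config()
        self.weights_ = init_weights(self.config_, seed=self.random_state)
        from .training import TrainingHistory

        self.history_ = TrainingHistory(paradigm="none", seed=self.random_state)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("this PredictiveCodingNetwork is not fitted yet")

    def transform(self, X, area: int | None = None) -> np.ndarray:
        """Converged representations of every frame (rows, sequence-major)."""
        self._check_fitted()
        dataset = self._as_dataset(X)
        area = len(self.config_.area_sizes) - 1 if area is None else area
        reps = infer_representations(self.weights_, dataset, self.config_, area)
        return reps.data

    def representations(self, X, area: int | None = None) -> RepresentationMatrix:
        """Like :meth:`transform` but returning the labelled container."""
        self._check_fitted()
        dataset = self._as_dataset(X)
        area = len(self.config_.area_sizes) - 1 if area is None else area
        return infer_representations(self.weights_, dataset, self.config_, area)

    def inverse_transform(self, R: np.ndarray, area: int | None = None) -> np.ndarray:
        """Top-down cascade from area representations back to input images."""
        from .generative import topdown_reconstruct

        self._check_fitted()
        area = len(self.config_.area_sizes) - 1 if area is None else area
        R = np.atleast_2d(np.asarray(R, dtype=float))
        out = np.stack(
            [
                topdown_reconstruct(self.weights_, r, area, config=self.config_)[0]
                for r in R
            ]
        )
        return out
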