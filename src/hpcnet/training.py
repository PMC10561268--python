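"""Training paradigms.

Two paradigms share one nested loop — epochs over sequences, 10 repetitions
of each sequence, frames within a repetition, inference-learning cycles per
frame.  They differ only in where network activity is reset to the uniform
low value:

* **continuous** — reset once at the start of each sequence's repetition
  block; activity carries over between frames and repetitions, so the
  lingering representation of the previous frame acts as a temporal prior
  that binds consecutive views of the same object together.
* **static** — reset before every frame; each view is inferred from scratch
  and no temporal structure is available to the learning rule.

Learning happens only here: every cycle runs ``inference_steps_per_cycle``
activity updates followed by one Hebbian weight update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .core import (
    NetworkState,
    WeightSet,
    clamp_input,
    compute_errors,
    hebbian_update,
    init_weights,
    inference_step,
    reset_state,
    total_squared_error,
    update_activations,
)
from .stimuli import Dataset

__all__ = ["TrainingHistory", "train_continuous", "train_static", "set_speed"]


@dataclass
class TrainingHistory:
    """Per-epoch record of the implicit objective and loop bookkeeping.

    ``total_error[e]`` is the summed squared prediction error measured at
    the end of every frame presentation during epoch e; ``area_error_norms``
    resolves it per error population.  The counters audit the loop
    structure (number of Hebbian updates and activity resets per epoch).
    """

    total_error: list = field(default_factory=list)
    area_error_norms: list = field(default_factory=list)  # per epoch: (L,) array
    hebbian_updates: list = field(default_factory=list)  # per epoch: int
    resets: list = field(default_factory=list)  # per epoch: int
    paradigm: str = ""
    seed: int | None = None
    config: dict | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.total_error)


def _train(
    dataset: Dataset,
    config: NetworkConfig,
    epochs: int,
    seed: int | None,
    *,
    reset_every_frame: bool,
    repetitions: int = 10,
    weights: WeightSet | None = None,
) -> tuple[WeightSet, TrainingHistory]:
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if weights is None:
        weights = init_weights(config, seed=config.seed if seed is None else seed)
    history = TrainingHistory(
        paradigm="static" if reset_every_frame else "continuous",
        seed=config.seed if seed is None else seed,
        config=config.to_dict(),
    )
    L = len(config.area_sizes) - 1
    for _epoch in range(epochs):
        epoch_error = 0.0
        area_norms = np.zeros(L)
        n_updates = 0
        n_resets = 0
        for seq in dataset:
            state = None
            if not reset_every_frame:
                state = reset_state(config)
                n_resets += 1
            for rep in range(repetitions):
                if not reset_every_frame and config.reset_per_repetition and rep > 0:
                    state = reset_state(config)
                    n_resets += 1
                for frame in seq.frames:
                    if reset_every_frame:
                        state = reset_state(config)
                        n_resets += 1
                    clamp_input(state, frame)
                    for _cycle in range(config.cycles_per_frame):
                        for _step in range(config.inference_steps_per_cycle):
                            compute_errors(state, weights)
                            update_activations(state, weights, config)
                        hebbian_update(weights, state, config)
                        n_updates += 1
                    compute_errors(state, weights)
                    epoch_error += total_squared_error(state)
                    area_norms += np.array(
                        [float(np.linalg.norm(b)) for b in state.beta]
                    )
        history.total_error.append(epoch_error)
        history.area_error_norms.append(area_norms)
        history.hebbian_updates.append(n_updates)
        history.resets.append(n_resets)
    return weights, history


def train_continuous(
    dataset: Dataset,
    config: NetworkConfig,
    epochs: int,
    seed: int | None = None,
    repetitions: int = 10,
    weights: WeightSet | None = None,
) -> tuple[WeightSet, TrainingHistory]:
    """Train on temporally continuous sequences.

    Activity is reset once at the start of each sequence's repetition block
    (or before every repetition if ``config.reset_per_repetition``) and
    carries over between frames.
    """
    return _train(
        dataset,
        config,
        epochs,
        seed,
        reset_every_frame=False,
        repetitions=repetitions,
        weights=weights,
    )


def train_static(
    dataset: Dataset,
    config: NetworkConfig,
    epochs: int,
    seed: int | None = None,
    repetitions: int = 10,
    weights: WeightSet | None = None,
) -> tuple[WeightSet, TrainingHistory]:
    """Train on isolated frames: activity is reset before every frame."""
    return _train(
        dataset,
        config,
        epochs,
        seed,
        reset_every_frame=True,
        repetitions=repetitions,
        weights=weights,
    )


def set_speed(config: NetworkConfig, speed: float) -> NetworkConfig:
    """Scale the stimulus timescale: divide the per-frame cycles by `speed`.

    Speed 2 halves the number of inference steps spent on each frame.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    return config.replace(cycles_per_frame=int(round(config.cycles_per_frame / speed)))
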