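"""Network configuration.

All architectural and numeric hyperparameters of the hierarchical
predictive-coding network live in a single frozen dataclass so that every
experiment can be reproduced from one record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of a hierarchical predictive-coding network.

    Parameters
    ----------
    area_sizes
        Number of neurons per area, lowest (input) first.  Index 0 is the
        input area whose rates are clamped to pixel intensities; every
        higher area holds representation neurons, and every area except the
        top one holds an error population of the same size.
    inference_rate
        Step size of the activation-state update (membrane dynamics).
    learning_rate
        Step size of the Hebbian weight update.
    activation_offset
        Constant lateral offset of the firing threshold: rates are
        ``sigmoid(x + activation_offset)``.  Negative values keep resting
        rates low.
    inference_steps_per_cycle
        Number of activity-update steps between consecutive weight updates.
    cycles_per_frame
        Number of inference-learning cycles spent on each video frame
        during training (and during frozen-weight presentation of a frame).
    reset_rate
        The uniform low firing rate installed in every area when activity
        is reset at a sequence boundary.  Must lie strictly in (0, 1).
    seed
        Default seed for weight initialization.
    convergence_tol
        Relative change of the total squared prediction error between
        consecutive cycles below which inference on a still image is
        considered converged.
    max_convergence_steps
        Cap on the number of cycles when running to convergence.
    reset_per_repetition
        If True, continuous training resets activity before every
        repetition of a sequence instead of once per 10-repetition block.
    reconstruct_through_sigmoid
        If True, top-down reconstruction passes intermediate-area
        predictions through the rate nonlinearity instead of installing
        the raw linear prediction.
    """

    area_sizes: tuple[int, ...] = (784, 2000, 500, 30)
    inference_rate: float = 0.05
    learning_rate: float = 0.01
    activation_offset: float = -2.0
    inference_steps_per_cycle: int = 10
    cycles_per_frame: int = 100
    reset_rate: float = 0.1
    seed: int = 0
    convergence_tol: float = 1e-4
    max_convergence_steps: int = 5000
    reset_per_repetition: bool = False
    reconstruct_through_sigmoid: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "area_sizes", tuple(int(n) for n in self.area_sizes))
        if len(self.area_sizes) < 2:
            raise ValueError("area_sizes needs at least an input and one higher area")
        if any(n < 1 for n in self.area_sizes):
            raise ValueError("every area needs at least one neuron")
        if self.inference_rate <= 0:
            raise ValueError("inference_rate must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not (0.0 < self.reset_rate < 1.0):
            raise ValueError("reset_rate must lie strictly in (0, 1)")
        if self.inference_steps_per_cycle < 0:
            raise ValueError("inference_steps_per_cycle must be >= 0")
        if self.cycles_per_frame < 0:
            raise ValueError("cycles_per_frame must be >= 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.max_convergence_steps < 1:
            raise ValueError("max_convergence_steps must be >= 1")

    @property
    def n_areas(self) -> int:
        """Number of areas including the input area."""
        return len(self.area_sizes)

    @property
    def top_area(self) -> int:
        """Index of the highest area (which has no error population)."""
        return len(self.area_sizes) - 1

    def replace(self, **changes) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["area_sizes"] = list(self.area_sizes)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls.from_dict(json.loads(s))
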