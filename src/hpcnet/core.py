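"""State containers and single-step dynamics of the predictive-coding network.

The network is a stack of areas.  Area 0 holds the input: its rates are
clamped linearly to pixel intensities.  Every higher area l carries an
activation state ``x_l`` (membrane potential) and a rate ``y_l =
sigmoid(x_l + offset)``.  Every area below the top additionally carries an
error population ``beta_l = y_l - W_l y_{l+1}``: the mismatch between the
area's own rates and the top-down prediction generated by the area above
through the weight matrix ``W_l``.  The same matrix, transposed, routes the
errors back up during inference — the weights are used symmetrically by
construction.

All operations accept rate/error vectors of shape ``(n,)`` or batched
matrices of shape ``(n, B)`` holding B independent network copies that share
one weight set; batching is used by the frozen-weight analyses, never during
learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .config import NetworkConfig

__all__ = [
    "NetworkState",
    "WeightSet",
    "init_weights",
    "reset_state",
    "clamp_input",
    "compute_errors",
    "update_activations",
    "inference_step",
    "hebbian_update",
    "inference_cycle",
    "run_to_convergence",
    "total_squared_error",
    "save_checkpoint",
    "load_checkpoint",
]


class WeightSet:
    """The inter-area weight matrices ``W_l`` of shape (n_l, n_{l+1}).

    ``W_l`` generates the top-down prediction ``W_l @ y_{l+1}`` for area l
    and, transposed, carries area-l errors up to area l+1.
    """

    def __init__(self, matrices):
        self.W = [np.asarray(m, dtype=float) for m in matrices]
        for l in range(len(self.W) - 1):
            if self.W[l].shape[1] != self.W[l + 1].shape[0]:
                raise ValueError(
                    f"weight shapes are not chainable at area {l + 1}: "
                    f"{self.W[l].shape} -> {self.W[l + 1].shape}"
                )

    def __len__(self) -> int:
        return len(self.W)

    def __getitem__(self, l: int) -> np.ndarray:
        return self.W[l]

    def __iter__(self):
        return iter(self.W)

    @property
    def area_sizes(self) -> tuple[int, ...]:
        return tuple([m.shape[0] for m in self.W] + [self.W[-1].shape[1]])

    def copy(self) -> "WeightSet":
        return WeightSet([m.copy() for m in self.W])

    def allclose(self, other: "WeightSet", **kw) -> bool:
        return len(self) == len(other) and all(
            np.allclose(a, b, **kw) for a, b in zip(self.W, other.W)
        )


@dataclass
class NetworkState:
    """Per-area activations ``x``, rates ``y`` and errors ``beta``.

    ``x[0]`` is unused (the input area has no membrane dynamics) and kept as
    zeros; ``beta`` has one entry per area below the top.
    """

    x: list
    y: list
    beta: list

    @property
    def top(self) -> int:
        return len(self.y) - 1

    @property
    def batch_size(self) -> int | None:
        """None for a single-network state, B for a batched one."""
        return None if self.y[0].ndim == 1 else self.y[0].shape[1]

    def copy(self) -> "NetworkState":
        return NetworkState(
            [a.copy() for a in self.x],
            [a.copy() for a in self.y],
            [a.copy() for a in self.beta],
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def init_weights(config: NetworkConfig, seed: int | None = None) -> WeightSet:
    """Draw the initial weights.

    Each entry is a clipped Gaussian ``max(0, g)`` with ``g ~ N(0, 0.5)``,
    divided by the number of neurons in the next (higher) area, so that the
    summed top-down prediction stays of order one.  Non-negative by
    construction; learning is free to drive entries negative later.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.area_sizes
    mats = []
    for l in range(len(sizes) - 1):
        g = rng.normal(0.0, 0.5, size=(sizes[l], sizes[l + 1]))
        mats.append(np.clip(g, 0.0, None) / sizes[l + 1])
    return WeightSet(mats)


def reset_state(config: NetworkConfig, batch_size: int | None = None) -> NetworkState:
    """Set all activity to the uniform low value ``reset_rate``.

    The activation state is placed at the unique pre-activation consistent
    with the rate equation, ``x = logit(reset_rate) - offset``, and all
    errors are cleared.
    """
    if not (0.0 < config.reset_rate < 1.0):  # defensive; config validates too
        raise ValueError("reset_rate must lie strictly in (0, 1)")
    shape = (lambda n: (n,)) if batch_size is None else (lambda n: (n, batch_size))
    x0 = float(logit(config.reset_rate)) - config.activation_offset
    sizes = config.area_sizes
    x = [np.zeros(shape(sizes[0]))]
    y = [np.full(shape(sizes[0]), config.reset_rate)]
    for n in sizes[1:]:
        x.append(np.full(shape(n), x0))
        y.append(np.full(shape(n), config.reset_rate))
    beta = [np.zeros(shape(n)) for n in sizes[:-1]]
    return NetworkState(x, y, beta)


def _flatten_frames(frame: np.ndarray, n_pixels: int) -> np.ndarray:
    """Frame(s) -> column vector(s): (n,) for one image, (n, B) for a stack."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim <= 2 and frame.size == n_pixels:
        return frame.reshape(n_pixels)
    # a batch: leading axis enumerates images
    flat = frame.reshape(frame.shape[0], -1)
    if flat.shape[1] != n_pixels:
        raise ValueError(
            f"frame has {flat.shape[1]} pixels, input area expects {n_pixels}"
        )
    return flat.T


def clamp_input(state: NetworkState, frame: np.ndarray) -> NetworkState:
    """Clamp input-area rates linearly to the pixel intensities of `frame`.

    No nonlinearity is applied to area 0; higher areas are untouched.
    """
    n0 = state.y[0].shape[0]
    flat = _flatten_frames(frame, n0)
    if flat.ndim != state.y[0].ndim:
        if flat.ndim == 1 and state.batch_size is not None:
            flat = np.broadcast_to(flat[:, None], state.y[0].shape).copy()
        else:
            raise ValueError("frame batch does not match state batch")
    elif flat.shape != state.y[0].shape:
        raise ValueError(
            f"frame batch {flat.shape} does not match input area {state.y[0].shape}"
        )
    if flat.min() < 0.0 or flat.max() > 1.0:
        raise ValueError("pixel intensities must lie in [0, 1]")
    state.y[0] = flat
    return state


def compute_errors(state: NetworkState, weights: WeightSet) -> NetworkState:
    """beta_l = y_l - W_l y_{l+1} for every area below the top (in place)."""
    for l in range(state.top):
        state.beta[l] = state.y[l] - weights[l] @ state.y[l + 1]
    return state


def update_activations(
    state: NetworkState, weights: WeightSet, config: NetworkConfig
) -> NetworkState:
    """One synchronous activation step from the freshly computed errors.

    Interior areas integrate bottom-up errors minus their own error;
    the top area, having no error population, integrates bottom-up errors
    only.  Rates follow as ``sigmoid(x + offset)``; area 0 stays clamped.
    """
    eps = config.inference_rate
    top = state.top
    for l in range(1, top):
        state.x[l] = state.x[l] + eps * (
            weights[l - 1].T @ state.beta[l - 1] - state.beta[l]
        )
    state.x[top] = state.x[top] + eps * (weights[top - 1].T @ state.beta[top - 1])
    off = config.activation_offset
    for l in range(1, top + 1):
        state.y[l] = _sigmoid(state.x[l] + off)
    return state


def inference_step(
    state: NetworkState, weights: WeightSet, config: NetworkConfig
) -> NetworkState:
    """Error computation followed by one synchronous activation update."""
    compute_errors(state, weights)
    return update_activations(state, weights, config)


def hebbian_update(
    weights: WeightSet, state: NetworkState, config: NetworkConfig
) -> WeightSet:
    """Hebbian weight change from coactive error and representation neurons.

    ``W_l += learning_rate * beta_l y_{l+1}^T`` — an exact gradient step on
    the summed squared prediction error with the rates held fixed.  No
    clipping, decay or normalization is applied.
    """
    lr = config.learning_rate
    for l in range(state.top):
        b, r = state.beta[l], state.y[l + 1]
        if b.ndim == 1:
            weights.W[l] += lr * np.outer(b, r)
        else:
            weights.W[l] += lr * (b @ r.T)
    return weights


def total_squared_error(state: NetworkState) -> float | np.ndarray:
    """Sum of squared prediction errors over all error populations.

    Scalar for a single-network state; a length-B vector for a batch.
    """
    if state.batch_size is None:
        return float(sum(float(np.dot(b, b)) for b in state.beta))
    return sum(np.einsum("nb,nb->b", b, b) for b in state.beta)


def inference_cycle(
    state: NetworkState,
    weights: WeightSet,
    frame: np.ndarray,
    config: NetworkConfig,
    n_steps: int | None = None,
) -> NetworkState:
    """Clamp `frame` and run one cycle of pure inference (no learning)."""
    clamp_input(state, frame)
    steps = config.inference_steps_per_cycle if n_steps is None else n_steps
    for _ in range(steps):
        inference_step(state, weights, config)
    return state


def run_to_convergence(
    state: NetworkState,
    weights: WeightSet,
    frame: np.ndarray,
    config: NetworkConfig,
):
    """Iterate inference cycles on a still frame until the error settles.

    Convergence: the relative change of the total squared prediction error
    between consecutive cycles drops below ``config.convergence_tol``
    (per batch element when batched), or ``max_convergence_steps`` cycles
    have run.

    Returns
    -------
    (state, converged, n_cycles)
        ``converged`` is a bool (or bool array for a batch) flagging whether
        the tolerance was met.
    """
    clamp_input(state, frame)
    compute_errors(state, weights)
    prev = total_squared_error(state)  # baseline: error of the initial state
    n_cycles = 0
    batched = state.batch_size is not None
    converged = np.zeros(state.batch_size, dtype=bool) if batched else False
    while n_cycles < config.max_convergence_steps:
        for _ in range(config.inference_steps_per_cycle):
            inference_step(state, weights, config)
        cur = total_squared_error(state)
        rel = np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-300)
        n_cycles += 1
        prev = cur
        if batched:
            converged |= rel < config.convergence_tol
            if converged.all():
                break
        else:
            if rel < config.convergence_tol:
                converged = True
                break
    return state, converged, n_cycles


# ---------------------------------------------------------------------------
# serialization: one compressed array archive + a JSON sidecar of the config


def save_checkpoint(
    path,
    weights: WeightSet,
    config: NetworkConfig,
    state: NetworkState | None = None,
    seed: int | None = None,
) -> None:
    """Write weights (and optionally state) to ``path``.npz + ``path``.json."""
    path = Path(path)
    arrays = {f"W_{l}": m for l, m in enumerate(weights)}
    if state is not None:
        arrays.update({f"x_{l}": a for l, a in enumerate(state.x)})
        arrays.update({f"y_{l}": a for l, a in enumerate(state.y)})
        arrays.update({f"beta_{l}": a for l, a in enumerate(state.beta)})
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": config.to_dict(), "seed": seed, "has_state": state is not None}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.

    Returns (weights, config, state_or_None, seed_or_None).
    """
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = NetworkConfig.from_dict(sidecar["config"])
    with np.load(path.with_suffix(".npz")) as data:
        n_w = len([k for k in data.files if k.startswith("W_")])
        weights = WeightSet([data[f"W_{l}"] for l in range(n_w)])
        state = None
        if sidecar.get("has_state"):
            L = n_w
            state = NetworkState(
                [data[f"x_{l}"] for l in range(L + 1)],
                [data[f"y_{l}"] for l in range(L + 1)],
                [data[f"beta_{l}"] for l in range(L)],
            )
    return weights, config, state, sidecar.get("seed")
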