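"""Generative (top-down) analyses.

After training, the same weights that routed errors upward can run the
network as a generative model: the rate vector of a chosen area is
propagated down, area by area, as a cascade of top-down predictions until
an image forms in the input area.  This module scores such reconstructions
against the original inputs and measures occlusion filling-in — how much of
an occluded object the top-down prediction restores — against a purely
feedforward baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import NetworkConfig
from .core import (
    NetworkState,
    WeightSet,
    clamp_input,
    inference_step,
    reset_state,
    run_to_convergence,
)
from .stimuli import Dataset, StimulusSequence

__all__ = [
    "ReconstructionResult",
    "OcclusionResult",
    "topdown_reconstruct",
    "reconstruct_after_blanking",
    "occlusion_experiment",
    "feedforward_baseline",
    "compare_occlusion",
]


@dataclass
class ReconstructionResult:
    """Top-down reconstruction of one frame plus its pixel-level MSE."""

    source_area: int
    image: np.ndarray  # raw top-down prediction, input shape
    image_normalized: np.ndarray  # min-max scaled copy for display
    mse: float  # vs the original frame, raw pixel scale
    converged: bool


@dataclass
class OcclusionResult:
    """Per-frame filling-in scores of one network on an occluded dataset.

    ``mse_per_frame[i]`` is the mean squared error between the (normalized)
    top-down prediction and the unoccluded ground truth, restricted to the
    occluded pixels of frame i, averaged across sequences.  Frames with an
    empty occluded region score 0 by definition.
    """

    mse_per_frame: np.ndarray
    predictions: list  # per sequence: (n_frames, H, W) predicted inputs
    normalized: bool


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def topdown_reconstruct(
    weights: WeightSet,
    representation: np.ndarray,
    source_area: int,
    config: NetworkConfig | None = None,
    image_shape: tuple[int, int] | None = None,
):
    """Cascade a representation down to the input area.

    Iteratively installs ``y_l := W_l y_{l+1}`` from ``source_area - 1``
    down to area 0 and returns (raw_image, normalized_image).  By default
    the raw linear prediction is installed at every level (the cascade is
    then exactly linear in the representation); with
    ``config.reconstruct_through_sigmoid`` intermediate areas pass their
    prediction through the rate nonlinearity instead.
    """
    from scipy.special import expit

    sizes = weights.area_sizes
    if not (1 <= source_area < len(sizes)):
        raise ValueError(f"source_area must be in 1..{len(sizes) - 1}")
    y = np.asarray(representation, dtype=float)
    if y.shape[0] != sizes[source_area]:
        raise ValueError(
            f"representation length {y.shape[0]} != area size {sizes[source_area]}"
        )
    through_sigmoid = config is not None and config.reconstruct_through_sigmoid
    offset = config.activation_offset if config is not None else 0.0
    for l in range(source_area - 1, -1, -1):
        y = weights[l] @ y
        if through_sigmoid and l > 0:  # the input area is linear by construction
            y = expit(y + offset)
    img = y
    if image_shape is not None:
        img = img.reshape(image_shape)
    return img, _minmax(img)


def reconstruct_after_blanking(
    weights: WeightSet,
    frame: np.ndarray,
    config: NetworkConfig,
    source_area: int,
) -> ReconstructionResult:
    """Present a still image to convergence, blank it, reconstruct top-down.

    The converged rates of ``source_area`` are propagated back to the input
    area; the MSE compares the raw reconstruction to the original frame.
    Weights are read-only throughout.
    """
    frame = np.asarray(frame, dtype=float)
    state = reset_state(config)
    state, converged, _ = run_to_convergence(state, weights, frame, config)
    rep = state.y[source_area]
    img, img_norm = topdown_reconstruct(
        weights, rep, source_area, config=config, image_shape=frame.shape
    )
    mse = float(np.mean((img - frame) ** 2))
    return ReconstructionResult(
        source_area=source_area,
        image=img,
        image_normalized=img_norm,
        mse=mse,
        converged=bool(np.all(converged)),
    )


def occlusion_experiment(
    weights: WeightSet,
    occluded_dataset: Dataset,
    config: NetworkConfig,
    normalize: bool = False,
) -> OcclusionResult:
    """Filling-in scores on occluded sequences.

    Each occluded sequence is presented continuously (reset at the start,
    activity carried between frames, frozen weights).  After each frame's
    inference the prediction sent to the input area, ``W_0 y_1``, is
    compared to the unoccluded ground truth inside the occluded region
    only; scores are averaged across sequences per frame index.

    Scoring uses the raw prediction by default: min-max normalization
    (``normalize=True``, useful for display) rescales the whole image by
    its extremes, so a single negative background pixel shifts the empty
    occluded region away from zero and dominates the region MSE.
    """
    for seq in occluded_dataset:
        if seq.occluder_mask is None or seq.ground_truth is None:
            raise ValueError("occluded dataset must carry masks and ground truth")
    n_frames = occluded_dataset.sequences[0].n_frames
    shape = tuple(occluded_dataset.image_shape)
    steps_per_frame = config.cycles_per_frame * config.inference_steps_per_cycle
    per_frame = np.zeros((len(occluded_dataset), n_frames))
    predictions = []
    for s_idx, seq in enumerate(occluded_dataset):
        state = reset_state(config)
        preds = np.empty((n_frames,) + shape)
        for f_idx in range(n_frames):
            clamp_input(state, seq.frames[f_idx])
            for _ in range(steps_per_frame):
                inference_step(state, weights, config)
            pred = (weights[0] @ state.y[1]).reshape(shape)
            if normalize:
                pred = _minmax(pred)
            preds[f_idx] = pred
            mask = seq.occluder_mask[f_idx]
            if mask.any():
                diff = pred[mask] - seq.ground_truth[f_idx][mask]
                per_frame[s_idx, f_idx] = float(np.mean(diff**2))
            else:
                per_frame[s_idx, f_idx] = 0.0
        predictions.append(preds)
    return OcclusionResult(
        mse_per_frame=per_frame.mean(axis=0),
        predictions=predictions,
        normalized=normalize,
    )


def feedforward_baseline(occluded_dataset: Dataset) -> np.ndarray:
    """Occluded-region MSE of a network with no generative pathway.

    A purely feedforward model cannot restore occluded pixels; its
    "reconstruction" is the occluded input itself (zero inside the
    occluder), so the per-frame MSE is the mean squared ground-truth
    intensity inside the occluded region, averaged across sequences.
    """
    n_frames = occluded_dataset.sequences[0].n_frames
    per_frame = np.zeros((len(occluded_dataset), n_frames))
    for s_idx, seq in enumerate(occluded_dataset):
        if seq.occluder_mask is None or seq.ground_truth is None:
            raise ValueError("occluded dataset must carry masks and ground truth")
        for f_idx in range(n_frames):
            mask = seq.occluder_mask[f_idx]
            if mask.any():
                gt = seq.ground_truth[f_idx][mask]
                per_frame[s_idx, f_idx] = float(np.mean(gt**2))
    return per_frame.mean(axis=0)


def compare_occlusion(pc_results, baselines: dict) -> dict:
    """Per-frame unequal-variance t-tests of the filling-in scores.

    ``pc_results``: list (across seeds) of per-frame MSE arrays of the
    predictive-coding network; ``baselines``: mapping name -> list of
    per-frame MSE arrays.  Returns, per baseline, per-frame means, mean
    differences and Welch t-test p-values.
    """
    pc = np.asarray(pc_results, dtype=float)
    if pc.ndim != 2 or pc.shape[0] < 2:
        raise ValueError("need per-frame MSE arrays from at least two seeds")
    report = {"pc_mean": pc.mean(axis=0), "frames": np.arange(pc.shape[1])}
    for name, vals in baselines.items():
        b = np.asarray(vals, dtype=float)
        if b.ndim != 2 or b.shape[0] < 2:
            raise ValueError(f"baseline {name!r} needs at least two seeds")
        t, p = stats.ttest_ind(pc, b, axis=0, equal_var=False)
        report[name] = {
            "baseline_mean": b.mean(axis=0),
            "difference": pc.mean(axis=0) - b.mean(axis=0),
            "t": t,
            "p": p,
        }
    return report
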