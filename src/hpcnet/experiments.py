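"""The standard synthetic fixture and the end-to-end experiments run on it.

The fixture is the package's self-contained stand-in for the digit
experiments: 10 glyph classes on a 28x28 canvas, 6-frame transformation
sequences, four independently initialized networks.  The network is a
scaled-down sibling of the full model (hidden areas 160/60/30 instead of
2000/500/30, 100 inference steps per frame during training) so that every
experiment runs in minutes on one CPU core; the qualitative effects under
study — invariance from temporal continuity, the timescale hierarchy, the
generative ordering and occlusion filling-in — are ordinal and survive the
scaling.  The dynamics probe presents frames at the same dwell time used in
training, so the measured timescales reflect dynamics the paradigm shaped.
"""

from __future__ import annotations

import numpy as np

from .config import NetworkConfig
from .core import init_weights
from .dynamics import timescale_experiment, timescale_stats
from .generative import feedforward_baseline, occlusion_experiment
from .representation import (
    block_structure_score,
    compute_rdm,
    decode_linear,
    infer_representations,
    kmeans_baseline,
    sfa_baseline,
)
from .stimuli import Dataset, make_dataset, make_occlusion_dataset
from .training import train_continuous, train_static

__all__ = [
    "FIXTURE_AREA_SIZES",
    "FULL_AREA_SIZES",
    "fixture_config",
    "analysis_config",
    "derive_seeds",
    "fixture_dataset",
    "untrained_collapse_experiment",
    "train_fixture_networks",
    "invariance_experiment",
    "decoding_experiment",
    "timescale_fixture_experiment",
    "reconstruction_experiment",
    "occlusion_fixture_experiment",
]

#: Hidden-area sizes of the scaled-down fixture network.
FIXTURE_AREA_SIZES = (784, 160, 60, 30)
#: The full-size architecture (input, area 1..3).
FULL_AREA_SIZES = (784, 2000, 500, 30)
#: Fixture problem size.
N_CLASSES = 10
N_FRAMES = 6
N_SEEDS = 4
#: Training epochs on the fixture.
EPOCHS = 6
#: Inference-learning cycles per frame during fixture training (x10 steps).
TRAIN_CYCLES_PER_FRAME = 10


def fixture_config(**overrides) -> NetworkConfig:
    """Training configuration of the standard fixture."""
    kw = dict(
        area_sizes=FIXTURE_AREA_SIZES,
        cycles_per_frame=TRAIN_CYCLES_PER_FRAME,
    )
    kw.update(overrides)
    return NetworkConfig(**kw)


def analysis_config(config: NetworkConfig) -> NetworkConfig:
    """Frozen-weight probe configuration.

    The dynamics probe keeps the per-frame dwell time the network was
    trained with: a network trained at N inference steps per frame never
    visited the frame-specific attractors it settles into when given much
    longer, so probing at a strongly mismatched dwell time measures
    dynamics the training paradigm did not shape.
    """
    return config


def derive_seeds(base_seed: int, n: int = N_SEEDS) -> list[int]:
    """n reproducible sub-seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(int(base_seed))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def fixture_dataset(
    transform: str = "translate",
    seed: int = 0,
    noise: bool = False,
    speed: float = 1,
) -> Dataset:
    return make_dataset(
        N_CLASSES, transform, speed=speed, noise=noise, shape=(28, 28), seed=seed
    )


#: Process-level cache of trained fixture networks, so the experiments that
#: share a training condition (invariance, decoding, reconstruction) do not
#: retrain.  Keyed by every input that determines the result.
_TRAIN_CACHE: dict = {}


def get_trained_network(
    seed: int,
    paradigm: str = "continuous",
    transform: str = "translate",
    epochs: int = None,
    data_seed: int = 0,
    config: NetworkConfig | None = None,
    dataset: Dataset | None = None,
):
    """Train (or fetch the cached) fixture network for one condition."""
    epochs = EPOCHS if epochs is None else epochs
    config = fixture_config() if config is None else config
    key = (int(seed), paradigm, transform, int(epochs), int(data_seed), config.to_json())
    if key not in _TRAIN_CACHE:
        if dataset is None:
            dataset = fixture_dataset(transform, seed=data_seed)
        trainer = train_continuous if paradigm == "continuous" else train_static
        _TRAIN_CACHE[key] = trainer(dataset, config, epochs=epochs, seed=seed)
    return _TRAIN_CACHE[key]


# ---------------------------------------------------------------------------


def untrained_collapse_experiment(
    seeds, area_sizes=FULL_AREA_SIZES, data_seed: int = 0
) -> dict:
    """Maximum pairwise cosine dissimilarity of untrained top-area codes.

    For each seed, initialize weights at full architecture, run every still
    frame of the 10-sequence translation dataset to convergence and measure
    the largest pairwise cosine dissimilarity among the 60 top-area rate
    vectors.  An untrained network collapses all frames onto nearly the
    same direction.
    """
    config = NetworkConfig(area_sizes=area_sizes)
    dataset = fixture_dataset("translate", seed=data_seed)
    top = len(area_sizes) - 1
    per_seed = []
    for seed in seeds:
        weights = init_weights(config, seed=seed)
        reps = infer_representations(weights, dataset, config, area=top)
        rdm = compute_rdm(reps)
        per_seed.append(float(rdm.matrix.max()))
    return {"max_dissimilarity": max(per_seed), "per_seed": per_seed}


def train_fixture_networks(
    seeds,
    paradigm: str = "continuous",
    transform: str = "translate",
    epochs: int = EPOCHS,
    data_seed: int = 0,
    config: NetworkConfig | None = None,
) -> dict:
    """Train one fixture network per seed; returns seed -> (weights, history)."""
    return {
        seed: get_trained_network(
            seed, paradigm, transform, epochs=epochs, data_seed=data_seed, config=config
        )
        for seed in seeds
    }


def invariance_experiment(
    seeds, transform: str = "translate", epochs: int = EPOCHS, data_seed: int = 0
) -> dict:
    """Within- vs across-sequence RDM structure for the three training regimes.

    Returns per-seed (within, across) means at the top area for the
    continuously trained, statically trained and untrained network, plus
    the invariance gap (across - within) of each.
    """
    config = fixture_config()
    dataset = fixture_dataset(transform, seed=data_seed)
    top = len(config.area_sizes) - 1
    results: dict = {"continuous": [], "static": [], "untrained": []}
    for seed in seeds:
        for regime in results:
            if regime == "untrained":
                weights = init_weights(config, seed=seed)
            else:
                weights, _ = get_trained_network(
                    seed, regime, transform, epochs=epochs, data_seed=data_seed
                )
            reps = infer_representations(weights, dataset, config, area=top)
            within, across = block_structure_score(compute_rdm(reps))
            results[regime].append(
                {"within": within, "across": across, "gap": across - within}
            )
    return results


def decoding_experiment(
    seeds,
    transform: str = "translate",
    epochs: int = EPOCHS,
    data_seed: int = 0,
    k: int = 3,
) -> dict:
    """Top-area decoding of the two paradigms against the input baselines.

    Per seed: linear decoding accuracy on top-area representations of the
    continuously and statically trained networks; plus k-means, direct
    linear decoding and linear SFA on the raw input frames (fold seeds
    matched to the network seeds), and the chance level.
    """
    config = fixture_config()
    dataset = fixture_dataset(transform, seed=data_seed)
    top = len(config.area_sizes) - 1
    X_in = dataset.frames_matrix()
    y = dataset.frame_labels()
    out: dict = {
        "pc_continuous": [],
        "pc_static": [],
        "kmeans": [],
        "input_ld": [],
        "sfa": [],
        "chance": 1.0 / dataset.n_classes,
    }
    for seed in seeds:
        for paradigm, key in (("continuous", "pc_continuous"), ("static", "pc_static")):
            weights, _ = get_trained_network(
                seed, paradigm, transform, epochs=epochs, data_seed=data_seed
            )
            reps = infer_representations(weights, dataset, config, area=top)
            out[key].append(decode_linear(reps, k=k, seed=seed).mean)
        out["kmeans"].append(
            kmeans_baseline(X_in, y, dataset.n_classes, seed=seed, k=k).mean
        )
        out["input_ld"].append(
            decode_linear(X_in, y, k=k, seed=seed, method="input_ld").mean
        )
        out["sfa"].append(sfa_baseline(dataset, seed=seed, k=k).mean)
    return out


def timescale_fixture_experiment(
    seeds,
    transform: str = "rotate",
    epochs: int = EPOCHS,
    data_seed: int = 0,
    speeds=(1, 2, 4),
) -> dict:
    """Decay-constant table for trained fixture networks across speeds."""
    config = fixture_config()
    dataset = fixture_dataset(transform, seed=data_seed)
    trained = {
        seed: get_trained_network(
            seed, "continuous", transform, epochs=epochs, data_seed=data_seed
        )[0]
        for seed in seeds
    }
    probe = analysis_config(config)
    taus = timescale_experiment(trained, dataset, probe, speeds=speeds)
    try:
        stats = timescale_stats(taus[taus["speed"] == 1])
    except ValueError:
        stats = None
    return {"taus": taus, "stats": stats}


def reconstruction_experiment(
    seeds,
    transform: str = "translate",
    epochs: int = EPOCHS,
    data_seed: int = 0,
) -> dict:
    """Mean top-down reconstruction MSE per source area on trained networks.

    Averages the raw-pixel MSE of blank-and-reconstruct over every frame of
    the dataset, per source area and seed.
    """
    from .core import reset_state, run_to_convergence
    from .generative import topdown_reconstruct

    config = fixture_config()
    dataset = fixture_dataset(transform, seed=data_seed)
    areas = list(range(1, len(config.area_sizes)))
    frames = dataset.frames_matrix()  # (R, n_pixels)
    per_seed = {a: [] for a in areas}
    for seed in seeds:
        weights, _ = get_trained_network(
            seed, "continuous", transform, epochs=epochs, data_seed=data_seed
        )
        # one batched convergence run per seed; reconstruct from every area
        # of the same converged state (equivalent to blanking per frame)
        state = reset_state(config, batch_size=frames.shape[0])
        state, _, _ = run_to_convergence(state, weights, frames, config)
        for a in areas:
            recon = state.y[a]  # (n_units, R)
            for l in range(a - 1, -1, -1):
                recon = weights[l] @ recon
            mse = np.mean((recon.T - frames) ** 2)
            per_seed[a].append(float(mse))
    return {
        "mse_by_area": {a: float(np.mean(v)) for a, v in per_seed.items()},
        "per_seed": per_seed,
    }


def occlusion_fixture_experiment(
    seeds,
    epochs: int = EPOCHS,
    data_seed: int = 0,
) -> dict:
    """Occlusion filling-in of trained networks vs the feedforward baseline.

    Networks are trained on unoccluded versions of the translation
    sequences, then tested on the same objects sliding behind a static
    occluder.  Returns per-seed per-frame occluded-region MSE and the
    (deterministic) feedforward baseline.
    """
    config = fixture_config()
    occluded = make_occlusion_dataset(N_CLASSES, shape=(28, 28), seed=data_seed)
    # train on the unoccluded ground-truth sequences
    from dataclasses import replace

    train_seqs = [
        replace(s, frames=s.ground_truth, occluder_mask=None, ground_truth=None)
        for s in occluded
    ]
    train_set = Dataset(
        sequences=train_seqs,
        n_classes=occluded.n_classes,
        image_shape=occluded.image_shape,
    )
    pc_mse = []
    for seed in seeds:
        weights, _ = get_trained_network(
            seed,
            "continuous",
            "occlusion-translate",
            epochs=epochs,
            data_seed=data_seed,
            dataset=train_set,
        )
        res = occlusion_experiment(weights, occluded, config)
        pc_mse.append(res.mse_per_frame)
    return {
        "pc_mse_per_frame": np.asarray(pc_mse),
        "feedforward_mse_per_frame": feedforward_baseline(occluded),
    }
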