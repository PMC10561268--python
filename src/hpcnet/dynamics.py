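"""Temporal-stability analysis of network activity.

Records subpopulation activity while a frozen network watches a sequence,
computes the un-centred activity autocorrelation over time lags, and
extracts a decay constant tau — the lag at which the autocorrelation falls
to 1/e of its zero-lag value (with a linear extrapolation through the
endpoints when the curve never crosses within the sequence).  Tau is the
population's intrinsic timescale; comparing representation-neuron (RN) and
error-neuron (EN) populations across areas and stimulus speeds probes the
hierarchy of timescales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

from .config import NetworkConfig
from .core import (
    NetworkState,
    WeightSet,
    clamp_input,
    inference_step,
    reset_state,
)
from .stimuli import Dataset, StimulusSequence
from .training import set_speed

__all__ = [
    "ActivityTrace",
    "AutocorrelationResult",
    "record_activity",
    "record_all_activity",
    "autocorrelation",
    "autocorrelation_curve",
    "decay_constant",
    "timescale_experiment",
    "timescale_stats",
]

#: Default block size for averaging activity before autocorrelation,
#: in inference steps.
BLOCK_SIZE = 10


@dataclass
class ActivityTrace:
    """Block-averaged activity of one subpopulation over a sequence.

    ``z`` has shape (T / block_size, n_neurons); each row is the activity
    averaged across ``block_size`` consecutive inference steps.  ``T`` is
    the total number of inference steps in the presentation.
    """

    z: np.ndarray
    population: str  # "RN" or "EN"
    area: int
    T: int  # total inference steps
    block_size: int = BLOCK_SIZE

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("trace must be (time, neurons)")
        if not np.isfinite(self.z).all():
            raise ValueError("trace contains non-finite entries")

    @property
    def n_blocks(self) -> int:
        return self.z.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.z.shape[1]


@dataclass
class AutocorrelationResult:
    """R over the lag grid plus the extracted decay constant."""

    lags: np.ndarray  # in inference steps
    R: np.ndarray
    tau: float  # in inference steps
    censored: bool


def record_all_activity(
    weights: WeightSet, sequence: StimulusSequence, config: NetworkConfig
) -> dict:
    """Run a sequence once (frozen weights) and record every subpopulation.

    Continuous presentation: activity is reset once at the start, each frame
    is shown for ``cycles_per_frame * inference_steps_per_cycle`` steps, and
    activity carries over between frames.  Returns a dict keyed by
    ("RN", area 1..L) and ("EN", area 0..L-1) of :class:`ActivityTrace`.
    """
    steps_per_frame = config.cycles_per_frame * config.inference_steps_per_cycle
    T = sequence.n_frames * steps_per_frame
    L = len(config.area_sizes) - 1
    rn = {l: np.empty((T, config.area_sizes[l])) for l in range(1, L + 1)}
    en = {l: np.empty((T, config.area_sizes[l])) for l in range(L)}
    state = reset_state(config)
    t = 0
    for frame in sequence.frames:
        clamp_input(state, frame)
        for _ in range(steps_per_frame):
            inference_step(state, weights, config)
            for l in range(1, L + 1):
                rn[l][t] = state.y[l]
            for l in range(L):
                en[l][t] = state.beta[l]
            t += 1
    out = {}
    nb = T // BLOCK_SIZE
    for l in range(1, L + 1):
        z = rn[l][: nb * BLOCK_SIZE].reshape(nb, BLOCK_SIZE, -1).mean(axis=1)
        out[("RN", l)] = ActivityTrace(z=z, population="RN", area=l, T=T)
    for l in range(L):
        z = en[l][: nb * BLOCK_SIZE].reshape(nb, BLOCK_SIZE, -1).mean(axis=1)
        out[("EN", l)] = ActivityTrace(z=z, population="EN", area=l, T=T)
    return out


def record_activity(
    weights: WeightSet,
    sequence: StimulusSequence,
    config: NetworkConfig,
    population: str = "RN",
    area: int = 1,
) -> ActivityTrace:
    """Activity trace of one subpopulation during one sequence presentation."""
    L = len(config.area_sizes) - 1
    if population == "RN":
        if not (1 <= area <= L):
            raise ValueError(f"RN area must be in 1..{L}")
    elif population == "EN":
        if not (0 <= area <= L - 1):
            raise ValueError(f"EN area must be in 0..{L - 1} (top area has no errors)")
    else:
        raise ValueError("population must be 'RN' or 'EN'")
    return record_all_activity(weights, sequence, config)[(population, area)]


def autocorrelation(trace: ActivityTrace, lag: int) -> float:
    """Un-centred autocorrelation at one lag (in inference steps).

    ``R = 1/(N (T' - k)) sum_t z(t).z(t+k)`` where k is the lag on the
    block-averaged grid and T' the number of grid points.  No mean is
    subtracted, so persistently active populations keep high R.
    """
    k, rem = divmod(int(lag), trace.block_size)
    if rem:
        raise ValueError(f"lag must be a multiple of the block size {trace.block_size}")
    Tb = trace.n_blocks
    if not (0 <= k < Tb):
        raise ValueError("lag must be smaller than the trace duration")
    z = trace.z
    if k == 0:
        s = float(np.sum(z * z))
    else:
        s = float(np.sum(z[:-k] * z[k:]))
    return s / (trace.n_neurons * (Tb - k))


def autocorrelation_curve(trace: ActivityTrace) -> tuple[np.ndarray, np.ndarray]:
    """R over all lags 0, block, 2*block, ... (in inference steps)."""
    Tb = trace.n_blocks
    z = trace.z
    N = trace.n_neurons
    R = np.empty(Tb)
    R[0] = np.sum(z * z) / (N * Tb)
    for k in range(1, Tb):
        R[k] = np.sum(z[:-k] * z[k:]) / (N * (Tb - k))
    lags = np.arange(Tb) * trace.block_size
    return lags, R


def decay_constant(
    R: np.ndarray,
    lags: np.ndarray,
    T: float | None = None,
    censored_cap_factor: float = 10.0,
) -> tuple[float, bool]:
    """Lag at which R decays to 1/e of R(0).

    Linear interpolation between lag samples at the first crossing.  If the
    curve never reaches R(0)/e, a line through (0, R(0)) and (T, R(T)) is
    extended until it does; if even that line does not decay (slope >= 0),
    tau is censored at ``censored_cap_factor * T``.
    """
    R = np.asarray(R, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if R[0] <= 0:
        raise ValueError("R(0) must be positive")
    T = float(lags[-1]) if T is None else float(T)
    target = R[0] / np.e
    below = np.where(R <= target)[0]
    if below.size:
        i = below[0]
        if i == 0:
            return 0.0, False
        # linear interpolation between the bracketing samples
        x0, x1 = lags[i - 1], lags[i]
        y0, y1 = R[i - 1], R[i]
        tau = x0 if y0 == y1 else x0 + (y0 - target) * (x1 - x0) / (y0 - y1)
        return float(tau), False
    slope = (R[-1] - R[0]) / T
    if slope >= 0:
        return censored_cap_factor * T, True
    return float((target - R[0]) / slope), False


def timescale_experiment(
    weights,
    dataset: Dataset,
    config: NetworkConfig,
    speeds=(1, 2, 4),
) -> pd.DataFrame:
    """Decay constants per (population, area, speed, seed).

    ``weights`` is either one :class:`WeightSet` or a mapping seed ->
    WeightSet (independently initialized networks).  For each speed the
    per-frame inference steps are divided by the speed; R curves are
    averaged across the dataset's sequences before tau extraction.
    """
    if isinstance(weights, WeightSet):
        weights = {0: weights}
    L = len(config.area_sizes) - 1
    rows = []
    for seed, W in weights.items():
        for speed in speeds:
            cfg = set_speed(config, speed)
            curves: dict = {}
            for seq in dataset:
                traces = record_all_activity(W, seq, cfg)
                for key, tr in traces.items():
                    lags, R = autocorrelation_curve(tr)
                    curves.setdefault(key, []).append((lags, R))
            for (pop, area), entries in curves.items():
                lags = entries[0][0]
                R_mean = np.mean([R for _, R in entries], axis=0)
                T = seq.n_frames * cfg.cycles_per_frame * cfg.inference_steps_per_cycle
                tau, censored = decay_constant(R_mean, lags, T=T)
                rows.append(
                    {
                        "population": pop,
                        "area": area,
                        "speed": speed,
                        "seed": seed,
                        "tau": tau,
                        "censored": censored,
                    }
                )
    return pd.DataFrame(rows)


def timescale_stats(taus: pd.DataFrame, include_censored: bool = False) -> dict:
    """Welch's ANOVA across the (population, area) groups + Games-Howell post hoc.

    Expects the table produced by :func:`timescale_experiment`; censored
    taus are excluded by default.  Returns {'anova': DataFrame, 'posthoc':
    DataFrame} with one pairwise row per group pair.
    """
    df = taus if include_censored else taus[~taus["censored"]]
    df = df.copy()
    df["group"] = df["population"] + df["area"].astype(str)
    counts = df.groupby("group")["tau"].count()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton group(s): {bad}")
    anova = pg.welch_anova(data=df, dv="tau", between="group")
    posthoc = pg.pairwise_gameshowell(data=df, dv="tau", between="group")
    return {"anova": anova, "posthoc": posthoc}
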