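"""End-to-end driver for the standard-fixture experiment battery.

Runs every fixture experiment (untrained collapse, invariance, decoding,
timescales, reconstruction, occlusion) for a set of derived seeds and
summarizes the ordinal properties the model is expected to show: lower
within- than across-sequence dissimilarity after continuous training, a
decoding advantage over the baselines, the timescale hierarchy, the
area-wise reconstruction ordering and the occlusion filling-in advantage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

from . import experiments

STAGES = (
    "untrained_collapse",
    "invariance",
    "decoding",
    "timescales",
    "reconstruction",
    "occlusion",
)

__all__ = ["STAGES", "run_all", "summarize"]


def summarize(results: dict) -> dict:
    """Ordinal pass/fail summary of the fixture battery."""
    summary: dict = {}

    col = results["untrained_collapse"]
    summary["untrained_max_dissimilarity"] = col["max_dissimilarity"]
    summary["untrained_collapse_below_1e3"] = bool(col["max_dissimilarity"] < 1e-3)

    inv = results["invariance"]
    gaps = {r: np.mean([d["gap"] for d in inv[r]]) for r in inv}
    within_lt_across = all(d["within"] < d["across"] for d in inv["continuous"])
    summary["invariance"] = {
        "gap_continuous": float(gaps["continuous"]),
        "gap_static": float(gaps["static"]),
        "gap_untrained": float(gaps["untrained"]),
        "within_lt_across_continuous": bool(within_lt_across),
        "gap_exceeds_untrained": bool(gaps["continuous"] > gaps["untrained"]),
        "gap_exceeds_static": bool(gaps["continuous"] > gaps["static"]),
    }

    dec = results["decoding"]
    n_seeds = len(dec["pc_continuous"])
    wins = 0
    for i in range(n_seeds):
        beats = (
            dec["pc_continuous"][i] > dec["pc_static"][i]
            and dec["pc_continuous"][i] > dec["kmeans"][i]
            and dec["pc_continuous"][i] > dec["input_ld"][i]
            and dec["pc_continuous"][i] > dec["chance"]
        )
        wins += int(beats)
    summary["decoding"] = {
        "mean_accuracy": {
            k: float(np.mean(v)) for k, v in dec.items() if k != "chance"
        },
        "chance": dec["chance"],
        "seeds_beating_all_baselines": wins,
        "n_seeds": n_seeds,
        "ordinal_pass": bool(wins >= min(3, n_seeds)),
    }

    taus = results["timescales"]["taus"]
    sp1 = taus[taus["speed"] == 1]
    per_seed_rn = []
    per_seed_en = []
    for seed, grp in sp1.groupby("seed"):
        t = {
            (p, a): float(v)
            for p, a, v in zip(grp["population"], grp["area"], grp["tau"])
        }
        per_seed_rn.append(t[("RN", 3)] > t[("RN", 2)] > t[("RN", 1)])
        per_seed_en.append(t[("EN", 2)] < t[("RN", 2)])
    ok = taus[~taus["censored"]]
    rho = sps.spearmanr(1.0 / ok["speed"], ok["tau"]).statistic
    summary["timescales"] = {
        "rn_hierarchy_seeds": int(np.sum(per_seed_rn)),
        "en_faster_than_rn_area2_seeds": int(np.sum(per_seed_en)),
        "n_seeds": len(per_seed_rn),
        "spearman_tau_vs_stimulus_timescale": float(rho),
        "mean_tau_speed1": {
            f"{p}{a}": float(g["tau"].mean())
            for (p, a), g in sp1.groupby(["population", "area"])
        },
    }

    rec = results["reconstruction"]["mse_by_area"]
    areas = sorted(rec)
    summary["reconstruction"] = {
        "mse_by_area": {str(a): rec[a] for a in areas},
        "ordering_pass": bool(
            all(rec[a] < rec[b] for a, b in zip(areas[:-1], areas[1:]))
        ),
    }

    occ = results["occlusion"]
    pc = occ["pc_mse_per_frame"].mean(axis=0)
    ff = occ["feedforward_mse_per_frame"]
    summary["occlusion"] = {
        "pc_mse_per_frame": pc.tolist(),
        "feedforward_mse_per_frame": ff.tolist(),
        "pc_below_feedforward_after_first": bool(np.all(pc[1:] < ff[1:])),
        "mse_non_decreasing": bool(np.all(np.diff(pc) >= -1e-12)),
    }
    return summary


def run_all(
    seed: int = 0,
    n_seeds: int = 4,
    epochs: int | None = None,
    out_dir: Path | None = None,
) -> tuple[dict, dict]:
    """Run all fixture stages; optionally write tables under ``out_dir``."""
    epochs = experiments.EPOCHS if epochs is None else epochs
    seeds = experiments.derive_seeds(seed, n_seeds)
    results = {
        "untrained_collapse": experiments.untrained_collapse_experiment(seeds),
        "invariance": experiments.invariance_experiment(seeds, epochs=epochs),
        "decoding": experiments.decoding_experiment(seeds, epochs=epochs),
        "timescales": experiments.timescale_fixture_experiment(seeds, epochs=epochs),
        "reconstruction": experiments.reconstruction_experiment(seeds, epochs=epochs),
        "occlusion": experiments.occlusion_fixture_experiment(seeds, epochs=epochs),
    }
    summary = summarize(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results["timescales"]["taus"].to_csv(out_dir / "taus.csv", index=False)
        stats = results["timescales"]["stats"]
        if stats is not None:
            stats["anova"].to_csv(out_dir / "welch_anova.csv", index=False)
            stats["posthoc"].to_csv(out_dir / "games_howell.csv", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=str)
        )
    return results, summary
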