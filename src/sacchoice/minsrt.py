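"""Minimum reliably-accurate SRT estimation.

Accepted trials are grouped into 10 ms latency bins, left-inclusive: the
bin centered at 120 ms covers saccades starting 115-124 ms after
stimulus onset. In each bin, a Monte Carlo chi-square test (2000
replications by default) asks whether correct saccades outnumber
incorrect ones beyond chance; the minimum SRT of a task is the center of
the first bin of the first run of at least five consecutive bins where
correct significantly exceeds incorrect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH = 10.0
ALPHA = 0.05
N_REPLICATIONS = 2000
RUN_LENGTH = 5


def bin_srt(srt) -> np.ndarray | float:
    """Map an SRT (ms) to its 10 ms bin center, left-inclusive.

    ``center - 5 <= srt < center + 5``; e.g. 115-124 ms all map to 120.
    """
    srt_arr = np.asarray(srt, dtype=float)
    if np.any(srt_arr < 0):
        raise ValueError("SRT must be non-negative")
    center = (np.floor((srt_arr + 5.0) / BIN_WIDTH) * BIN_WIDTH).astype(float)
    return float(center) if np.isscalar(srt) else center


def mc_chisq_bin(
    n_correct: int,
    n_incorrect: int,
    n_replications: int = N_REPLICATIONS,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte Carlo chi-square p-value against a 50/50 split.

    The statistic is the goodness-of-fit chi-square of the observed
    (correct, incorrect) counts against equal expected counts; the null
    distribution is simulated by drawing ``n_replications`` binomial
    splits of the same total, and the p-value uses the add-one
    estimator ``(1 + #{simulated >= observed}) / (n_replications + 1)``
    so it is never exactly zero.
    """
    if n_correct < 0 or n_incorrect < 0:
        raise ValueError("counts must be non-negative")
    n = n_correct + n_incorrect
    if n == 0:
        warnings.warn("empty bin: chi-square undefined, returning p=1")
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = n / 2.0
    observed_stat = (n_correct - expected) ** 2 / expected + (
        n_incorrect - expected
    ) ** 2 / expected
    sim_correct = rng.binomial(n, 0.5, size=n_replications)
    sim_stat = (sim_correct - expected) ** 2 / expected + (
        (n - sim_correct) - expected
    ) ** 2 / expected
    return float((1 + np.sum(sim_stat >= observed_stat - 1e-12)) / (n_replications + 1))


@dataclass(frozen=True)
class BinTest:
    """One latency bin's counts and test outcome."""

    bin_center: float
    n_correct: int
    n_incorrect: int
    p_value: float
    significant: bool  # p < alpha AND correct > incorrect


@dataclass
class MinSRTResult:
    """Minimum-SRT estimate for one task."""

    task: str
    min_srt: float | None
    bins: list[BinTest]
    alpha: float = ALPHA
    n_replications: int = N_REPLICATIONS
    run_length: int = RUN_LENGTH

    def bins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": [b.bin_center for b in self.bins],
                "n_correct": [b.n_correct for b in self.bins],
                "n_incorrect": [b.n_incorrect for b in self.bins],
                "p_value": [b.p_value for b in self.bins],
                "significant": [b.significant for b in self.bins],
            }
        )


def minimum_srt(
    results: pd.DataFrame,
    task: str = "",
    alpha: float = ALPHA,
    run_length: int = RUN_LENGTH,
    n_replications: int = N_REPLICATIONS,
    seed: int = 0,
    min_bin: float = 80.0,
) -> MinSRTResult:
    """Estimate the minimum reliably-accurate SRT for one task.

    ``results`` holds accepted trials with ``srt`` (ms) and boolean
    ``correct`` columns. Bins are scanned in ascending order from the
    bin containing ``min_bin`` to the last bin with data; empty bins are
    non-significant and break runs. ``min_srt`` is the center of the
    first bin of the first run of ``run_length`` or more consecutive
    bins with ``p < alpha`` and more correct than incorrect trials;
    ``None`` if no such run exists.
    """
    if len(results) == 0:
        raise ValueError("no accepted trials")
    srt = np.asarray(results["srt"], dtype=float)
    correct = np.asarray(results["correct"], dtype=bool)
    centers_all = bin_srt(srt)
    first = bin_srt(min_bin)
    last = centers_all.max()
    rng = np.random.default_rng(seed)
    bins: list[BinTest] = []
    for center in np.arange(first, last + BIN_WIDTH / 2, BIN_WIDTH):
        in_bin = centers_all == center
        nc = int(np.sum(correct[in_bin]))
        ni = int(np.sum(~correct[in_bin]))
        if nc + ni == 0:
            bins.append(BinTest(center, 0, 0, 1.0, False))
            continue
        p = mc_chisq_bin(nc, ni, n_replications=n_replications, seed=rng)
        bins.append(BinTest(center, nc, ni, p, bool(p < alpha and nc > ni)))

    min_srt_value: float | None = None
    run = 0
    for i, b in enumerate(bins):
        run = run + 1 if b.significant else 0
        if run == run_length:
            min_srt_value = bins[i - run_length + 1].bin_center
            break
    return MinSRTResult(
        task=task,
        min_srt=min_srt_value,
        bins=bins,
        alpha=alpha,
        n_replications=n_replications,
        run_length=run_length,
    )


def minimum_srt_by_task(
    results: pd.DataFrame, accepted_only: bool = True, **kwargs
) -> dict[str, MinSRTResult]:
    """Run :func:`minimum_srt` separately for every task in a results table."""
    if accepted_only and "status" in results.columns:
        results = results[results["status"] == "accepted"]
    return {
        task: minimum_srt(group, task=task, **kwargs)
        for task, group in results.groupby("task", sort=True)
    }


def summarize_conditions(
    results: pd.DataFrame,
    chance_tasks: set[str] | None = None,
    correct_only_srt: bool = True,
) -> pd.DataFrame:
    """Accuracy (%) and mean SRT (ms) per task x target position.

    One row per task for each of left, right and overall target
    positions. Mean SRT is computed over correct trials only (the
    convention used for the latency analyses; configurable) and is
    suppressed (NaN) for tasks in ``chance_tasks`` — tasks whose
    accuracy the inference module found indistinguishable from chance.
    """
    chance_tasks = chance_tasks or set()
    if "status" in results.columns:
        results = results[results["status"] == "accepted"]
    rows = []
    for task, group in results.groupby("task", sort=True):
        for position in ("overall", "left", "right"):
            sub = group if position == "overall" else group[
                group["target_hemifield"] == position
            ]
            if len(sub) == 0:
                rows.append({"task": task, "target_position": position,
                             "n": 0, "accuracy": np.nan, "mean_srt": np.nan})
                continue
            acc = 100.0 * np.mean(sub["correct"].astype(bool))
            if task in chance_tasks:
                srt_mean = np.nan
            else:
                pool = sub[sub["correct"].astype(bool)] if correct_only_srt else sub
                srt_mean = float(np.mean(pool["srt"])) if len(pool) else np.nan
            rows.append(
                {
                    "task": task,
                    "target_position": position,
                    "n": len(sub),
                    "accuracy": float(acc),
                    "mean_srt": srt_mean,
                }
            )
    return pd.DataFrame(rows)
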