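"""Simulated listener for the texture-discrimination and rating tasks.

The discrimination task is a three-interval "oddest man out": two intervals
share the statistics of one stimulus class and one interval (always the
second or third) is the odd one; chance is therefore 50%.  The simulated
observer extracts a single decision statistic from the auditory model for
each interval, perturbs it with Gaussian internal noise, and picks whichever
allowed interval lies farthest from the other two.  Dissimilarity ratings
map the absolute difference of two decision variables through a bounded
logistic onto [0, 1].

Fresh exemplars are synthesized for every interval, as in the experiments:
two intervals share parameters, never waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .auditory import FilterbankConfig, analyze_token, modulation_centroid, summary_stats
from .synth import TextureParams, TextureToken, synthesize

__all__ = [
    "ORDERINGS",
    "TrialRecord",
    "ObserverConfig",
    "make_trial_sequence",
    "decision_variable",
    "simulate_trial",
    "simulate_dissimilarity",
    "trials_to_frame",
]

#: the four sequential orderings of test (T) and standard (S) stimuli; the
#: odd stimulus is the minority letter and is never the first interval.
ORDERINGS = ("TTS", "TST", "STS", "SST")


def odd_interval(ordering: str) -> int:
    """1-based position of the minority letter (always 2 or 3)."""
    if ordering not in ORDERINGS:
        raise ValueError(f"unknown ordering {ordering!r}")
    minority = "S" if ordering.count("T") == 2 else "T"
    return ordering.index(minority) + 1


@dataclass
class TrialRecord:
    ordering: str
    standard_params: TextureParams
    test_params: TextureParams
    token_seeds: tuple[int, int, int]
    level: float | None = None
    response_interval: int | None = None
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.ordering not in ORDERINGS:
            raise ValueError(f"unknown ordering {self.ordering!r}")

    @property
    def odd_interval(self) -> int:
        return odd_interval(self.ordering)

    def interval_params(self) -> list[TextureParams]:
        return [
            (self.test_params if letter == "T" else self.standard_params).with_(seed=seed)
            for letter, seed in zip(self.ordering, self.token_seeds)
        ]


@dataclass(frozen=True)
class ObserverConfig:
    """Decision statistic, internal noise and rating-scale mapping."""

    decision_statistic: str = "across_smd"
    internal_noise_sd: float = 0.02
    rating_gain: float = 1.5
    rating_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.internal_noise_sd < 0:
            raise ValueError("internal noise sd must be >= 0")
        valid = {"within_smd", "across_smd", "across_corr", "mod_centroid"}
        if self.decision_statistic not in valid:
            raise ValueError(f"decision_statistic must be one of {sorted(valid)}")


def make_trial_sequence(
    signal_levels: list[float],
    rng: np.random.Generator,
    standard_params: TextureParams,
    make_test_params,
    n_blocks: int = 4,
    trials_per_block: int = 48,
) -> list[TrialRecord]:
    """Balanced randomized trial list for one simulated session.

    Each block contains every (signal level, ordering) combination equally
    often; the order within a block is a random permutation (drawing without
    replacement).  ``make_test_params(level)`` maps a signal level to the
    test-stimulus parameters.  Defaults give 4 blocks x 48 trials, i.e. 2
    repeats of 6 levels x 4 orderings per block.
    """
    n_cells = 4 * len(signal_levels)
    if trials_per_block % n_cells:
        raise ValueError(
            f"trials_per_block = {trials_per_block} not divisible by "
            f"4 x {len(signal_levels)} (level, ordering) cells"
        )
    reps = trials_per_block // n_cells
    trials: list[TrialRecord] = []
    for _ in range(n_blocks):
        cells = [
            (level, ordering)
            for level in signal_levels
            for ordering in ORDERINGS
            for _ in range(reps)
        ]
        for idx in rng.permutation(len(cells)):
            level, ordering = cells[idx]
            seeds = tuple(int(s) for s in rng.integers(0, 2**31, size=3))
            trials.append(
                TrialRecord(
                    ordering=ordering,
                    standard_params=standard_params,
                    test_params=make_test_params(level),
                    token_seeds=seeds,
                    level=level,
                )
            )
    return trials


# Tokens are deterministic functions of their parameters (seed included), so
# the noise-free statistic can be memoized; rating blocks that present the
# same fixed tokens many times then cost one analysis per token.
_stat_cache: dict = {}


def _token_statistic(token: TextureToken, statistic: str, fb: FilterbankConfig) -> float:
    key = (token.params, statistic, fb)
    if key not in _stat_cache:
        if len(_stat_cache) > 4096:
            _stat_cache.clear()
        if statistic == "mod_centroid":
            value = modulation_centroid(analyze_token(token.samples, fb))
        else:
            value = getattr(summary_stats(token.samples, fb), statistic)
        _stat_cache[key] = float(value)
    return _stat_cache[key]


def decision_variable(
    token: TextureToken,
    cfg: ObserverConfig,
    fb: FilterbankConfig,
    rng: np.random.Generator,
) -> float:
    """Selected summary statistic of ``token`` plus Gaussian internal noise."""
    stat = _token_statistic(token, cfg.decision_statistic, fb)
    if cfg.internal_noise_sd > 0:
        stat += rng.normal(0.0, cfg.internal_noise_sd)
    return float(stat)


def simulate_trial(
    trial: TrialRecord,
    cfg: ObserverConfig,
    fb: FilterbankConfig,
    rng: np.random.Generator,
) -> TrialRecord:
    """Synthesize the three intervals, decide, and fill in the response.

    The observer reports the allowed interval k in {2, 3} whose decision
    variable lies farthest from the other two (sum of absolute differences);
    exact ties are broken by a fair coin.
    """
    d = [
        decision_variable(synthesize(p), cfg, fb, rng) for p in trial.interval_params()
    ]
    scores = {k: sum(abs(d[k - 1] - d[j]) for j in range(3) if j != k - 1) for k in (2, 3)}
    if scores[2] == scores[3]:
        response = int(rng.choice([2, 3]))
    else:
        response = 2 if scores[2] > scores[3] else 3
    trial.response_interval = response
    trial.correct = response == trial.odd_interval
    return trial


def simulate_dissimilarity(
    pair: tuple[TextureToken, TextureToken],
    cfg: ObserverConfig,
    fb: FilterbankConfig,
    rng: np.random.Generator,
) -> float:
    """Rating in [0, 1]: scaled logistic of |d1 - d2| plus rating noise.

    The mapping 2 / (1 + exp(-g |d1 - d2|)) - 1 sends identical decision
    variables to 0 and saturates at 1, and is symmetric in the pair order.
    """
    d = [decision_variable(tok, cfg, fb, rng) for tok in pair]
    rating = 2.0 / (1.0 + np.exp(-cfg.rating_gain * abs(d[0] - d[1]))) - 1.0
    if cfg.rating_noise_sd > 0:
        rating += rng.normal(0.0, cfg.rating_noise_sd)
    return float(np.clip(rating, 0.0, 1.0))


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Trial table: one row per trial with parameters, seeds and outcome."""
    rows = []
    for t in trials:
        rows.append(
            {
                "ordering": t.ordering,
                "level": t.level,
                "odd_interval": t.odd_interval,
                "response_interval": t.response_interval,
                "correct": t.correct,
                "standard_A": t.standard_params.A,
                "standard_C": t.standard_params.C,
                "test_A": t.test_params.A,
                "test_C": t.test_params.C,
                "seed_1": t.token_seeds[0],
                "seed_2": t.token_seeds[1],
                "seed_3": t.token_seeds[2],
            }
        )
    return pd.DataFrame(rows)
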