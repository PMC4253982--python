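"""Permutation-derived genome-wide significance threshold.

For one arrangement of bin heterozygosity values the *minimax run
threshold* is the minimum, over all windows of ``run_len`` consecutive
bins within a chromosome, of the maximum value inside the window: the
smallest threshold at which at least one qualifying run exists, i.e. the
value at which the count of significant regions transitions from zero to
one (exactly one, absent ties).  Shuffling the genome-wide multiset of bin
values and recording this statistic per replicate gives its null
distribution; the lower ``alpha`` empirical quantile is the genome-wide
threshold, so a whole-genome scan of a permuted genome yields at least one
qualifying run with probability ``alpha``.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from sweepscan.errors import ConfigurationError, InfeasibleError
from sweepscan.windows import PopulationWindowTrack

DEFAULT_RUN_LEN = 5
DEFAULT_N_REPS = 7000
DEFAULT_ALPHA = 0.05


def replicate_threshold(
    bin_values: Sequence[np.ndarray] | Sequence[Sequence[float]],
    run_len: int = DEFAULT_RUN_LEN,
) -> float:
    """Minimax run threshold of one arrangement of per-chromosome bin values.

    Runs never span chromosome boundaries; chromosomes shorter than
    ``run_len`` contribute no windows.
    """
    if run_len < 1:
        raise ConfigurationError("run_len must be >= 1")
    best = math.inf
    for values in bin_values:
        v = np.asarray(values, dtype=float)
        if len(v) < run_len:
            continue
        best = min(best, float(sliding_window_view(v, run_len).max(axis=1).min()))
    if math.isinf(best):
        raise InfeasibleError(f"no chromosome has >= {run_len} bins")
    return best


def has_qualifying_run(
    bin_values: Sequence[np.ndarray],
    threshold: float,
    run_len: int = DEFAULT_RUN_LEN,
) -> bool:
    """Whether any chromosome carries ``run_len`` consecutive bins with
    value at or below ``threshold``."""
    return replicate_threshold(bin_values, run_len) <= threshold


def lower_quantile(values: np.ndarray, alpha: float) -> float:
    """Lower empirical quantile: the order statistic of rank
    ``ceil(alpha * n)`` (1-based)."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    v = np.sort(np.asarray(values, dtype=float))
    rank = max(math.ceil(alpha * len(v)), 1)
    return float(v[rank - 1])


def _split(pool: np.ndarray, counts: Sequence[int]) -> list[np.ndarray]:
    return np.split(pool, np.cumsum(counts)[:-1])


def _valid_window_starts(counts: Sequence[int], run_len: int) -> np.ndarray:
    """Start indices, in the pooled genome array, of windows of ``run_len``
    bins that do not cross a chromosome boundary."""
    starts = []
    offset = 0
    for c in counts:
        if c >= run_len:
            starts.append(np.arange(offset, offset + c - run_len + 1))
        offset += c
    if not starts:
        raise InfeasibleError(f"no chromosome has >= {run_len} bins")
    return np.concatenate(starts)


def _pooled_minimax(pool: np.ndarray, valid_starts: np.ndarray, run_len: int) -> float:
    window_max = sliding_window_view(pool, run_len).max(axis=1)
    return float(window_max[valid_starts].min())


@dataclass
class ThresholdResult:
    population: str
    run_len: int
    n_reps: int
    alpha: float
    replicate_thresholds: np.ndarray
    genome_wide_threshold: float
    seed: int

    def to_json(self, path: str | Path, include_replicates: bool = True) -> None:
        payload = {
            "population": self.population,
            "run_len": self.run_len,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "genome_wide_threshold": self.genome_wide_threshold,
            "seed": self.seed,
        }
        if include_replicates:
            payload["replicate_thresholds"] = [float(x) for x in self.replicate_thresholds]
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdResult":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            payload = json.load(fh)
        return cls(
            population=payload["population"],
            run_len=payload["run_len"],
            n_reps=payload["n_reps"],
            alpha=payload["alpha"],
            replicate_thresholds=np.asarray(
                payload.get("replicate_thresholds", []), dtype=float
            ),
            genome_wide_threshold=payload["genome_wide_threshold"],
            seed=payload["seed"],
        )


def permute_and_estimate(
    track: PopulationWindowTrack,
    run_len: int = DEFAULT_RUN_LEN,
    n_reps: int = DEFAULT_N_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> ThresholdResult:
    """Estimate the genome-wide threshold for one population's track.

    Each replicate shuffles the pooled genome-wide multiset of bin values
    uniformly, redistributes them into the fixed per-chromosome bin
    structure, and records the minimax run threshold.  Replicate ``r`` uses
    an independently derived random substream of ``seed``, so results are
    reproducible and order-independent.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    counts = track.chromosome_bin_counts()
    if max(counts) < run_len:
        raise InfeasibleError(f"no chromosome has >= {run_len} bins")
    # sorting first makes replicate streams a function of the value multiset
    # (and the seed) alone, not of the genome ordering of the input track
    pool = np.sort(track.het_rates)
    valid = _valid_window_starts(counts, run_len)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    thresholds = np.empty(n_reps, dtype=float)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        thresholds[r] = _pooled_minimax(rng.permutation(pool), valid, run_len)
    return ThresholdResult(
        population=track.population,
        run_len=run_len,
        n_reps=n_reps,
        alpha=alpha,
        replicate_thresholds=thresholds,
        genome_wide_threshold=lower_quantile(thresholds, alpha),
        seed=seed,
    )


def permutation_scan_fraction(
    track: PopulationWindowTrack,
    threshold: float,
    run_len: int = DEFAULT_RUN_LEN,
    n_scans: int = 2000,
    seed: int = 0,
) -> float:
    """Fraction of fresh genome-wide permutations of the track's bin values
    that contain at least one run of ``run_len`` consecutive bins at or
    below ``threshold``: the empirical genome-wide false-positive rate of
    that threshold.  Uses a random stream independent of
    :func:`permute_and_estimate` at the same seed.
    """
    counts = track.chromosome_bin_counts()
    valid = _valid_window_starts(counts, run_len)
    pool = track.het_rates
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1_000_003]))
    hits = 0
    for _ in range(n_scans):
        if _pooled_minimax(rng.permutation(pool), valid, run_len) <= threshold:
            hits += 1
    return hits / n_scans
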