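r"""Online greedy run-selection model.

The sampler maintains a per-tile count vector :math:`c` of uniquely aligned
spots (reads or read pairs) and maximises the concave coverage score

.. math:: S(c) = \sum_{j=1}^{T} \ln(1 + c_j),

whose diminishing returns favour covering new tiles over piling reads onto
already-covered ones.  The next batch of :math:`b` spots is drawn from the run

.. math:: r^* = \operatorname*{argmax}_r \; S(c + b\,\hat q_r\,\hat p_r),

where :math:`\hat p_r` is a pseudocount-smoothed multinomial estimate of the
run's tile profile,

.. math:: \hat p_r[j] \propto c^r_j + \lambda\,T\,\bar p[j] + a,

with :math:`\bar p` the pooled tile frequency over all sampled batches, and
:math:`\hat q_r \in [0,1]` an alignment-quality estimate (a weighted sum of
the run's cumulative uniquely-aligned and spliced fractions).  Never-sampled
runs get an optimistic :math:`\hat q` and a profile equal to the smoothed
pooled profile, so their expected scores tie and exploration is driven by the
tie-break: a random draw biased towards longer average read lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

__all__ = [
    "SelectionParams",
    "RunQuality",
    "CoverageState",
    "ArchiveExhausted",
    "score",
    "estimate_profile",
    "expected_score_after_batch",
    "choose_next_run",
    "update_state",
]


class ArchiveExhausted(RuntimeError):
    """Raised when no eligible (non-blacklisted, non-exhausted) run remains."""


@dataclass
class SelectionParams:
    """Tunable parameters of the selection model.

    Attributes
    ----------
    b : batch size in spots.
    lambda_ : weight of the pooled-profile pseudocount term.
    a : general additive pseudocount.
    max_batches : total batch budget of a sampling session.
    q_weights : ``(w_unique, w_spliced)``, nonnegative, summing to 1; weights
        of the uniquely-aligned and spliced fractions in the quality estimate.
    blacklist_threshold : minimum uniquely-aligned fraction of a run's first
        batch; below it the run is permanently ignored.
    tie_rel_tol : relative tolerance within which expected scores count as tied.
    initial_q_hat : quality assumed for never-sampled runs (optimism drives
        exploration).
    seed : seed for all selection randomness.
    """

    b: int = 50_000
    lambda_: float = 10.0
    a: float = 1.0
    max_batches: int = 1000
    q_weights: tuple = (0.9, 0.1)
    blacklist_threshold: float = 0.05
    tie_rel_tol: float = 1e-12
    initial_q_hat: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("batch size b must be >= 1")
        if self.lambda_ < 0 or self.a < 0:
            raise ValueError("pseudocount parameters must be nonnegative")
        if self.max_batches < 0:
            raise ValueError("max_batches must be >= 0")
        if not 0.0 <= self.blacklist_threshold <= 1.0:
            raise ValueError("blacklist_threshold must be in [0, 1]")
        wu, ws = self.q_weights
        if wu < 0 or ws < 0 or abs(wu + ws - 1.0) > 1e-9:
            raise ValueError("q_weights must be nonnegative and sum to 1")
        if not 0.0 <= self.initial_q_hat <= 1.0:
            raise ValueError("initial_q_hat must be in [0, 1]")


@dataclass
class RunQuality:
    """Cumulative alignment-quality statistics of one run.

    Fractions are pooled over all batches of the run (not averages of
    per-batch fractions).
    """

    n_sampled: int = 0
    n_unique: int = 0
    n_spliced: int = 0

    @property
    def f_unique(self) -> float:
        return self.n_unique / self.n_sampled if self.n_sampled else 0.0

    @property
    def f_spliced(self) -> float:
        return self.n_spliced / self.n_sampled if self.n_sampled else 0.0

    def q_hat(self, q_weights: tuple) -> float:
        wu, ws = q_weights
        return wu * self.f_unique + ws * self.f_spliced


class CoverageState:
    """Global and per-run aligned-spot counts over tiles.

    Maintains the conservation invariant ``c[j] == sum_r c_r[j]``; only
    uniquely aligned spots are counted.
    """

    def __init__(self, n_tiles: int):
        if n_tiles < 1:
            raise ValueError("need at least one tile")
        self.n_tiles = int(n_tiles)
        self.c = np.zeros(self.n_tiles, dtype=np.int64)
        self.per_run: Dict[str, np.ndarray] = {}
        self.quality: Dict[str, RunQuality] = {}

    def run_counts(self, run_id: str) -> np.ndarray:
        counts = self.per_run.get(run_id)
        if counts is None:
            return np.zeros(self.n_tiles, dtype=np.int64)
        return counts

    def grand_total(self) -> int:
        return int(self.c.sum())

    def pooled_profile(self) -> np.ndarray:
        """Relative tile frequency over all sampled batches (uniform if empty)."""
        total = self.c.sum()
        if total == 0:
            return np.full(self.n_tiles, 1.0 / self.n_tiles)
        return self.c / total

    def validate(self) -> None:
        if (self.c < 0).any():
            raise AssertionError("negative global counts")
        pooled = np.zeros(self.n_tiles, dtype=np.int64)
        for counts in self.per_run.values():
            if (counts < 0).any():
                raise AssertionError("negative per-run counts")
            pooled += counts
        if not np.array_equal(pooled, self.c):
            raise AssertionError("count conservation violated: c != sum of per-run counts")


def score(c) -> float:
    r"""Coverage score :math:`S(c) = \sum_j \ln(1 + c_j)`.

    Accepts real-valued (expected) count vectors; entries must be >= 0.
    """
    arr = np.asarray(c, dtype=float)
    if arr.size and float(arr.min()) < 0:
        raise ValueError("count vector has negative entries")
    return float(np.log1p(arr).sum())


def estimate_profile(run_id: str, state: CoverageState, params: SelectionParams) -> np.ndarray:
    """Pseudocount-smoothed multinomial tile profile of a run.

    ``p_hat[j] ∝ c_r[j] + lambda * T * pooled[j] + a``, normalised to sum to 1.
    With no counts anywhere the pooled profile is uniform, so the estimate is
    uniform too.
    """
    T = state.n_tiles
    weights = state.run_counts(run_id) + params.lambda_ * T * state.pooled_profile() + params.a
    total = weights.sum()
    if total == 0.0:  # lambda == a == 0 and run never sampled
        return np.full(T, 1.0 / T)
    return weights / total


def _q_hat(run_id: str, state: CoverageState, params: SelectionParams) -> float:
    quality = state.quality.get(run_id)
    if quality is None or quality.n_sampled == 0:
        return params.initial_q_hat
    return quality.q_hat(params.q_weights)


def expected_score_after_batch(run, state: CoverageState, params: SelectionParams) -> float:
    """Score of the expected count vector after one batch from ``run``.

    ``run`` may be a run id or a record with ``run_id`` (and optionally
    ``blacklisted`` / ``exhausted`` flags, which must be unset).
    The expectation ``b * q_hat * p_hat`` is real-valued; no rounding.
    """
    run_id = getattr(run, "run_id", run)
    if getattr(run, "blacklisted", False):
        raise ValueError(f"run {run_id} is blacklisted")
    if getattr(run, "exhausted", False):
        raise ValueError(f"run {run_id} is exhausted")
    p_hat = estimate_profile(run_id, state, params)
    q_hat = _q_hat(run_id, state, params)
    return score(state.c + params.b * q_hat * p_hat)


def _tie_break_weights(candidates: Sequence) -> np.ndarray:
    """Draw weights proportional to average read length; missing lengths are
    imputed as the median of the known ones (equal weights if none known)."""
    lengths = [getattr(r, "avg_read_length", None) for r in candidates]
    known = [float(x) for x in lengths if x is not None and x == x and x > 0]
    fill = float(np.median(known)) if known else 1.0
    weights = np.array(
        [float(x) if (x is not None and x == x and x > 0) else fill for x in lengths]
    )
    if weights.sum() <= 0:
        weights = np.ones(len(candidates))
    return weights / weights.sum()


def choose_next_run(
    candidates: Sequence,
    state: CoverageState,
    params: SelectionParams,
    rng: np.random.Generator,
) -> str:
    """Greedy choice of the next run to sample.

    Returns the id of a run maximising the expected post-batch score; among
    runs tied within ``tie_rel_tol`` (relative), one is drawn with probability
    proportional to its average read length.  All never-sampled runs share one
    expected score (identical profile estimate and initial quality), which is
    evaluated once for the whole class.

    Raises :class:`ArchiveExhausted` on an empty candidate list.
    """
    if not candidates:
        raise ArchiveExhausted("no eligible run remains")
    values = {}
    unsampled_value: Optional[float] = None
    for run in candidates:
        run_id = getattr(run, "run_id", run)
        sampled = run_id in state.quality or run_id in state.per_run
        if not sampled:
            if unsampled_value is None:
                unsampled_value = expected_score_after_batch(run, state, params)
            values[run_id] = unsampled_value
        else:
            values[run_id] = expected_score_after_batch(run, state, params)
    v_max = max(values.values())
    tol = params.tie_rel_tol * max(abs(v_max), 1.0)
    tied = [r for r in candidates if values[getattr(r, "run_id", r)] >= v_max - tol]
    if len(tied) == 1:
        return getattr(tied[0], "run_id", tied[0])
    weights = _tie_break_weights(tied)
    idx = int(rng.choice(len(tied), p=weights))
    return getattr(tied[idx], "run_id", tied[idx])


def update_state(state: CoverageState, run_id: str, batch) -> CoverageState:
    """Fold one classified batch into the coverage state.

    Increments global and per-run tile counts by the batch's uniquely aligned
    spots and pools the run's quality statistics over all of its batches.
    ``batch`` is a :class:`~rnascout.accounting.BatchResult`.
    """
    if batch.run_id != run_id:
        raise ValueError(f"batch belongs to {batch.run_id!r}, not {run_id!r}")
    if batch.tile_increments:
        counts = state.per_run.get(run_id)
        if counts is None:
            counts = state.per_run.setdefault(run_id, np.zeros(state.n_tiles, dtype=np.int64))
        for tile, n in batch.tile_increments.items():
            if not 0 <= tile < state.n_tiles:
                raise ValueError(f"tile index {tile} out of range 0..{state.n_tiles - 1}")
            counts[tile] += n
            state.c[tile] += n
    quality = state.quality.setdefault(run_id, RunQuality())
    quality.n_sampled += batch.spots_downloaded
    quality.n_unique += batch.spots_unique
    quality.n_spliced += batch.spots_spliced
    return state
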