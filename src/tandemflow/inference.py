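"""Surrogate-data null construction, bias correction and hypothesis tests.

Plug-in transfer entropy is biased upward on finite samples. The null used
here re-pairs leaders with followers from *different* trials (a derangement
of follower indices), which preserves each series' marginal dynamics while
breaking any within-pair coupling. The mean transfer entropy over an
ensemble of such surrogate datasets (default 50) serves as a finite-sample
bias correction; the ensemble and per-trial values also feed one-sided
Wilcoxon tests of experimental-vs-surrogate and leader-vs-follower effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .encoding import EncodedDataset, SymbolSeries, _truncate_to_common
from .infodyn import InfoDynError, TEResult, transfer_entropy
from .trajectory_io import Dataset, TandemPair, TrajectoryError


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Derangements and surrogate datasets


def sample_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of 0..n-1 with no fixed point.

    Rejection sampling: acceptance probability tends to 1/e, so this is fast
    for the dataset sizes in play (n <= a few dozen).
    """
    if n < 2:
        raise InferenceError("no derangement exists for fewer than 2 trials")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _truncate_pair(leader, follower):
    n = min(len(leader), len(follower))
    lead = replace(leader, positions=leader.positions[:n])
    foll = replace(follower, positions=follower.positions[:n])
    return lead, foll


def make_surrogate_dataset(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Re-pair each leader with a follower from a different trial."""
    n = len(dataset)
    if n < 2:
        raise InferenceError("surrogate construction needs at least 2 pairs")
    perm = sample_derangement(n, rng)
    pairs = []
    for i, j in enumerate(perm):
        lead, foll = _truncate_pair(dataset.pairs[i].leader, dataset.pairs[j].follower)
        pairs.append(
            TandemPair(
                lead,
                foll,
                species=dataset.species,
                body_length_mm=dataset.pairs[i].body_length_mm,
            )
        )
    return Dataset(tuple(pairs), species=dataset.species)


def surrogate_pairs(
    encoded: EncodedDataset, rng: np.random.Generator
) -> tuple[tuple[SymbolSeries, ...], tuple[SymbolSeries, ...]]:
    """Derange the follower series of an encoded dataset, lengths realigned."""
    n = len(encoded)
    if n < 2:
        raise InferenceError("surrogate construction needs at least 2 pairs")
    perm = sample_derangement(n, rng)
    leaders, followers = [], []
    for i, j in enumerate(perm):
        sl, sf = _truncate_to_common(encoded.leaders[i], encoded.followers[j])
        leaders.append(sl)
        followers.append(sf)
    return tuple(leaders), tuple(followers)


# ---------------------------------------------------------------------------
# Surrogate transfer entropy


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Transfer entropy over re-paired pseudo-datasets."""

    n_replicates: int
    seed: int
    per_replicate_te: tuple[float, ...]
    mean_bits: float
    se_bits: float  # nan when n_replicates == 1

    def __post_init__(self) -> None:
        if len(self.per_replicate_te) != self.n_replicates:
            raise InferenceError("replicate vector length != n_replicates")


def _directed(leaders, followers, direction):
    if direction == ("leader", "follower"):
        return leaders, followers
    if direction == ("follower", "leader"):
        return followers, leaders
    raise InferenceError(f"unknown direction {direction!r}")


def surrogate_te(
    encoded: EncodedDataset,
    k: int,
    direction: tuple[str, str] = ("leader", "follower"),
    n_replicates: int = 50,
    seed: int = 0,
    mode: str = "pooled",
) -> SurrogateEnsemble:
    """Transfer entropy of ``n_replicates`` independently re-paired datasets.

    Uses the same estimator mode as the experimental estimate; the ensemble
    mean is the bias-correction factor and the SE its uncertainty.
    """
    if n_replicates < 1:
        raise InferenceError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_replicates):
        leaders, followers = surrogate_pairs(encoded, rng)
        src, dst = _directed(leaders, followers, direction)
        values.append(transfer_entropy(src, dst, k, mode=mode, direction=direction).te_bits)
    arr = np.asarray(values)
    se = float("nan") if n_replicates == 1 else float(arr.std(ddof=1) / np.sqrt(n_replicates))
    return SurrogateEnsemble(
        n_replicates=n_replicates,
        seed=seed,
        per_replicate_te=tuple(float(v) for v in values),
        mean_bits=float(arr.mean()),
        se_bits=se,
    )


def surrogate_per_trial_te(
    encoded: EncodedDataset,
    k: int,
    direction: tuple[str, str] = ("leader", "follower"),
    seed: int = 0,
) -> tuple[float, ...]:
    """Per-trial TE values of a single re-paired replicate.

    One value per surrogate pair — the comparison set whose size matches the
    experimental per-trial sample in the rank-sum test.
    """
    rng = np.random.default_rng(seed)
    leaders, followers = surrogate_pairs(encoded, rng)
    src, dst = _directed(leaders, followers, direction)
    res = transfer_entropy(src, dst, k, mode="per_trial", direction=direction)
    return res.per_trial_values


def corrected_te(raw_bits: float, ensemble: SurrogateEnsemble) -> float:
    """Raw estimate discounted by the surrogate-ensemble mean (may go negative)."""
    return raw_bits - ensemble.mean_bits


# ---------------------------------------------------------------------------
# Wilcoxon tests


@dataclass(frozen=True)
class HypothesisResult:
    test: str  # {rank_sum, signed_rank}
    alternative: str
    statistic: float  # W (Mann-Whitney U of x) or V (positive-rank sum)
    p_value: float


def ranksum_greater(x: Sequence[float], y: Sequence[float]) -> HypothesisResult:
    """One-sided two-sample Wilcoxon rank-sum test, alternative x > y.

    Normal approximation with continuity correction and midrank ties. The
    statistic is the Mann-Whitney U of x over y (maximum ``n1 * n2``).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InferenceError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="greater", use_continuity=True, method="asymptotic"
    )
    return HypothesisResult("rank_sum", "greater", float(res.statistic), float(res.pvalue))


def signedrank_greater(x: Sequence[float], y: Sequence[float]) -> HypothesisResult:
    """One-sided paired Wilcoxon signed-rank test, alternative x > y.

    V is the sum of ranks of positive differences (maximum ``n(n+1)/2``);
    zero differences are discarded, normal approximation with continuity
    correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise InferenceError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise InferenceError("all paired differences are zero")
    res = stats.wilcoxon(
        x,
        y,
        alternative="greater",
        correction=True,
        zero_method="wilcox",
        method="approx",
    )
    return HypothesisResult("signed_rank", "greater", float(res.statistic), float(res.pvalue))
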