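"""Plug-in information dynamics on symbolic series.

Entropy, conditional entropy, transfer entropy, local transfer entropy and
the derived net/normalized quantities, all in bits, estimated by substituting
empirical block frequencies for probabilities (the plug-in estimator).

Transfer entropy from a source S to a destination X with destination history
length k is

    T(S -> X) = sum p(x_{i+1}, x_i^{(k)}, s_i)
                    log2 [ p(x_{i+1} | x_i^{(k)}, s_i) / p(x_{i+1} | x_i^{(k)}) ]

where x_i^{(k)} = (x_{i-k+1}, ..., x_i). The source enters only through its
present symbol s_i. The per-step logarithm is the local transfer entropy; its
average over all counted transitions equals the pooled estimate exactly.

Counting is sparse: blocks are packed into integer codes and tallied with
``np.unique``, so memory scales with the number of *observed* blocks (at most
the series length), never with alphabet**k — the landscape sweep conditions
on histories up to k = 20.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .encoding import SymbolSeries

_LOG2 = math.log(2.0)


class InfoDynError(ValueError):
    pass


def entropy(distribution: Sequence[float], tol: float = 1e-9) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    p = np.asarray(distribution, dtype=float)
    if np.any(p < -tol):
        raise InfoDynError("negative probability mass")
    if abs(p.sum() - 1.0) > max(tol, 1e-6):
        raise InfoDynError(f"probabilities sum to {p.sum()!r}, not 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Block extraction and sparse counting


def _as_codes(series) -> np.ndarray:
    if isinstance(series, SymbolSeries):
        return series.symbols.astype(np.int64)
    return np.asarray(series, dtype=np.int64)


def _alphabet_size(trials) -> int:
    sizes = set()
    amax = 0
    for t in trials:
        if isinstance(t, SymbolSeries):
            sizes.add(len(t.alphabet))
        else:
            amax = max(amax, int(np.max(t)) + 1)
    if len(sizes) > 1:
        raise InfoDynError("mixed alphabets across trials")
    return sizes.pop() if sizes else max(amax, 2)


def _transition_codes(dest: np.ndarray, src: np.ndarray | None, k: int, a: int):
    """Per-transition (history, future, source) codes for one trial.

    Returns arrays of length ``n - k`` where ``n = len(dest)``; history codes
    pack ``(x_{i-k+1}, ..., x_i)`` base-``a``.
    """
    n = dest.size
    if n < k + 1:
        return None
    # history code ending at index i for i = k-1 .. n-1
    h = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        h = h * a + dest[j : n - k + 1 + j]
    hist = h[:-1]  # ends at i = k-1 .. n-2
    fut = dest[k:]
    s = None if src is None else src[k - 1 : n - 1]
    return hist, fut, s


@dataclass(frozen=True)
class BlockCounts:
    """Sparse counts of (future, k-history, source) transition blocks.

    Only observed blocks are stored: ``keys``/``counts`` are the packed
    integer codes and tallies of distinct (history, future[, source]) blocks,
    so at most ``total`` entries exist regardless of alphabet**k.
    """

    k: int
    dest_alphabet_size: int
    src_alphabet_size: int | None
    keys: np.ndarray
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.total:
            raise InfoDynError("counts do not sum to total")
        if np.any(self.counts <= 0):
            raise InfoDynError("stored block with non-positive count")

    def _decode_key(self, key: int):
        a = self.dest_alphabet_size
        if self.src_alphabet_size is not None:
            key, src = divmod(key, self.src_alphabet_size)
        else:
            src = None
        key, fut = divmod(key, a)
        hist = []
        for _ in range(self.k):
            key, sym = divmod(key, a)
            hist.append(sym)
        block = (int(fut), tuple(reversed([int(s) for s in hist])))
        return block if src is None else block + (int(src),)

    def as_dict(self) -> dict:
        """Counts keyed by (future, history-tuple[, source]) symbol codes."""
        return {
            self._decode_key(int(key)): int(c)
            for key, c in zip(self.keys, self.counts)
        }


def _pooled_transitions(dest_trials, src_trials, k: int):
    """Concatenate per-trial transition codes; returns (hist, fut, src, a, a_src, slices)."""
    dest_list = [_as_codes(t) for t in dest_trials]
    src_list = None if src_trials is None else [_as_codes(t) for t in src_trials]
    if src_list is not None:
        if len(src_list) != len(dest_list):
            raise InfoDynError("source and destination trial counts differ")
        for s, d in zip(src_list, dest_list):
            if s.size != d.size:
                raise InfoDynError(
                    f"misaligned series: source has {s.size} symbols, "
                    f"destination {d.size}"
                )
    a = _alphabet_size(dest_trials)
    a_src = None if src_trials is None else _alphabet_size(src_trials)

    hists, futs, srcs, slices = [], [], [], []
    start = 0
    for i, d in enumerate(dest_list):
        tc = _transition_codes(d, None if src_list is None else src_list[i], k, a)
        if tc is None:
            warnings.warn(
                f"trial {i} has {d.size} symbols < k+1 = {k + 1}; skipped",
                stacklevel=2,
            )
            slices.append((start, start))
            continue
        hist, fut, s = tc
        hists.append(hist)
        futs.append(fut)
        if s is not None:
            srcs.append(s)
        slices.append((start, start + fut.size))
        start += fut.size
    if not futs:
        raise InfoDynError(f"every trial is shorter than k+1 = {k + 1} symbols")
    hist = np.concatenate(hists)
    fut = np.concatenate(futs)
    src = np.concatenate(srcs) if srcs else None
    return hist, fut, src, a, a_src, slices


def count_blocks(dest_trials, k: int, src_trials=None) -> BlockCounts:
    """Tally every (future, k-history[, source]) transition, pooled over trials.

    Blocks never span trial boundaries; trials shorter than k+1 symbols are
    skipped with a warning.
    """
    if k < 1:
        raise InfoDynError("history length k must be >= 1")
    hist, fut, src, a, a_src, _ = _pooled_transitions(dest_trials, src_trials, k)
    key = hist * a + fut
    if src is not None:
        key = key * a_src + src
    keys, counts = np.unique(key, return_counts=True)
    return BlockCounts(k, a, a_src, keys, counts, int(counts.sum()))


def _per_sample_counts(codes: np.ndarray) -> np.ndarray:
    """For each entry, the number of times its value occurs in the array."""
    _, inv, cnt = np.unique(codes, return_inverse=True, return_counts=True)
    return cnt[inv]


def _local_terms(hist, fut, src, a, a_src):
    """Per-transition -log2 p(f|h), and with a source also -log2 p(f|h,s)."""
    n = fut.size
    key_hf = hist * a + fut
    c_h = _per_sample_counts(hist)
    c_hf = _per_sample_counts(key_hf)
    nll_f_given_h = -np.log2(c_hf / c_h)
    if src is None:
        return nll_f_given_h, None
    key_hs = hist * a_src + src
    key_hfs = key_hf * a_src + src
    c_hs = _per_sample_counts(key_hs)
    c_hfs = _per_sample_counts(key_hfs)
    nll_f_given_hs = -np.log2(c_hfs / c_hs)
    return nll_f_given_h, nll_f_given_hs


# ---------------------------------------------------------------------------
# Estimators


@dataclass(frozen=True)
class TEResult:
    """A transfer-entropy estimate with its conditioning parameters."""

    direction: tuple[str, str]  # (source role, destination role)
    te_bits: float
    cond_entropy_bits: float  # H(X_{i+1} | X^{(k)}) of the destination
    k: int
    period_s: float = float("nan")
    mode: str = "pooled"  # {pooled, per_trial}
    per_trial_values: tuple[float, ...] | None = None
    n_transitions: int = 0

    def to_dict(self) -> dict:
        d = {
            "direction": list(self.direction),
            "te_bits": self.te_bits,
            "cond_entropy_bits": self.cond_entropy_bits,
            "k": self.k,
            "period_s": self.period_s,
            "mode": self.mode,
            "n_transitions": self.n_transitions,
        }
        if self.per_trial_values is not None:
            d["per_trial_values"] = list(self.per_trial_values)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TEResult":
        d = json.loads(s)
        ptv = d.get("per_trial_values")
        return cls(
            direction=tuple(d["direction"]),
            te_bits=d["te_bits"],
            cond_entropy_bits=d["cond_entropy_bits"],
            k=d["k"],
            period_s=d["period_s"],
            mode=d["mode"],
            per_trial_values=None if ptv is None else tuple(ptv),
            n_transitions=d["n_transitions"],
        )


@dataclass(frozen=True)
class LocalTESeries:
    """Per-time-step local transfer entropy, one array per trial.

    Values are aligned to destination time indices: entry ``t`` of a trial's
    array is the local term for the transition whose future symbol has index
    ``k + t`` in that trial's series. The grand mean over every counted step
    equals the pooled transfer entropy exactly.
    """

    per_trial: tuple[np.ndarray, ...]
    k: int
    direction: tuple[str, str]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([v for v in self.per_trial if v.size])

    @property
    def mean_bits(self) -> float:
        return float(self.values.mean())

    def to_dict(self) -> dict:
        return {
            "direction": list(self.direction),
            "k": self.k,
            "per_trial_values": [v.tolist() for v in self.per_trial],
        }


def _meta(dest_trials, direction=None):
    period = float("nan")
    roles = ("source", "destination")
    for t in dest_trials:
        if isinstance(t, SymbolSeries):
            period = t.period_s
            break
    return direction if direction is not None else roles, period


def conditional_entropy(dest_trials, k: int) -> float:
    """Plug-in H(X_{i+1} | X^{(k)}) in bits from pooled block frequencies."""
    if k < 1:
        raise InfoDynError("history length k must be >= 1")
    hist, fut, _, a, _, _ = _pooled_transitions(dest_trials, None, k)
    nll, _ = _local_terms(hist, fut, None, a, None)
    return float(nll.mean())


def transfer_entropy(
    src_trials, dest_trials, k: int, mode: str = "pooled", direction=None
) -> TEResult:
    """Plug-in transfer entropy source -> destination in bits.

    ``pooled`` estimates one value from block counts summed over all trials
    (the headline estimate); ``per_trial`` computes one value per trial from
    that trial's counts alone and reports their mean, with the vector kept in
    ``per_trial_values``.
    """
    if k < 1:
        raise InfoDynError("history length k must be >= 1")
    if mode not in ("pooled", "per_trial"):
        raise InfoDynError(f"unknown mode {mode!r}")
    direction, period = _meta(dest_trials, direction)

    if mode == "per_trial":
        values, hs = [], []
        ns = []
        for s, d in zip(src_trials, dest_trials):
            try:
                r = transfer_entropy([s], [d], k, mode="pooled", direction=direction)
            except InfoDynError:
                continue
            values.append(r.te_bits)
            hs.append(r.cond_entropy_bits)
            ns.append(r.n_transitions)
        if not values:
            raise InfoDynError(f"every trial is shorter than k+1 = {k + 1} symbols")
        return TEResult(
            direction=tuple(direction),
            te_bits=float(np.mean(values)),
            cond_entropy_bits=float(np.mean(hs)),
            k=k,
            period_s=period,
            mode="per_trial",
            per_trial_values=tuple(float(v) for v in values),
            n_transitions=int(np.sum(ns)),
        )

    hist, fut, src, a, a_src, _ = _pooled_transitions(dest_trials, src_trials, k)
    if src is None:
        raise InfoDynError("transfer entropy requires a source")
    nll_h, nll_hs = _local_terms(hist, fut, src, a, a_src)
    local = nll_h - nll_hs
    return TEResult(
        direction=tuple(direction),
        te_bits=float(local.mean()),
        cond_entropy_bits=float(nll_h.mean()),
        k=k,
        period_s=period,
        mode="pooled",
        n_transitions=int(fut.size),
    )


def local_transfer_entropy(src_trials, dest_trials, k: int, direction=None) -> LocalTESeries:
    """Per-transition log-ratio terms using pooled plug-in probabilities.

    Positive values are informative steps, negative ones misinformative; the
    mean over all counted steps is the pooled transfer entropy.
    """
    if k < 1:
        raise InfoDynError("history length k must be >= 1")
    direction, _ = _meta(dest_trials, direction)
    hist, fut, src, a, a_src, slices = _pooled_transitions(dest_trials, src_trials, k)
    if src is None:
        raise InfoDynError("local transfer entropy requires a source")
    nll_h, nll_hs = _local_terms(hist, fut, src, a, a_src)
    local = nll_h - nll_hs
    per_trial = tuple(local[lo:hi] for lo, hi in slices)
    return LocalTESeries(per_trial=per_trial, k=k, direction=tuple(direction))


def net_transfer_entropy(
    leader_trials, follower_trials, k_lf: int, k_fl: int | None = None, mode: str = "pooled"
) -> float:
    """T(leader -> follower) - T(follower -> leader), in bits.

    Positive values mean information flows predominantly from the leader to
    the follower.
    """
    if k_fl is None:
        k_fl = k_lf
    t_lf = transfer_entropy(
        leader_trials, follower_trials, k_lf, mode=mode, direction=("leader", "follower")
    )
    t_fl = transfer_entropy(
        follower_trials, leader_trials, k_fl, mode=mode, direction=("follower", "leader")
    )
    return t_lf.te_bits - t_fl.te_bits


def normalized_transfer_entropy(te: TEResult, correction: float = 0.0) -> float:
    """(TE - correction) / H(X_{i+1}|X^{(k)}), clamped to [0, 1].

    The fraction of the destination's remaining uncertainty explained by the
    source. ``correction`` is typically a surrogate-ensemble mean.
    """
    if not te.cond_entropy_bits > 0:
        raise InfoDynError(
            "conditional entropy is zero: destination is fully self-predictable"
        )
    val = (te.te_bits - correction) / te.cond_entropy_bits
    return float(min(1.0, max(0.0, val)))
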