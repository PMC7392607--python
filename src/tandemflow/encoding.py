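"""Symbolic coarse-graining of trajectories into behavioral patterns.

Three encodings are supported, each mapping a (subsampled) spatial trajectory
to a discrete symbol series:

``pausing``
    Binary motion/pause alphabet ``(M, P)``. A time step is a pause when the
    distance travelled between consecutive sampled positions falls within the
    q-th percentile (default 10) of the step-size distribution pooled over all
    runners of the species at that sampling period.
``rotation``
    Binary turn alphabet ``(CW, CCW)`` from the sign of the 2-D cross product
    of consecutive displacement vectors; exactly-collinear steps copy the
    previous turn direction.
``compound``
    Ternary ``(P, CW, CCW)``: pause wherever the pausing encoder pauses
    (pauses and rotations are mutually exclusive), the rotation symbol
    elsewhere.

Symbols are stored as small integer codes with the alphabet kept alongside,
which makes the downstream block counting cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Dataset, RawTrajectory, TandemPair

PAUSING_ALPHABET = ("M", "P")
ROTATION_ALPHABET = ("CW", "CCW")
COMPOUND_ALPHABET = ("P", "CW", "CCW")

PATTERNS = ("pausing", "rotation", "compound")

#: Patterns that depend on the pause/motion step-size threshold.
PAUSE_BEARING = ("pausing", "compound")


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class SymbolSeries:
    """A coarse-grained behavioral sequence over a fixed alphabet."""

    symbols: np.ndarray  # int8 codes into `alphabet`
    alphabet: tuple[str, ...]
    period_s: float
    trial_id: str = ""
    role: str = ""

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype=np.int8)
        if sym.size == 0:
            raise EncodingError("empty symbol series")
        if sym.min() < 0 or sym.max() >= len(self.alphabet):
            raise EncodingError("symbol code outside alphabet")
        object.__setattr__(self, "symbols", sym)

    def __len__(self) -> int:
        return self.symbols.size

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.alphabet)[self.symbols]


@dataclass(frozen=True)
class StepSizeThreshold:
    """Step-size percentile threshold separating pauses from motion."""

    species: str
    period_s: float
    percentile_q: float
    threshold_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.percentile_q <= 100:
            raise EncodingError("percentile_q must be in [0, 100]")
        if self.threshold_mm < 0:
            raise EncodingError("threshold_mm must be non-negative")


def step_sizes(traj: RawTrajectory) -> np.ndarray:
    """Euclidean distance travelled between consecutive sampled positions."""
    if len(traj) < 2:
        raise EncodingError("need at least 2 positions to compute step sizes")
    return np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)


def pause_threshold(dataset: Dataset, period_s: float, q: float = 10.0) -> StepSizeThreshold:
    """Fit the q-th percentile of step sizes pooled over every runner.

    Leaders and followers contribute jointly; the dataset must already be
    subsampled at ``period_s``. Linear interpolation between order statistics.
    """
    pooled = []
    for pair in dataset:
        pooled.append(step_sizes(pair.leader))
        pooled.append(step_sizes(pair.follower))
    if not pooled:
        raise EncodingError("empty dataset: no step sizes to pool")
    sizes = np.concatenate(pooled)
    thr = float(np.percentile(sizes, q))
    return StepSizeThreshold(dataset.species, period_s, q, thr)


def _check_period(traj: RawTrajectory, thr: StepSizeThreshold) -> None:
    native = 1.0 / traj.frame_rate
    if not np.isclose(native, thr.period_s, rtol=5e-3, atol=1e-6):
        raise EncodingError(
            f"trajectory period {native:.4f} s does not match threshold "
            f"period {thr.period_s:.4f} s"
        )


def encode_pausing(traj: RawTrajectory, thr: StepSizeThreshold) -> SymbolSeries:
    """One symbol per step: P if step size <= threshold, else M.

    Ties at the threshold are pauses (the q-th percentile is inclusive).
    """
    _check_period(traj, thr)
    sizes = step_sizes(traj)
    codes = (sizes <= thr.threshold_mm).astype(np.int8)  # M=0, P=1
    return SymbolSeries(codes, PAUSING_ALPHABET, thr.period_s, traj.trial_id, traj.role)


def _carry_forward(signs: np.ndarray, trial_id: str) -> np.ndarray:
    """Resolve zero cross products by copying the previous signed symbol.

    A leading collinear run takes the first signed symbol retroactively; a
    fully collinear series is an error.
    """
    nz = np.flatnonzero(signs)
    if nz.size == 0:
        raise EncodingError(
            f"trial {trial_id!r}: entire trajectory is collinear, "
            "no turn direction can be assigned"
        )
    # forward-fill indices of the last signed entry; leading zeros -> first signed
    idx = np.arange(signs.size)
    last = np.maximum.accumulate(np.where(signs != 0, idx, -1))
    last[last < 0] = nz[0]
    return signs[last]


def encode_rotation(traj: RawTrajectory, y_axis_down: bool = False) -> SymbolSeries:
    """Turn direction at each interior point from the displacement cross product.

    With a y-up (mathematical) axis convention, a positive cross product is a
    counterclockwise turn. ``y_axis_down=True`` (image coordinates) flips the
    sign so the labels stay physically correct.
    """
    if len(traj) < 3:
        raise EncodingError("need at least 3 positions to encode rotation")
    disp = np.diff(traj.positions, axis=0)
    u, v = disp[:-1], disp[1:]
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    if y_axis_down:
        cross = -cross
    signs = np.sign(cross)
    signs = _carry_forward(signs, traj.trial_id)
    codes = (signs > 0).astype(np.int8)  # CW=0, CCW=1
    period = 1.0 / traj.frame_rate
    return SymbolSeries(codes, ROTATION_ALPHABET, period, traj.trial_id, traj.role)


def encode_compound(
    traj: RawTrajectory, thr: StepSizeThreshold, y_axis_down: bool = False
) -> SymbolSeries:
    """Ternary pause/turn series; pauses override turn geometry.

    The pausing stream (one symbol per step) and the rotation stream (one per
    interior point) are aligned by dropping the leading pausing entry, so the
    result has ``len(traj) - 2`` symbols.
    """
    pausing = encode_pausing(traj, thr)
    rotation = encode_rotation(traj, y_axis_down=y_axis_down)
    pause_mask = pausing.symbols[1:] == 1  # drop leading entry to align
    codes = np.where(pause_mask, 0, rotation.symbols + 1).astype(np.int8)
    return SymbolSeries(codes, COMPOUND_ALPHABET, thr.period_s, traj.trial_id, traj.role)


# ---------------------------------------------------------------------------
# Dataset-level encoding


@dataclass(frozen=True)
class EncodedDataset:
    """Aligned leader/follower symbol series for every trial of a dataset."""

    leaders: tuple[SymbolSeries, ...]
    followers: tuple[SymbolSeries, ...]
    pattern: str
    threshold: StepSizeThreshold | None = None

    def __len__(self) -> int:
        return len(self.leaders)


def _truncate_to_common(a: SymbolSeries, b: SymbolSeries) -> tuple[SymbolSeries, SymbolSeries]:
    """Drop leading entries so both series of a trial have equal length."""
    n = min(len(a), len(b))
    trim = lambda s: SymbolSeries(s.symbols[len(s) - n :], s.alphabet, s.period_s, s.trial_id, s.role)
    return trim(a), trim(b)


def encode_dataset(
    dataset: Dataset,
    pattern: str,
    q: float = 10.0,
    y_axis_down: bool = False,
    threshold: StepSizeThreshold | None = None,
) -> EncodedDataset:
    """Encode every pair of a (subsampled) dataset under one pattern.

    For pause-bearing patterns the threshold is fitted on the pooled dataset
    unless one is supplied. Leader and follower series of each trial are
    truncated to a common length by dropping leading entries.
    """
    if pattern not in PATTERNS:
        raise EncodingError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")
    thr = threshold
    if pattern in PAUSE_BEARING and thr is None:
        period = 1.0 / dataset.pairs[0].frame_rate if len(dataset) else 0.0
        thr = pause_threshold(dataset, period, q)

    def enc(traj: RawTrajectory) -> SymbolSeries:
        if pattern == "pausing":
            return encode_pausing(traj, thr)
        if pattern == "rotation":
            return encode_rotation(traj, y_axis_down=y_axis_down)
        return encode_compound(traj, thr, y_axis_down=y_axis_down)

    leaders, followers = [], []
    for pair in dataset:
        sl, sf = _truncate_to_common(enc(pair.leader), enc(pair.follower))
        leaders.append(sl)
        followers.append(sf)
    return EncodedDataset(tuple(leaders), tuple(followers), pattern, thr)


# ---------------------------------------------------------------------------
# Symbol-series round-trip I/O


def write_symbols(series: Iterable[SymbolSeries], path) -> None:
    rows = []
    for s in series:
        for t, lab in enumerate(s.labels):
            rows.append((s.trial_id, s.role, t, lab))
    pd.DataFrame(rows, columns=["trial_id", "role", "t_index", "symbol"]).to_csv(
        path, index=False
    )


def read_symbols(path, alphabet: tuple[str, ...], period_s: float) -> list[SymbolSeries]:
    df = pd.read_csv(path, dtype={"trial_id": str, "role": str, "symbol": str})
    lookup = {lab: i for i, lab in enumerate(alphabet)}
    out = []
    for (trial_id, role), grp in df.groupby(["trial_id", "role"], sort=True):
        grp = grp.sort_values("t_index")
        try:
            codes = np.array([lookup[s] for s in grp["symbol"]], dtype=np.int8)
        except KeyError as e:
            raise EncodingError(f"symbol {e.args[0]!r} not in alphabet {alphabet}") from None
        out.append(SymbolSeries(codes, alphabet, period_s, str(trial_id), role))
    return out
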