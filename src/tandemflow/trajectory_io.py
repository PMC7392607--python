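"""Loading, scaling, clipping and temporal subsampling of paired trajectories.

A tandem run is recorded as two synchronized 2-D tracks, one for the leader
and one for the follower, sampled at a fixed frame rate. This module owns the
canonical in-memory containers (:class:`RawTrajectory`, :class:`TandemPair`,
:class:`Dataset`) and the three transformations every downstream stage relies
on: pixel-to-mm scaling at load time, clipping to a common duration, and
temporal subsampling to a coarser sampling period.

Subsampling convention
----------------------
Retaining every *n*-th frame (frames ``n, 2n, 3n, ...``) from ``N`` frames
yields ``floor(N / n)`` positions, with ``n = round(period * frame_rate)``.
For comparisons against counts reported at a printed (rounded) period, use
:func:`expected_sample_count`, which evaluates ``floor(duration / period)``
with the printed period; integer-frame decimation can differ from it by one
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LEADER = "leader"
FOLLOWER = "follower"
ROLES = (LEADER, FOLLOWER)

#: Mean body length in mm per species (used as the cross-species distance unit).
BODY_LENGTH_MM = {
    "T. rugatulus": 2.34,
    "C. formosanus": 8.89,
    "R. speratus": 5.5,
}


class TrajectoryError(ValueError):
    """Structural or parse problem in trajectory data."""


@dataclass(frozen=True)
class RawTrajectory:
    """A single runner's track: ordered 2-D positions in mm at a fixed rate."""

    trial_id: str
    role: str
    positions: np.ndarray  # shape (n, 2), mm
    frame_rate: float  # samples per second of *this* series

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] == 0:
            raise TrajectoryError(
                f"positions must be a non-empty (n, 2) array, got shape {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise TrajectoryError(f"non-finite coordinate in trial {self.trial_id!r}")
        if self.role not in ROLES:
            raise TrajectoryError(f"role must be one of {ROLES}, got {self.role!r}")
        if not self.frame_rate > 0:
            raise TrajectoryError("frame_rate must be positive")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds implied by the sample count."""
        return len(self) / self.frame_rate


@dataclass(frozen=True)
class TandemPair:
    """Synchronized leader and follower trajectories for one trial."""

    leader: RawTrajectory
    follower: RawTrajectory
    species: str = ""
    body_length_mm: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.leader) != len(self.follower):
            raise TrajectoryError(
                f"trial {self.trial_id!r}: leader has {len(self.leader)} frames, "
                f"follower has {len(self.follower)}"
            )
        if self.leader.frame_rate != self.follower.frame_rate:
            raise TrajectoryError(f"trial {self.trial_id!r}: frame rates differ")
        if math.isnan(self.body_length_mm):
            bl = BODY_LENGTH_MM.get(self.species, float("nan"))
            object.__setattr__(self, "body_length_mm", bl)
        elif not self.body_length_mm > 0:
            raise TrajectoryError("body_length_mm must be positive")

    @property
    def trial_id(self) -> str:
        return self.leader.trial_id

    @property
    def frame_rate(self) -> float:
        return self.leader.frame_rate

    def __len__(self) -> int:
        return len(self.leader)


@dataclass(frozen=True)
class Dataset:
    """All tandem-run pairs of one species."""

    pairs: tuple[TandemPair, ...]
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        for p in self.pairs:
            if p.species and self.species and p.species != self.species:
                raise TrajectoryError(
                    f"pair {p.trial_id!r} species {p.species!r} != dataset {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def map_pairs(self, fn) -> "Dataset":
        """Apply ``fn`` to both trajectories of every pair, keeping alignment."""
        new = []
        for p in self.pairs:
            new.append(replace(p, leader=fn(p.leader), follower=fn(p.follower)))
        return Dataset(tuple(new), species=self.species)


# ---------------------------------------------------------------------------
# I/O

REQUIRED_COLUMNS = ("trial_id", "role", "frame", "x", "y")


def read_pairs(
    path,
    scale_mm_per_px: float = 1.0,
    frame_rate: float = 29.97,
    species: str = "",
    body_length_mm: float | None = None,
) -> Dataset:
    """Read paired trajectories from a delimited text file.

    The file must have columns ``trial_id, role, frame, x, y`` with exactly one
    leader and one follower track per trial. Coordinates are multiplied by
    ``scale_mm_per_px``; frames must be consecutive with no gaps.
    """
    if not scale_mm_per_px > 0:
        raise ValueError("scale_mm_per_px must be positive")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"missing columns: {missing}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.loc[coerced.isna(), col].iloc[0]
            raise TrajectoryError(f"non-numeric coordinate {bad!r} in column {col}")
        df[col] = coerced
    if df[["x", "y"]].isna().any().any():
        raise TrajectoryError("missing coordinate value")

    pairs = []
    for trial_id, trial_df in df.groupby("trial_id", sort=True):
        tracks: dict[str, RawTrajectory] = {}
        for role, track in trial_df.groupby("role"):
            if role not in ROLES:
                raise TrajectoryError(f"trial {trial_id!r}: unknown role {role!r}")
            track = track.sort_values("frame")
            frames = track["frame"].to_numpy()
            if len(frames) != len(np.unique(frames)):
                raise TrajectoryError(f"trial {trial_id!r}: duplicate frames for {role}")
            if np.any(np.diff(frames) != 1):
                raise TrajectoryError(
                    f"trial {trial_id!r}: non-consecutive frames for {role} "
                    "(gaps are not interpolated)"
                )
            pos = track[["x", "y"]].to_numpy(dtype=float) * scale_mm_per_px
            tracks[role] = RawTrajectory(str(trial_id), role, pos, frame_rate)
        if set(tracks) != set(ROLES):
            raise TrajectoryError(
                f"trial {trial_id!r}: need exactly one leader and one follower, "
                f"got roles {sorted(tracks)}"
            )
        kwargs = {} if body_length_mm is None else {"body_length_mm": body_length_mm}
        pairs.append(
            TandemPair(tracks[LEADER], tracks[FOLLOWER], species=species, **kwargs)
        )
    return Dataset(tuple(pairs), species=species)


def write_pairs(dataset: Dataset, path) -> None:
    """Write a dataset back to the same CSV dialect, coordinates in mm."""
    rows = []
    for pair in dataset:
        for traj in (pair.leader, pair.follower):
            for i, (x, y) in enumerate(traj.positions):
                rows.append((traj.trial_id, traj.role, i, x, y))
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transformations


def clip_duration(traj: RawTrajectory, duration_s: float) -> RawTrajectory:
    """Keep the first ``floor(duration_s * frame_rate)`` positions."""
    n = int(math.floor(duration_s * traj.frame_rate + 1e-9))
    if n > len(traj):
        raise TrajectoryError(
            f"requested {duration_s} s but only {traj.duration:.3f} s "
            f"({len(traj)} samples) available"
        )
    return replace(traj, positions=traj.positions[:n])


def subsample(traj: RawTrajectory, period_s: float) -> RawTrajectory:
    """Retain every n-th position, ``n = round(period_s * frame_rate)``.

    Keeps frames ``n, 2n, 3n, ... <= N`` (1-based), so the result has
    ``floor(N / n)`` positions and an effective frame rate ``frame_rate / n``.
    """
    n = int(round(period_s * traj.frame_rate))
    if n < 1:
        raise TrajectoryError(
            f"period {period_s} s is below the native frame interval "
            f"{1.0 / traj.frame_rate:.6f} s"
        )
    if n == 1:
        return traj
    return replace(
        traj,
        positions=traj.positions[n - 1 :: n],
        frame_rate=traj.frame_rate / n,
    )


def expected_sample_count(duration_s: float, period_s: float) -> int:
    """Sample count implied by a printed (rounded) sampling period.

    ``floor(duration_s / period_s)`` — the convention under which a 15-min
    recording yields 599 samples at a 1.5015 s period and 5395 at 0.1668 s.
    """
    return int(math.floor(duration_s / period_s))


def prepare_dataset(
    dataset: Dataset, duration_s: float | None = None, period_s: float | None = None
) -> Dataset:
    """Clip every pair to ``duration_s`` then subsample to ``period_s``."""
    out = dataset
    if duration_s is not None:
        out = out.map_pairs(lambda t: clip_duration(t, duration_s))
    if period_s is not None:
        out = out.map_pairs(lambda t: subsample(t, period_s))
    return out
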