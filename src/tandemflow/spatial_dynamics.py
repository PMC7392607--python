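"""Distance- and speed-resolved views of local information flow.

Local transfer entropy tells us, step by step, when the sender's present
state is informative about the receiver's next move. Conditioning it on the
instantaneous leader-follower separation (in body lengths) reveals *where*
each channel operates: e.g. turn information dominating at close range and
pause information at larger separations. Profiles are binned means over
0.1-body-length bins followed by LOESS smoothing (default span 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .infodyn import LocalTESeries
from .trajectory_io import TandemPair, subsample


class SpatialError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceSeries:
    """Per-time-step inter-centroid distance for one trial."""

    values_mm: np.ndarray
    body_length_mm: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values_mm, dtype=float)
        if np.any(v <= 0):
            raise SpatialError(
                f"trial {self.trial_id!r}: non-positive inter-centroid distance "
                "(centroids of distinct bodies never coincide)"
            )
        object.__setattr__(self, "values_mm", v)

    @property
    def values_bl(self) -> np.ndarray:
        return self.values_mm / self.body_length_mm

    def __len__(self) -> int:
        return self.values_mm.size


def pair_distance(pair: TandemPair, period_s: float | None = None) -> DistanceSeries:
    """Euclidean leader-follower distance at every (subsampled) time step."""
    leader, follower = pair.leader, pair.follower
    if period_s is not None:
        leader = subsample(leader, period_s)
        follower = subsample(follower, period_s)
    d = np.linalg.norm(leader.positions - follower.positions, axis=1)
    return DistanceSeries(d, pair.body_length_mm, pair.trial_id)


@dataclass(frozen=True)
class BinnedProfile:
    """A signal averaged within distance bins, with a smoothed overlay."""

    bin_centers_bl: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    smoothed: np.ndarray
    span: float

    def overall_mean(self) -> float:
        """Count-weighted mean over bins (equals the unconditioned mean)."""
        return float((self.mean * self.count).sum() / self.count.sum())


def _bin_profile(dist_bl: np.ndarray, signal: np.ndarray, span: float,
                 bin_width_bl: float) -> BinnedProfile:
    if dist_bl.size != signal.size:
        raise SpatialError(
            f"length mismatch: {dist_bl.size} distances vs {signal.size} values"
        )
    if dist_bl.size == 0:
        raise SpatialError("empty profile input")
    lo = np.floor(dist_bl.min() / bin_width_bl) * bin_width_bl
    hi = np.ceil(dist_bl.max() / bin_width_bl) * bin_width_bl
    n_bins = max(1, int(round((hi - lo) / bin_width_bl)))
    edges = lo + np.arange(n_bins + 1) * bin_width_bl
    idx = np.clip(np.digitize(dist_bl, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins).astype(float)
    total = np.bincount(idx, weights=signal, minlength=n_bins)
    occupied = count > 0
    centers = (edges[:-1] + edges[1:]) / 2.0
    centers, count, total = centers[occupied], count[occupied], total[occupied]
    mean = total / count
    if centers.size >= 3 and span > 0:
        smoothed = lowess(mean, centers, frac=min(1.0, span), return_sorted=False)
    else:
        smoothed = mean.copy()
    return BinnedProfile(centers, mean, count, smoothed, span)


def local_te_by_distance(
    local: LocalTESeries,
    distances: list[DistanceSeries],
    span: float = 0.3,
    bin_width_bl: float = 0.1,
) -> BinnedProfile:
    """Mean local TE conditioned on leader-follower distance.

    Each trial's distance series is aligned to its local-TE array by dropping
    leading entries (local values start k steps in, plus any encoder offset);
    the distance paired with a local value is the separation at the step
    whose transition the value scores.
    """
    if len(distances) != len(local.per_trial):
        raise SpatialError("one distance series per local-TE trial required")
    dist_all, val_all = [], []
    for dist, vals in zip(distances, local.per_trial):
        if vals.size == 0:
            continue
        if len(dist) < vals.size:
            raise SpatialError(
                f"trial {dist.trial_id!r}: {len(dist)} distances cannot align "
                f"with {vals.size} local-TE values"
            )
        if len(dist) > vals.size:
            aligned = dist.values_bl[len(dist) - vals.size - 1 : len(dist) - 1]
        else:
            aligned = dist.values_bl
        dist_all.append(aligned)
        val_all.append(vals)
    return _bin_profile(np.concatenate(dist_all), np.concatenate(val_all),
                        span, bin_width_bl)


def _classify_distance_change(dist: np.ndarray) -> np.ndarray:
    """Per-step +1 (increasing) / -1 (decreasing); zero change joins the previous class."""
    delta = np.sign(np.diff(dist))
    nz = np.flatnonzero(delta)
    if nz.size == 0:
        return np.ones_like(delta)  # degenerate: constant separation
    idx = np.arange(delta.size)
    last = np.maximum.accumulate(np.where(delta != 0, idx, -1))
    last[last < 0] = nz[0]
    return delta[last]


def speed_vs_distance(
    pair: TandemPair,
    period_s: float | None = None,
    span: float = 0.3,
    bin_width_bl: float = 0.1,
) -> dict[tuple[str, str], BinnedProfile]:
    """Speed of each runner vs separation, split by closing/opening distance.

    Returns profiles keyed by (role, "increasing"|"decreasing"). Speed is the
    step size divided by the sampling period; each step is classified by the
    sign of the distance change over that step.
    """
    leader, follower = pair.leader, pair.follower
    if period_s is not None:
        leader = subsample(leader, period_s)
        follower = subsample(follower, period_s)
    if len(leader) < 3:
        raise SpatialError("need at least 3 time steps")
    dt = 1.0 / leader.frame_rate
    dist = np.linalg.norm(leader.positions - follower.positions, axis=1)
    dist_bl = dist / pair.body_length_mm
    cls = _classify_distance_change(dist)
    out: dict[tuple[str, str], BinnedProfile] = {}
    for traj in (leader, follower):
        speed = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) / dt
        for label, sign in (("increasing", 1), ("decreasing", -1)):
            mask = cls == sign
            if not mask.any():
                continue
            out[(traj.role, label)] = _bin_profile(
                dist_bl[:-1][mask], speed[mask], span, bin_width_bl
            )
    return out
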