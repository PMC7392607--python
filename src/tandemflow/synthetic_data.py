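"""Coupled leader-follower walker simulation with known information flow.

Generates tandem-run-like trajectory pairs under three communication
protocols whose ground-truth flow directions are fixed by construction, so
every stage of the analysis pipeline can be validated without recordings:

``ant``
    The leader performs a persistent turning walk and demonstrates the
    route: its turn history drives the pursuing follower's heading
    (rotation flow leader -> follower). The *follower* initiates search
    pauses; the resulting separation makes the leader stop once the gap
    exceeds ``d_stop_bl`` body lengths and resume below ``d_go_bl``, so the
    follower's stop-go state temporally precedes and predicts the leader's
    (pausing flow follower -> leader).
``termite``
    Same pursuit, but pauses are initiated spontaneously by the leader; the
    follower simply runs out of road when it catches the stopped leader, so
    both rotation and pausing flow leader -> follower.
``independent``
    Two uncoupled persistent walkers with spontaneous pauses: no flow in
    either direction (surrogate-corrected net TE ~ 0).

Speeds are mm/s and event rates are events/s, converted internally by the
frame interval, so a protocol behaves the same whether rendered at the full
29.97 Hz of the recordings or at a reduced rate for quick experiments.
Pause bouts have geometric (per-frame) durations. A small isotropic
positional jitter emulates centroid-tracking noise and gives the step-size
distribution its bimodal pause/motion shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory_io import Dataset, RawTrajectory, TandemPair

MODES = ("ant", "termite", "independent")


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolConfig:
    """Generative parameters of a leader-follower communication protocol."""

    mode: str
    seed: int = 0
    # kinematics
    leader_speed_mm_s: float = 2.0
    follower_speed_mm_s: float = 3.0
    turn_rate_deg_s: float = 40.0  # magnitude of the leader's heading drift
    turn_switch_rate_s: float = 0.25  # CW/CCW Markov-chain switch rate
    heading_noise_deg: float = 12.0  # follower pursuit noise (per step, deg)
    leader_heading_noise_deg: float = 8.0
    # pausing protocol
    follower_pause_rate_s: float = 0.08  # search-pause starts/s (ant mode)
    leader_spontaneous_pause_rate_s: float = 0.08  # (termite/independent)
    pause_duration_mean_s: float = 2.5
    d_stop_bl: float = 3.0  # leader stops when gap exceeds this (ant mode)
    d_go_bl: float = 1.2  # ... and resumes below this
    contact_bl: float = 0.5  # follower stops short of the leader's centroid
    # geometry & sampling
    body_length_mm: float = 2.34
    arena_mm: tuple[float, float] = (370.0, 655.0)
    frame_rate: float = 29.97
    duration_s: float = 900.0
    tracking_noise_mm: float = 0.03

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SyntheticError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("leader_speed_mm_s", "follower_speed_mm_s", "body_length_mm",
                     "frame_rate", "duration_s", "pause_duration_mean_s"):
            if not getattr(self, name) > 0:
                raise SyntheticError(f"{name} must be positive")
        if not self.d_go_bl < self.d_stop_bl:
            raise SyntheticError("d_go_bl must be smaller than d_stop_bl")
        dt = 1.0 / self.frame_rate
        for name in ("follower_pause_rate_s", "leader_spontaneous_pause_rate_s",
                     "turn_switch_rate_s"):
            if not 0 <= getattr(self, name) * dt <= 1:
                raise SyntheticError(f"{name} out of range for this frame rate")


def ant_config(**overrides) -> ProtocolConfig:
    """Route-demonstration protocol (rotation L->F, pausing F->L)."""
    return ProtocolConfig(mode="ant", **overrides)


def termite_config(**overrides) -> ProtocolConfig:
    """Cohesion protocol (rotation and pausing both L->F)."""
    defaults = dict(
        body_length_mm=8.89,
        leader_speed_mm_s=10.0,
        follower_speed_mm_s=14.0,
        arena_mm=(145.0, 145.0),
        leader_spontaneous_pause_rate_s=0.10,
        pause_duration_mean_s=1.5,
    )
    defaults.update(overrides)
    return ProtocolConfig(mode="termite", **defaults)


def independent_config(**overrides) -> ProtocolConfig:
    """Uncoupled walkers: no information flow in either direction."""
    return ProtocolConfig(mode="independent", **overrides)


@dataclass(frozen=True)
class GroundTruth:
    """Expected sign of net TE (leader->follower positive) per pattern."""

    rotation_sign: int
    pausing_sign: int


def ground_truth(config: ProtocolConfig) -> GroundTruth:
    if config.mode == "ant":
        return GroundTruth(rotation_sign=+1, pausing_sign=-1)
    if config.mode == "termite":
        return GroundTruth(rotation_sign=+1, pausing_sign=+1)
    return GroundTruth(rotation_sign=0, pausing_sign=0)


# ---------------------------------------------------------------------------
# Simulation


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] (reflective arena wall)."""
    if value < lo:
        return 2 * lo - value
    if value > hi:
        return 2 * hi - value
    return value


def simulate_pair(config: ProtocolConfig, trial_id: str = "synthetic-0") -> TandemPair:
    """Simulate one leader-follower pair; bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    n = int(round(config.duration_s * config.frame_rate))
    bl = config.body_length_mm
    margin = 2.0 * bl
    w, h = config.arena_mm

    # pre-drawn randomness (one block per consumer keeps the loop cheap)
    u_switch = rng.random(n)
    u_pause_start = rng.random(n)
    u_pause_end = rng.random(n)
    u_f_switch = rng.random(n)
    u_f_pause_start = rng.random(n)
    u_f_pause_end = rng.random(n)
    g_leader = rng.standard_normal(n)
    g_follower = rng.standard_normal(n)
    jitter = rng.standard_normal((n, 4)) * config.tracking_noise_mm

    p_switch = config.turn_switch_rate_s * dt
    p_l_pause = config.leader_spontaneous_pause_rate_s * dt
    p_f_pause = config.follower_pause_rate_s * dt
    p_pause_end = min(1.0, dt / config.pause_duration_mean_s)
    turn_step = math.radians(config.turn_rate_deg_s) * dt
    l_noise = math.radians(config.leader_heading_noise_deg)
    f_noise = math.radians(config.heading_noise_deg)
    l_step = config.leader_speed_mm_s * dt
    f_step = config.follower_speed_mm_s * dt
    contact = config.contact_bl * bl

    # initial state: follower one body length behind the leader
    lx, ly = w / 2.0, h / 2.0
    heading = rng.uniform(0, 2 * math.pi)
    fx = lx - bl * math.cos(heading)
    fy = ly - bl * math.sin(heading)
    f_heading = heading
    turn_sign = 1 if rng.random() < 0.5 else -1
    f_turn_sign = 1 if rng.random() < 0.5 else -1
    leader_paused = False
    follower_paused = False

    independent = config.mode == "independent"
    lead_pos = np.empty((n, 2))
    foll_pos = np.empty((n, 2))

    for i in range(n):
        # -- leader turn chain and heading
        if u_switch[i] < p_switch:
            turn_sign = -turn_sign
        heading += turn_sign * turn_step + g_leader[i] * l_noise

        dist = math.hypot(lx - fx, ly - fy)

        # -- leader pause protocol
        if config.mode == "ant":
            if leader_paused:
                if dist < config.d_go_bl * bl:
                    leader_paused = False
            elif dist > config.d_stop_bl * bl:
                leader_paused = True
        else:  # termite & independent: spontaneous, geometric duration
            if leader_paused:
                if u_pause_end[i] < p_pause_end:
                    leader_paused = False
            elif u_pause_start[i] < p_l_pause:
                leader_paused = True

        if not leader_paused:
            lx += l_step * math.cos(heading)
            ly += l_step * math.sin(heading)
            nlx = _reflect(lx, margin, w - margin)
            nly = _reflect(ly, margin, h - margin)
            if nlx != lx or nly != ly:
                lx, ly = nlx, nly
                heading = math.atan2(h / 2.0 - ly, w / 2.0 - lx)

        # -- follower
        if independent:
            # uncoupled persistent walker with its own spontaneous pauses
            if follower_paused:
                if u_f_pause_end[i] < p_pause_end:
                    follower_paused = False
            elif u_f_pause_start[i] < p_l_pause:
                follower_paused = True
            if u_f_switch[i] < p_switch:
                f_turn_sign = -f_turn_sign
            f_heading += f_turn_sign * turn_step + g_follower[i] * f_noise
            if not follower_paused:
                fx += f_step * math.cos(f_heading)
                fy += f_step * math.sin(f_heading)
                nfx = _reflect(fx, margin, w - margin)
                nfy = _reflect(fy, margin, h - margin)
                if nfx != fx or nfy != fy:
                    fx, fy = nfx, nfy
                    f_heading = math.atan2(h / 2.0 - fy, w / 2.0 - fx)
        else:
            if config.mode == "ant":
                if follower_paused:
                    if u_f_pause_end[i] < p_pause_end:
                        follower_paused = False
                elif u_f_pause_start[i] < p_f_pause:
                    follower_paused = True
            else:
                follower_paused = False
            if not follower_paused:
                f_heading = math.atan2(ly - fy, lx - fx) + g_follower[i] * f_noise
                gap = math.hypot(lx - fx, ly - fy)
                advance = min(f_step, max(0.0, gap - contact))
                fx += advance * math.cos(f_heading)
                fy += advance * math.sin(f_heading)

        lead_pos[i, 0] = lx + jitter[i, 0]
        lead_pos[i, 1] = ly + jitter[i, 1]
        foll_pos[i, 0] = fx + jitter[i, 2]
        foll_pos[i, 1] = fy + jitter[i, 3]

    species = f"synthetic-{config.mode}"
    leader = RawTrajectory(trial_id, "leader", lead_pos, config.frame_rate)
    follower = RawTrajectory(trial_id, "follower", foll_pos, config.frame_rate)
    return TandemPair(leader, follower, species=species, body_length_mm=bl)


def pair_seed(master_seed: int, index: int) -> int:
    """Derived per-pair seed: ``(master * 1000003 + index) mod 2**31``.

    A fixed prime-stride counter scheme: deterministic, collision-free for
    any realistic dataset size, and bounded below 2**31.
    """
    return (int(master_seed) * 1_000_003 + int(index)) % (2**31)


def simulate_dataset(config: ProtocolConfig, n_pairs: int = 20) -> Dataset:
    """Simulate ``n_pairs`` independent pairs with seeds derived from the master.

    Pair ``i`` uses seed ``pair_seed(config.seed, i)``, so any pair can be
    re-simulated in isolation.
    """
    if n_pairs < 2:
        raise SyntheticError("need at least 2 pairs (surrogates require a derangement)")
    pairs = []
    for i in range(n_pairs):
        cfg = replace(config, seed=pair_seed(config.seed, i))
        pairs.append(simulate_pair(cfg, trial_id=f"synthetic-{i:03d}"))
    return Dataset(tuple(pairs), species=f"synthetic-{config.mode}")
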