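"""Headless multi-agent herding-game simulator with scripted player policies.

The environment is a square desert arena in which three player avatars
must locate, corral, and contain a set of autonomous target agents (TAs)
inside a small central containment disc.  TAs are unit point masses driven
by a piecewise-constant Brownian forcing (a random force resampled once
per simulated second), a short-range repulsion from nearby avatars that
falls off as the inverse of distance, and a linear drag; their speed is
capped.  Avatars move kinematically at a fixed fast or slow speed and
carry an independently controlled head-orientation channel.

A trial succeeds when every TA has been inside the containment disc
continuously for ``success_hold`` seconds; otherwise it fails when the
clock reaches ``trial_max`` and its duration is recorded at that ceiling.

Scripted policies stand in for human players.  They observe either the
full world state (global-information HUD emulation) or only entities
within a sensing radius (fog / compass emulation), and combine three
behaviors: *search* (sector-partitioned sweep, shared sweep, or random
walk), *corral* (move to the far side of a target relative to the
containment disc and push it inward), and *guard* (hold a post near the
disc and intercept escapees).  Head orientation is the movement heading
plus a sinusoidal scan and Gaussian noise.  Policies are explicitly
synthetic: they emulate the study conditions, not any particular human
strategy.

All randomness flows from a single root seed through named substreams
(spawn, Brownian forcing, one per policy), so a trial is bit-reproducible
from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "WorldConfig",
    "PolicyConfig",
    "WorldState",
    "TrialLog",
    "STATUS_LABELS",
    "IDLE",
    "FLEEING",
    "CONTAINED",
    "ALL_CONTAINED",
    "STRATEGIES",
    "sample_brownian_force",
    "repulsion_force",
    "step_world",
    "update_statuses",
    "policy_observe",
    "policy_act",
    "make_policy_state",
    "spawn_positions",
    "run_trial",
]

# TA status codes, ordered by display precedence (contained overrides fleeing).
IDLE, FLEEING, CONTAINED, ALL_CONTAINED = 0, 1, 2, 3
STATUS_LABELS = ("idle", "fleeing", "contained", "all_contained")

STRATEGIES = ("partitioned_sweep", "shared_sweep", "random_walk", "corral_nearest")

#: Golden-angle increment used by the deterministic sweep waypoint spiral.
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldConfig:
    """Physics, arena, and trial parameters.

    Defaults reproduce the study conditions: a 500 x 500 m arena with a
    10 m diameter containment disc at its center, 9 or 18 unit-mass TAs
    kicked by a force uniform on [0, 60] N in a uniform direction at 1 Hz,
    avatar repulsion within 10 m with magnitude ``min(450, 450/d)`` N,
    10 m/s speed caps, 90 Hz physics and logging, a 300 s trial ceiling,
    and a 5 s continuous containment requirement for success.
    """

    arena_side: float = 500.0
    containment_center: tuple[float, float] = (250.0, 250.0)
    containment_diameter: float = 10.0
    n_targets: int = 9
    ta_mass: float = 1.0
    brownian_force_max: float = 60.0
    brownian_rate: float = 1.0
    repulsion_radius: float = 10.0
    repulsion_force_max: float = 450.0
    repulsion_constant: float = 450.0  # N*m; magnitude = min(cap, constant/d)
    ta_speed_max: float = 10.0
    avatar_speed: float = 10.0
    avatar_speed_slow: float = 5.0
    player_spawn_radius: float = 100.0
    ta_spawn_radius: float = 180.0
    trial_max: float = 300.0
    success_hold: float = 5.0
    physics_hz: int = 90
    log_hz: int = 90
    # Linear drag force -gamma * v (gamma in N*s/m).  The default gives a
    # 0.1 s velocity relaxation time: unforced TAs roam diffusively at a
    # few m/s while fleeing TAs still reach the 10 m/s cap, which keeps
    # the containment task demanding but winnable.
    drag_coefficient: float = 10.0

    def __post_init__(self) -> None:
        positive = (
            "arena_side",
            "containment_diameter",
            "ta_mass",
            "brownian_rate",
            "repulsion_radius",
            "repulsion_force_max",
            "repulsion_constant",
            "ta_speed_max",
            "avatar_speed",
            "avatar_speed_slow",
            "player_spawn_radius",
            "ta_spawn_radius",
            "trial_max",
            "success_hold",
            "physics_hz",
            "log_hz",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.brownian_force_max < 0:
            raise ValueError("brownian_force_max must be non-negative")
        if self.drag_coefficient < 0:
            raise ValueError("drag_coefficient must be non-negative")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not self.avatar_speed_slow < self.avatar_speed:
            raise ValueError("avatar_speed_slow must be < avatar_speed")
        if not self.success_hold < self.trial_max:
            raise ValueError("success_hold must be < trial_max")
        if not self.containment_diameter < self.ta_spawn_radius:
            raise ValueError("containment_diameter must be < ta_spawn_radius")
        if self.physics_hz % self.log_hz != 0:
            raise ValueError("physics_hz must be an integer multiple of log_hz")

    @property
    def containment_radius(self) -> float:
        return self.containment_diameter / 2.0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["containment_center"] = list(self.containment_center)
        return d


@dataclass(frozen=True)
class PolicyConfig:
    """Sensing and strategy parameters of one scripted player.

    ``sense_radius`` emulates the visibility manipulation (about 10 m
    under fog, 150 m or more under clear skies); ``global_info`` emulates
    the HUD that reveals every avatar and TA regardless of distance.  The
    containment disc is always known: both the global HUD and the compass
    display its location as a landmark.

    The head-orientation channel is the movement heading plus a sinusoidal
    scan of amplitude ``scan_amplitude`` and period ``scan_period`` plus
    Gaussian noise with SD ``heading_noise_sd`` — a synthetic stand-in for
    mouse-driven visual scanning.

    ``decision_hz`` is the rate at which the policy recomputes its
    control; between decisions the control is held, mimicking the
    coarser-than-frame-rate cadence of human steering.
    """

    strategy: str = "partitioned_sweep"
    sense_radius: float = 150.0
    global_info: bool = True
    scan_amplitude: float = 0.6
    scan_period: float = 2.0
    heading_noise_sd: float = 0.05
    decision_hz: float = 15.0
    corral_standoff: float = 2.5  # m behind the target along the outward ray
    waypoint_tolerance: float = 5.0
    avoid_radius: float = 11.0  # keep clear of targets while repositioning

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if not self.sense_radius > 0:
            raise ValueError("sense_radius must be strictly positive")
        if not self.scan_period > 0:
            raise ValueError("scan_period must be strictly positive")
        if self.scan_amplitude < 0 or self.heading_noise_sd < 0:
            raise ValueError("scan_amplitude and heading_noise_sd must be >= 0")
        if not self.decision_hz > 0:
            raise ValueError("decision_hz must be strictly positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------


@dataclass
class WorldState:
    """Mutable simulation state (arrays, not per-entity objects)."""

    t: float
    ta_pos: np.ndarray  # (k, 2) m
    ta_vel: np.ndarray  # (k, 2) m/s
    ta_brownian: np.ndarray  # (k, 2) N, current 1 s force sample
    ta_status: np.ndarray  # (k,) int codes
    avatar_pos: np.ndarray  # (3, 2) m
    avatar_heading: np.ndarray  # (3,) rad in (-pi, pi]
    avatar_slow: np.ndarray  # (3,) bool

    def copy(self) -> "WorldState":
        return WorldState(
            t=self.t,
            ta_pos=self.ta_pos.copy(),
            ta_vel=self.ta_vel.copy(),
            ta_brownian=self.ta_brownian.copy(),
            ta_status=self.ta_status.copy(),
            avatar_pos=self.avatar_pos.copy(),
            avatar_heading=self.avatar_heading.copy(),
            avatar_slow=self.avatar_slow.copy(),
        )


@dataclass
class TrialLog:
    """Time-indexed multi-agent trajectory record of one trial.

    ``time`` has one entry per logged sample; player and TA tracks share
    that length.  ``duration`` equals ``trial_max`` for failed trials.
    """

    sample_rate: float
    time: np.ndarray  # (n,)
    player_pos: np.ndarray  # (n, 3, 2)
    player_heading: np.ndarray  # (n, 3)
    ta_pos: np.ndarray  # (n, k, 2)
    ta_status: np.ndarray  # (n, k) int codes
    outcome: str  # "success" | "fail"
    duration: float
    seed: int | None = None
    condition: dict[str, Any] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.time.shape[0])

    @property
    def n_players(self) -> int:
        return int(self.player_pos.shape[1])

    @property
    def n_targets(self) -> int:
        return int(self.ta_pos.shape[1])

    def validate(self) -> None:
        n = self.n_samples
        for name in ("player_pos", "player_heading", "ta_pos", "ta_status"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"track {name!r} length mismatch with time")
        if self.outcome not in ("success", "fail"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


# ---------------------------------------------------------------------------
# Physics primitives
# ---------------------------------------------------------------------------


def sample_brownian_force(
    rng: np.random.Generator, force_max: float = 60.0, size: int | None = None
) -> np.ndarray:
    """Random planar force: magnitude ~ U(0, force_max), direction ~ U(0, 2*pi).

    With ``size`` given, returns ``(size, 2)`` independent draws (one per
    TA); otherwise a single ``(2,)`` vector.  The caller holds each draw
    constant for one Brownian-rate period of simulated time.
    """
    k = 1 if size is None else size
    mag = rng.uniform(0.0, force_max, size=k)
    ang = rng.uniform(0.0, 2.0 * np.pi, size=k)
    out = np.column_stack((mag * np.cos(ang), mag * np.sin(ang)))
    return out[0] if size is None else out


def repulsion_force(
    ta_position: np.ndarray, avatar_position: np.ndarray, config: WorldConfig
) -> np.ndarray:
    """Avatar-to-TA repulsion, inverse in distance and capped.

    Zero beyond ``repulsion_radius``; otherwise directed from the avatar
    toward the TA with magnitude ``min(repulsion_force_max,
    repulsion_constant / d)``.  At exactly zero distance the direction is
    degenerate; the cap magnitude is returned along +x as a deterministic
    fallback.
    """
    delta = np.asarray(ta_position, dtype=float) - np.asarray(avatar_position, dtype=float)
    d = float(np.hypot(delta[0], delta[1]))
    if d > config.repulsion_radius:
        return np.zeros(2)
    if d == 0.0:
        return np.array([config.repulsion_force_max, 0.0])
    mag = min(config.repulsion_force_max, config.repulsion_constant / d)
    return (mag / d) * delta


def _total_repulsion(
    ta_pos: np.ndarray, avatar_pos: np.ndarray, config: WorldConfig
) -> np.ndarray:
    """Summed repulsion from all avatars on every TA, vectorized: (k, 2)."""
    delta = ta_pos[:, None, :] - avatar_pos[None, :, :]  # (k, a, 2)
    d = np.sqrt(delta[..., 0] ** 2 + delta[..., 1] ** 2)  # (k, a)
    return _repulsion_from(delta, d, config)


def _repulsion_from(delta: np.ndarray, d: np.ndarray, config: WorldConfig) -> np.ndarray:
    """Repulsion sum given precomputed TA-avatar offsets and distances."""
    with np.errstate(divide="ignore"):
        mag = np.minimum(config.repulsion_force_max, config.repulsion_constant / d)
    mag = np.where(d > config.repulsion_radius, 0.0, mag)
    zero = d == 0.0
    if np.any(zero):
        delta[zero] = (1.0, 0.0)
        d = np.where(zero, 1.0, d)
        mag = np.where(zero, config.repulsion_force_max, mag)
    return np.sum(delta * (mag / d)[..., None], axis=1)


def update_statuses(
    state: WorldState, config: WorldConfig, _d_av: np.ndarray | None = None
) -> WorldState:
    """Recompute TA status codes in place (state is also returned).

    A TA is *fleeing* when any avatar is within the repulsion radius,
    *contained* when inside the closed containment disc (containment takes
    precedence over fleeing), and every status becomes *all_contained*
    when the whole set is contained.  ``_d_av`` lets the stepper reuse its
    TA-avatar distance matrix.
    """
    center = np.asarray(config.containment_center)
    diff = state.ta_pos - center
    d_center = np.sqrt(diff[:, 0] ** 2 + diff[:, 1] ** 2)
    contained = d_center <= config.containment_radius
    if _d_av is None:
        delta = state.ta_pos[:, None, :] - state.avatar_pos[None, :, :]
        _d_av = np.sqrt(delta[..., 0] ** 2 + delta[..., 1] ** 2)
    fleeing = np.any(_d_av <= config.repulsion_radius, axis=1)
    status = np.full(state.ta_pos.shape[0], IDLE, dtype=np.int8)
    status[fleeing] = FLEEING
    status[contained] = CONTAINED
    if np.all(contained):
        status[:] = ALL_CONTAINED
    state.ta_status = status
    return state


def _clamp_to_arena(pos: np.ndarray, vel: np.ndarray | None, side: float) -> None:
    """Clamp positions to [0, side]^2 in place, zeroing outward velocity."""
    if pos.min() >= 0.0 and pos.max() <= side:  # common case: fully inside
        return
    for axis in (0, 1):
        low = pos[:, axis] < 0.0
        high = pos[:, axis] > side
        if np.any(low):
            pos[low, axis] = 0.0
            if vel is not None:
                vel[low, axis] = np.maximum(vel[low, axis], 0.0)
        if np.any(high):
            pos[high, axis] = side
            if vel is not None:
                vel[high, axis] = np.minimum(vel[high, axis], 0.0)


def step_world(
    state: WorldState,
    controls: list[dict[str, Any]],
    config: WorldConfig,
    dt: float | None = None,
) -> WorldState:
    """Advance the world one physics step (semi-implicit Euler) in place.

    TA velocities integrate (brownian + repulsion - drag) / mass, are
    rescaled onto the speed cap, and positions advance with the updated
    velocity.  Avatars move kinematically at the fast or slow speed along
    the commanded direction; their headings are set from the controls.
    Positions are clamped to the arena with the outward velocity component
    zeroed, and statuses are refreshed.
    """
    if dt is None:
        dt = 1.0 / config.physics_hz

    delta = state.ta_pos[:, None, :] - state.avatar_pos[None, :, :]  # (k, a, 2)
    d_av = np.sqrt(delta[..., 0] ** 2 + delta[..., 1] ** 2)
    force = state.ta_brownian - config.drag_coefficient * state.ta_vel
    if d_av.min() <= config.repulsion_radius:
        force = force + _repulsion_from(delta, d_av, config)
    state.ta_vel += (dt / config.ta_mass) * force
    speed_sq = state.ta_vel[:, 0] ** 2 + state.ta_vel[:, 1] ** 2
    cap_sq = config.ta_speed_max**2
    if speed_sq.max() > cap_sq:
        over = speed_sq > cap_sq
        state.ta_vel[over] *= (config.ta_speed_max / np.sqrt(speed_sq[over]))[:, None]
    state.ta_pos += state.ta_vel * dt
    _clamp_to_arena(state.ta_pos, state.ta_vel, config.arena_side)

    for i, ctrl in enumerate(controls):
        move = ctrl["move_dir"]
        norm = math.hypot(move[0], move[1])
        if norm > 0.0:
            speed_i = config.avatar_speed_slow if ctrl.get("slow", False) else config.avatar_speed
            scale = speed_i * dt / norm
            state.avatar_pos[i, 0] += scale * move[0]
            state.avatar_pos[i, 1] += scale * move[1]
        state.avatar_heading[i] = _wrap_scalar(float(ctrl["head"]))
        state.avatar_slow[i] = bool(ctrl.get("slow", False))
    _clamp_to_arena(state.avatar_pos, None, config.arena_side)

    state.t += dt
    checksum = float(state.ta_pos.sum() + state.ta_vel.sum() + state.avatar_pos.sum())
    if not math.isfinite(checksum):
        raise FloatingPointError(
            f"non-finite simulation state at t={state.t:.3f}s; "
            "check forces and configuration"
        )
    return update_statuses(state, config)


def _wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Map angle(s) to (-pi, pi]."""
    out = np.mod(a, 2.0 * np.pi)
    out = np.where(out > np.pi, out - 2.0 * np.pi, out)
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out


def _wrap_scalar(a: float) -> float:
    """Scalar fast path of :func:`_wrap_angle`."""
    a = math.fmod(a, 2.0 * math.pi)
    if a > math.pi:
        a -= 2.0 * math.pi
    elif a <= -math.pi:
        a += 2.0 * math.pi
    return a


# ---------------------------------------------------------------------------
# Spawning
# ---------------------------------------------------------------------------


def spawn_positions(
    rng: np.random.Generator, center: np.ndarray, radius: float, count: int
) -> np.ndarray:
    """Area-uniform positions on a disc: r = R * sqrt(u), angle uniform."""
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, size=count))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=count)
    return np.asarray(center, dtype=float) + np.column_stack(
        (r * np.cos(theta), r * np.sin(theta))
    )


# ---------------------------------------------------------------------------
# Scripted policies
# ---------------------------------------------------------------------------


def make_policy_state(config: PolicyConfig, player_index: int) -> dict[str, Any]:
    """Fresh per-player policy state (waypoint progress, cached control)."""
    return {
        "config": config,
        "player_index": player_index,
        "waypoint": None,
        "waypoint_index": player_index if config.strategy == "random_walk" else 0,
        "waypoint_deadline": 0.0,
        "scan_phase": 2.0 * np.pi * player_index / 3.0,
    }


def policy_observe(
    state: WorldState,
    config: PolicyConfig,
    player_index: int,
    world_config: WorldConfig,
) -> dict[str, Any]:
    """Build one player's observation under its sensing parameters.

    With ``global_info`` every avatar and TA (position, heading, status)
    is visible.  Otherwise only entities within ``sense_radius`` of the
    player are exposed.  The containment disc's location and size are
    always included — both the HUD and the compass display it — along
    with the player's own pose and the unit bearing toward the disc.
    """
    pos = state.avatar_pos[player_index].copy()
    center = np.asarray(world_config.containment_center, dtype=float)
    to_center = center - pos
    dist_center = float(np.hypot(to_center[0], to_center[1]))
    bearing = to_center / dist_center if dist_center > 0 else np.array([1.0, 0.0])

    if config.global_info:
        ta_mask = np.ones(state.ta_pos.shape[0], dtype=bool)
        player_mask = np.ones(state.avatar_pos.shape[0], dtype=bool)
    else:
        d_ta = np.hypot(*(state.ta_pos - pos).T)
        ta_mask = d_ta <= config.sense_radius
        d_pl = np.hypot(*(state.avatar_pos - pos).T)
        player_mask = d_pl <= config.sense_radius
        player_mask[player_index] = True

    return {
        "t": state.t,
        "player_index": player_index,
        "self_pos": pos,
        "self_heading": float(state.avatar_heading[player_index]),
        "player_pos": state.avatar_pos.copy(),
        "player_mask": player_mask,
        "ta_pos": state.ta_pos.copy(),
        "ta_vel": state.ta_vel.copy(),
        "ta_status": state.ta_status.copy(),
        "ta_mask": ta_mask,
        "containment_center": center,
        "containment_radius": world_config.containment_radius,
        "containment_bearing": bearing,
        "containment_distance": dist_center,
        "n_targets": state.ta_pos.shape[0],
    }


def _spiral_waypoint(k: int, center: np.ndarray, radius: float,
                     sector: tuple[float, float] | None) -> np.ndarray:
    """Deterministic low-discrepancy sweep waypoint number ``k``.

    A golden-angle spiral covers the disc of ``radius`` around ``center``;
    with ``sector`` given, the angle is folded into that angular interval
    so a player sweeps only its own wedge.
    """
    u = (k * 0.6180339887498949) % 1.0
    r = radius * np.sqrt(0.08 + 0.92 * u)
    theta = (k * _GOLDEN_ANGLE) % (2.0 * np.pi)
    if sector is not None:
        lo, width = sector
        theta = lo + (theta / (2.0 * np.pi)) * width
    return center + r * np.array([np.cos(theta), np.sin(theta)])


def _choose_threat(
    obs: dict[str, Any], ps: dict[str, Any]
) -> int | None:
    """Pick the TA this player should corral, de-conflicting via proximity.

    Threats are visible TAs that are not contained, plus contained TAs
    drifting near the disc boundary.  When teammates are visible, each
    threat is notionally assigned to the nearest visible player; the
    player corrals the nearest threat assigned to itself, falling back to
    the nearest threat overall.  All players with global information
    compute the same assignment, so they split targets without
    communicating.
    """
    center = obs["containment_center"]
    radius = obs["containment_radius"]
    mask = obs["ta_mask"]
    status = obs["ta_status"]
    tapos = obs["ta_pos"]
    d_center = np.hypot(*(tapos - center).T)
    uncontained = mask & (d_center > radius)
    stray = mask & (d_center <= radius) & (d_center > 0.5 * radius)
    threats = np.flatnonzero(uncontained | stray)
    if threats.size == 0:
        return None

    players = obs["player_pos"][obs["player_mask"]]
    player_ids = np.flatnonzero(obs["player_mask"])
    self_id = obs["player_index"]
    d_matrix = np.hypot(
        *(tapos[threats][:, None, :] - players[None, :, :]).transpose(2, 0, 1)
    )  # (n_threats, n_visible_players)
    owners = player_ids[np.argmin(d_matrix, axis=1)]
    self_col = int(np.flatnonzero(player_ids == self_id)[0])
    mine = threats[owners == self_id]
    # Prefer escapers far from the disc being handled first among "mine".
    if mine.size > 0:
        d_self = np.hypot(*(tapos[mine] - obs["self_pos"]).T)
        return int(mine[np.argmin(d_self)])
    d_self = d_matrix[:, self_col]
    return int(threats[np.argmin(d_self)])


def _corral_goal(
    obs: dict[str, Any], ta_index: int, cfg: PolicyConfig
) -> np.ndarray:
    """Stand-off point on the far side of the target from the containment disc."""
    center = obs["containment_center"]
    ta = obs["ta_pos"][ta_index]
    outward = ta - center
    norm = float(np.hypot(outward[0], outward[1]))
    if norm < 1e-9:
        outward = -obs["containment_bearing"]
        norm = 1.0
    return ta + (cfg.corral_standoff / norm) * outward


def _corral_move(
    pos: np.ndarray, obs: dict[str, Any], cfg: PolicyConfig, threat: int
) -> tuple[np.ndarray, bool]:
    """Shepherding step toward one target: orbit behind it, then push.

    Walking straight at the stand-off point would cross the target's
    repulsion zone and shove it away from the disc, so while the player
    is not yet within the 60-degree cone behind the target (relative to
    the containment disc) it orbits the target at a safe radius; once
    behind, it drives at the stand-off point so the repulsion pushes the
    target inward.  Slow mode engages for fine control near the disc.
    """
    center = obs["containment_center"]
    radius = obs["containment_radius"]
    # Lead the target: intercept where it is heading (TA headings are on
    # the HUD), not where it is.
    ta = obs["ta_pos"][threat] + 0.2 * obs["ta_vel"][threat]
    outward = ta - center
    n = math.hypot(outward[0], outward[1])
    outward = outward / n if n > 1e-9 else -obs["containment_bearing"]
    rel = pos - ta
    d = math.hypot(rel[0], rel[1])
    if d < 1e-9:
        return outward.copy(), False
    rel_u = rel / d
    endgame = n < radius + 20.0
    # Push hard from close behind during long-range herding; near the disc
    # hang back so the (inverse-distance) repulsion nudges rather than
    # launches the target across the disc.
    standoff = 8.0 if endgame else cfg.corral_standoff
    if float(rel_u @ outward) > 0.5:  # behind the target: push
        goal = ta + standoff * outward
        direction = goal - pos
        gn = math.hypot(direction[0], direction[1])
        if gn < 0.5:  # at the stand-off point: press on the target
            direction, gn = ta - pos, d
        # Slow only for the final fine positioning; dashing to the push
        # point must stay at full speed or escapees outrun the guard.
        return direction / gn, endgame and gn < 3.0
    # Orbit at the avoidance radius, turning toward the far side.
    turn = 1.0 if rel_u[0] * outward[1] - rel_u[1] * outward[0] > 0 else -1.0
    tangent = np.array([-rel_u[1] * turn, rel_u[0] * turn])
    radial = np.clip(0.3 * (cfg.avoid_radius - d), -1.0, 1.0)
    direction = tangent + radial * rel_u
    gn = math.hypot(direction[0], direction[1])
    return direction / gn, False


def _steer(pos: np.ndarray, goal: np.ndarray, obs: dict[str, Any],
           cfg: PolicyConfig, exclude: int | None) -> np.ndarray:
    """Movement direction toward ``goal`` with a detour around targets.

    Walking straight through a target's repulsion zone would shove it the
    wrong way, so when a visible TA (other than the one being corralled,
    which we deliberately push) sits near the direct path, the direction
    is rotated to skirt it.
    """
    direction = goal - pos
    dist_goal = float(np.hypot(direction[0], direction[1]))
    if dist_goal < 1e-9:
        return np.zeros(2)
    direction = direction / dist_goal
    tapos = obs["ta_pos"]
    mask = obs["ta_mask"].copy()
    if exclude is not None:
        mask[exclude] = False
    if not np.any(mask):
        return direction
    rel = tapos[mask] - pos
    d = np.hypot(rel[:, 0], rel[:, 1])
    along = rel @ direction
    near = (d < cfg.avoid_radius) & (along > 0.0) & (along < dist_goal + cfg.avoid_radius)
    if not np.any(near):
        return direction
    # Veer around the nearest obstructing TA, passing on its far side.
    nearest = rel[near][np.argmin(d[near])]
    side = float(np.sign(direction[0] * nearest[1] - direction[1] * nearest[0]))
    if side == 0:
        side = 1.0
    perp = np.array([-direction[1], direction[0]]) * (-side)
    blend = direction + 1.2 * perp
    return blend / np.hypot(blend[0], blend[1])


def policy_act(
    obs: dict[str, Any], policy_state: dict[str, Any], rng: np.random.Generator
) -> dict[str, Any]:
    """One control decision: movement direction, slow-mode flag, head angle.

    Priority: corral the chosen threat if any is known; otherwise search
    per the configured strategy (or hold a guard post for
    ``corral_nearest``, and whenever every known TA is safely contained).
    """
    cfg: PolicyConfig = policy_state["config"]
    i = policy_state["player_index"]
    pos = obs["self_pos"]
    center = obs["containment_center"]
    radius = obs["containment_radius"]
    t = obs["t"]

    threat = _choose_threat(obs, policy_state)
    slow = False
    if threat is not None:
        move, slow = _corral_move(pos, obs, cfg, threat)
        policy_state["waypoint"] = None
    else:
        all_visible_contained = bool(
            np.all(~obs["ta_mask"])
            or np.all(obs["ta_status"][obs["ta_mask"]] >= CONTAINED)
        )
        guard_mode = cfg.strategy == "corral_nearest" or (
            cfg.global_info and all_visible_contained
        )
        if guard_mode:
            # Stand just outside the disc at the azimuth of the i-th
            # outermost contained target: escapes start at the rim, so
            # guards pre-position where they are most likely.
            visible = np.flatnonzero(obs["ta_mask"])
            if visible.size > 0:
                rel_ta = obs["ta_pos"][visible] - center
                order = np.argsort(-np.hypot(rel_ta[:, 0], rel_ta[:, 1]))
                watched = rel_ta[order[min(i, visible.size - 1)]]
                azimuth = math.atan2(watched[1], watched[0])
            else:
                azimuth = 2.0 * np.pi * i / 3.0
            post = center + (radius + 7.0) * np.array(
                [math.cos(azimuth), math.sin(azimuth)]
            )
            move = _steer(pos, post, obs, cfg, exclude=None)
            if float(np.hypot(*(post - pos))) < 1.0:
                move = np.zeros(2)
        else:
            move = _search_move(obs, policy_state, rng)

    heading = float(np.arctan2(move[1], move[0])) if np.any(move != 0) else obs["self_heading"]
    head = heading
    if cfg.scan_amplitude > 0:
        head = head + cfg.scan_amplitude * np.sin(
            2.0 * np.pi * t / cfg.scan_period + policy_state["scan_phase"]
        )
    if cfg.heading_noise_sd > 0:
        head = head + cfg.heading_noise_sd * rng.standard_normal()
    return {"move_dir": move, "slow": slow, "head": _wrap_angle(float(head))}


def _search_move(
    obs: dict[str, Any], ps: dict[str, Any], rng: np.random.Generator
) -> np.ndarray:
    """Waypoint-following search step for the sweep / random-walk strategies."""
    cfg: PolicyConfig = ps["config"]
    i = ps["player_index"]
    pos = obs["self_pos"]
    center = obs["containment_center"]
    t = obs["t"]

    wp = ps["waypoint"]
    arrived = wp is not None and float(np.hypot(*(wp - pos))) < cfg.waypoint_tolerance
    expired = wp is not None and t > ps["waypoint_deadline"]
    if wp is None or arrived or expired:
        k = ps["waypoint_index"]
        sweep_radius = 180.0
        if cfg.strategy == "partitioned_sweep":
            lo = 2.0 * np.pi * i / 3.0 - np.pi / 3.0
            wp = _spiral_waypoint(k, center, sweep_radius, (lo, 2.0 * np.pi / 3.0))
        elif cfg.strategy == "shared_sweep":
            wp = _spiral_waypoint(k, center, sweep_radius, None)
        else:  # random_walk
            ang = rng.uniform(0.0, 2.0 * np.pi)
            step = rng.uniform(20.0, 60.0)
            wp = pos + step * np.array([np.cos(ang), np.sin(ang)])
        ps["waypoint"] = wp
        ps["waypoint_index"] = k + 1
        ps["waypoint_deadline"] = t + 25.0
    direction = wp - pos
    norm = float(np.hypot(direction[0], direction[1]))
    return direction / norm if norm > 1e-9 else np.zeros(2)


# ---------------------------------------------------------------------------
# Trial loop
# ---------------------------------------------------------------------------


def run_trial(
    world_config: WorldConfig,
    policy_configs: list[PolicyConfig] | tuple[PolicyConfig, ...],
    seed: int,
    initial_ta_positions: np.ndarray | None = None,
    initial_avatar_positions: np.ndarray | None = None,
    condition: dict[str, Any] | None = None,
) -> tuple[TrialLog, str]:
    """Simulate one seeded trial and return its log and outcome.

    Avatars spawn area-uniformly within ``player_spawn_radius`` of the
    containment center and TAs within ``ta_spawn_radius`` (explicit
    initial positions may override either, e.g. to construct containment
    scenarios).  The loop runs at ``physics_hz``, logs at ``log_hz``, and
    terminates early with outcome ``"success"`` once the all-contained
    state has been held for ``success_hold`` continuous seconds; a single
    frame outside the disc resets the hold timer.  Otherwise the trial
    fails at ``trial_max`` with its duration recorded at that ceiling.

    Deterministic: the same ``(configs, seed)`` give a bit-identical log.
    """
    if len(policy_configs) != 3:
        raise ValueError("exactly three policy configs are required")
    root = np.random.SeedSequence(seed)
    spawn_ss, brown_ss, *policy_ss = root.spawn(5)
    spawn_rng = np.random.default_rng(spawn_ss)
    brown_rng = np.random.default_rng(brown_ss)
    policy_rngs = [np.random.default_rng(s) for s in policy_ss]

    center = np.asarray(world_config.containment_center, dtype=float)
    avatar_pos = (
        np.array(initial_avatar_positions, dtype=float)
        if initial_avatar_positions is not None
        else spawn_positions(spawn_rng, center, world_config.player_spawn_radius, 3)
    )
    ta_pos = (
        np.array(initial_ta_positions, dtype=float)
        if initial_ta_positions is not None
        else spawn_positions(spawn_rng, center, world_config.ta_spawn_radius,
                             world_config.n_targets)
    )
    if avatar_pos.shape != (3, 2):
        raise ValueError("initial avatar positions must have shape (3, 2)")
    if ta_pos.shape != (world_config.n_targets, 2):
        raise ValueError(
            f"initial TA positions must have shape ({world_config.n_targets}, 2)"
        )

    k = world_config.n_targets
    state = WorldState(
        t=0.0,
        ta_pos=ta_pos,
        ta_vel=np.zeros((k, 2)),
        ta_brownian=sample_brownian_force(brown_rng, world_config.brownian_force_max, k),
        ta_status=np.zeros(k, dtype=np.int8),
        avatar_pos=avatar_pos,
        avatar_heading=np.zeros(3),
        avatar_slow=np.zeros(3, dtype=bool),
    )
    update_statuses(state, world_config)

    dt = 1.0 / world_config.physics_hz
    n_steps = int(round(world_config.trial_max * world_config.physics_hz))
    log_every = world_config.physics_hz // world_config.log_hz
    per_decision = [
        max(1, int(round(world_config.physics_hz / pc.decision_hz)))
        for pc in policy_configs
    ]
    brown_period = int(round(world_config.physics_hz / world_config.brownian_rate))

    n_log = n_steps // log_every
    time_log = np.empty(n_log)
    ppos_log = np.empty((n_log, 3, 2))
    phead_log = np.empty((n_log, 3))
    tpos_log = np.empty((n_log, k, 2))
    tstat_log = np.empty((n_log, k), dtype=np.int8)

    policy_states = [make_policy_state(pc, i) for i, pc in enumerate(policy_configs)]
    controls: list[dict[str, Any]] = [
        {"move_dir": np.zeros(2), "slow": False, "head": 0.0} for _ in range(3)
    ]

    hold = 0.0
    outcome = "fail"
    duration = world_config.trial_max
    n_logged = 0

    for step in range(n_steps):
        if step % log_every == 0:
            j = step // log_every
            time_log[j] = state.t
            ppos_log[j] = state.avatar_pos
            phead_log[j] = state.avatar_heading
            tpos_log[j] = state.ta_pos
            tstat_log[j] = state.ta_status
            n_logged = j + 1
        if step > 0 and step % brown_period == 0:
            state.ta_brownian = sample_brownian_force(
                brown_rng, world_config.brownian_force_max, k
            )
        for i, pc in enumerate(policy_configs):
            if step % per_decision[i] == 0:
                obs = policy_observe(state, pc, i, world_config)
                controls[i] = policy_act(obs, policy_states[i], policy_rngs[i])
        step_world(state, controls, world_config, dt)
        # update_statuses sets ALL_CONTAINED on every TA or none.
        if state.ta_status[0] == ALL_CONTAINED:
            hold += dt
        else:
            hold = 0.0
        if hold >= world_config.success_hold - 1e-12:
            outcome = "success"
            duration = (step + 1) * dt
            break

    log = TrialLog(
        sample_rate=float(world_config.log_hz),
        time=time_log[:n_logged].copy(),
        player_pos=ppos_log[:n_logged].copy(),
        player_heading=phead_log[:n_logged].copy(),
        ta_pos=tpos_log[:n_logged].copy(),
        ta_status=tstat_log[:n_logged].copy(),
        outcome=outcome,
        duration=float(duration),
        seed=int(seed),
        condition=dict(condition or {}),
        config={
            "world": world_config.to_dict(),
            "policies": [pc.to_dict() for pc in policy_configs],
        },
    )
    return log, outcome
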