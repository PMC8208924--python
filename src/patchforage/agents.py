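"""Synthetic foraging agents: parameterized patch-leaving policies.

Agents play the two-layer foraging task on a generated arena: they sweep
the aerial view to discover hidden patches, enter them, harvest resources
in the zoomed patch view, and leave according to a policy:

``fixed_residence``
    leave a fixed time after entry;
``give_up_time``
    leave a fixed time after the most recent reward (clock resets on
    every pickup);
``mvt_offset``
    track the current reward rate (trailing window) and the session
    average reward rate online, and leave ``olt_offset_s`` seconds
    relative to the CRR/ARR crossing that follows a CRR peak — the
    marginal-value-theorem leave point.  Negative offsets (leaving
    *before* the crossing) are realized by projecting the crossing
    forward under a no-further-reward assumption, which is exact once
    the agent has left;
``random_walker``
    residence drawn uniformly per visit.

These agents are test instruments with known ground truth, not models of
human cognition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import PatchLayout, validate_layout
from .records import AERIAL, PATCH, Event, ForagingEventLog, Sample

__all__ = ["AgentPolicy", "simulate_run", "simulate_cohort", "simulate_stationary_harvest_log"]

POLICY_KINDS = ("fixed_residence", "give_up_time", "mvt_offset", "random_walker")


@dataclass(frozen=True)
class AgentPolicy:
    """Patch-leaving policy plus movement strategy knobs.

    ``crr_window_s`` is the trailing window the mvt_offset agent uses for
    its own online CRR; by default it equals the analysis default (9 s)
    so that a planted offset delta maps onto LTD approximately -delta.
    """

    kind: str = "give_up_time"
    residence_s: float = 12.0
    giveup_s: float = 6.0
    olt_offset_s: float = 0.0
    crr_window_s: float = 9.0
    travel_strategy: str = "nearest_known"  # or "sweep"
    within_patch_strategy: str = "random_walk"  # or "lawnmower"
    travel_speed: float | None = None  # px/s in aerial view; None = the view's cap
    sample_rate_hz: float = 20.0
    no_reward_timeout_s: float = 20.0  # bail-out when a visit yields nothing
    turn_interval_s: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.travel_strategy not in ("nearest_known", "sweep"):
            raise ValueError(f"unknown travel_strategy {self.travel_strategy!r}")
        if self.within_patch_strategy not in ("random_walk", "lawnmower"):
            raise ValueError(f"unknown within_patch_strategy {self.within_patch_strategy!r}")
        for name in ("residence_s", "giveup_s", "crr_window_s", "sample_rate_hz",
                     "no_reward_timeout_s", "turn_interval_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isfinite(self.olt_offset_s):
            raise ValueError("olt_offset_s must be finite")


def _sweep_waypoints(size: float, margin: float, row_step: float) -> list[tuple[float, float]]:
    """Serpentine search path whose rows guarantee patch discovery."""
    rows: list[float] = []
    y = margin
    while y < size - margin:
        rows.append(y)
        y += row_step
    rows.append(size - margin)
    pts: list[tuple[float, float]] = []
    for i, ry in enumerate(rows):
        if i % 2 == 0:
            pts.extend([(margin, ry), (size - margin, ry)])
        else:
            pts.extend([(size - margin, ry), (margin, ry)])
    return pts


class _OnlineMVT:
    """Online CRR/ARR tracker mirroring the analysis pairing rule.

    Maintains, for the current visit, the last *sealed* CRR peak (a strict
    local maximum becomes a peak only once a lower sample follows it, the
    same semantics the offline peak detector uses) and the first CRR/ARR
    crossing at or after that peak: ``crossing_passed`` once it has been
    observed, else ``crossing_projected`` under a no-further-reward
    assumption (exact once the agent stops harvesting).  A new peak
    supersedes the old pairing, exactly as the offline scorer pairs each
    visit with its last peak.
    """

    def __init__(self, window_s: float, dt: float):
        self.W = window_s
        self.dt = dt
        self.reward_times: list[float] = []
        self._new_visit = True
        self.enter_visit(0.0)

    def enter_visit(self, crr_now: float) -> None:
        self.last_val = crr_now
        self.last_d: float | None = None  # previous sample's CRR - ARR
        self.run_start: float | None = None  # first sample of current value run
        self.rising = False
        self.peak_t: float | None = None  # last sealed peak
        self.crossing_passed: float | None = None
        self.crossing_projected: float | None = None
        self.prev_d: float | None = None
        self._dirty = True

    def crr(self, t: float) -> float:
        rt = self.reward_times
        lo = t - self.W
        return sum(1 for r in rt if lo < r <= t) / self.W

    def arr(self, t: float) -> float:
        return len(self.reward_times) / t if t > 0 else 0.0

    def add_reward(self, t: float) -> None:
        self.reward_times.append(t)
        self._dirty = True

    @property
    def crossing(self) -> float | None:
        """The pairing crossing: observed if passed, else projected."""
        if self.crossing_passed is not None:
            return self.crossing_passed
        return self.crossing_projected

    def step(self, t: float, duration: float) -> None:
        c = self.crr(t)
        d = c - self.arr(t)
        if c > self.last_val:
            self.rising = True
            self.run_start = t
        elif c < self.last_val:
            if self.rising and self.run_start is not None:
                # a lower sample seals the peak at the plateau's first sample;
                # the crossing scan restarts there, seeded with the final
                # plateau sample's margin (the sealing step may itself cross)
                self.peak_t = self.run_start
                self.crossing_passed = None
                self.crossing_projected = None
                self.prev_d = self.last_d
                self._dirty = True
            self.rising = False
            self.run_start = t
        self.last_val = c

        if self.peak_t is not None and self.crossing_passed is None:
            if self.prev_d is not None and self.prev_d > 0 and d <= 0:
                frac = self.prev_d / (self.prev_d - d)
                self.crossing_passed = (t - self.dt) + frac * self.dt
                self.crossing_projected = None
            self.prev_d = d
        if (
            self.peak_t is not None
            and self.crossing_passed is None
            and self._dirty
        ):
            self.crossing_projected = self._project(t, duration, d)
            self._dirty = False
        self.last_d = d

    def _project(self, t: float, duration: float, d_now: float) -> float | None:
        """First future from-above CRR/ARR crossing with no further rewards."""
        if d_now <= 0:
            # below the average rate and, absent new rewards, staying there
            return None
        rt = np.asarray(self.reward_times, dtype=float)
        n = rt.size
        if n == 0:
            return None
        horizon = min(t + 60.0, duration)
        k = int(np.ceil((horizon - t) / self.dt))
        if k < 1:
            return None
        tf = t + np.arange(0, k + 1) * self.dt
        hi = np.searchsorted(rt, tf, side="right")
        lo = np.searchsorted(rt, tf - self.W, side="right")
        crr_f = (hi - lo) / self.W
        with np.errstate(divide="ignore"):
            arr_f = np.where(tf > 0, n / tf, 0.0)
        d = crr_f - arr_f
        idx = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
        if idx.size == 0:
            return None
        i = int(idx[0])
        return float(tf[i] + d[i] * (tf[i + 1] - tf[i]) / (d[i] - d[i + 1]))


def simulate_run(
    layout: PatchLayout,
    policy: AgentPolicy,
    seed: int,
    participant_id: str = "sim",
    run_index: str = "pre",
) -> ForagingEventLog:
    """Simulate one full foraging run on ``layout`` under ``policy``.

    The log is sampled at ``policy.sample_rate_hz``; the agent moves at
    most at the aerial speed cap in the aerial view and the patch speed
    cap in the patch view; rewards fire only in patch view when the hand
    comes within the resource reveal radius of an unfound resource, and
    each resource is found at most once.  Deterministic for a fixed seed.
    """
    violations = validate_layout(layout)
    if violations:
        raise ValueError("invalid layout: " + "; ".join(violations[:3]))

    cfg = layout.config
    rng = np.random.default_rng(seed)
    rate = policy.sample_rate_hz
    n_steps = int(round(cfg.run_duration * rate))
    duration = cfg.run_duration
    size = cfg.arena_size

    centers = np.array([p.center for p in layout.patches], dtype=float)
    resources = [np.asarray(p.resources, dtype=float) for p in layout.patches]
    found = [np.zeros(len(p.resources), dtype=bool) for p in layout.patches]
    detect_r = cfg.aerial_reveal_radius + cfg.patch_radius

    margin = cfg.patch_radius + cfg.min_border_distance
    waypoints = _sweep_waypoints(size, margin, row_step=1.6 * cfg.aerial_reveal_radius + cfg.patch_radius)
    wp_i = 0

    samples: list[Sample] = []
    events: list[Event] = []
    mvt = _OnlineMVT(policy.crr_window_s, 1.0 / rate)

    pos = np.array([size / 2.0, size / 2.0])  # aerial position
    view = AERIAL
    discovered = np.zeros(len(layout.patches), dtype=bool)
    visited: set[int] = set()
    last_left: int | None = None
    target_patch: int | None = None

    # patch-view state
    cur_patch = -1
    hand = np.zeros(2)
    heading = 0.0
    steps_since_turn = 0
    t_enter = 0.0
    last_reward_t = 0.0
    visit_residence = 0.0  # random_walker draw
    mower_path: list[np.ndarray] = []
    mower_pos: dict[int, int] = {}  # per-patch progress along the mower path

    def discover() -> None:
        d = np.hypot(*(centers - pos).T)
        discovered[d <= detect_r] = True

    def pick_target() -> int | None:
        # "sweep" agents never return to a patch they already entered;
        # "nearest_known" agents prefer fresh patches but will revisit
        # known, unexhausted ones once everything has been tried.
        fresh = [i for i in range(len(layout.patches)) if discovered[i] and i not in visited]
        if fresh:
            cand = fresh
        elif policy.travel_strategy == "sweep":
            return None
        else:
            cand = [
                i
                for i in range(len(layout.patches))
                if discovered[i] and not found[i].all() and i != last_left
            ]
        if not cand:
            return None
        d = np.hypot(*(centers[cand] - pos).T)
        return cand[int(np.argmin(d))]

    def build_mower_path() -> list[np.ndarray]:
        step = 1.5 * cfg.resource_reveal_radius
        ys: list[float] = []
        y = cfg.resource_reveal_radius
        while y < size:
            ys.append(y)
            y += step
        pts = []
        for i, ry in enumerate(ys):
            if i % 2 == 0:
                pts.extend([np.array([0.0, ry]), np.array([size, ry])])
            else:
                pts.extend([np.array([size, ry]), np.array([0.0, ry])])
        return pts

    discover()
    for k in range(n_steps + 1):
        t = k / rate
        if view == AERIAL:
            samples.append(Sample(t, AERIAL, None, float(pos[0]), float(pos[1])))
        else:
            samples.append(Sample(t, PATCH, cur_patch, float(hand[0]), float(hand[1])))
        if k == n_steps:
            break
        t_next = (k + 1) / rate
        dt = t_next - t

        if view == AERIAL:
            target_patch = pick_target()
            if target_patch is not None:
                goal = centers[target_patch]
            else:
                goal = np.asarray(waypoints[wp_i])
                if np.hypot(*(goal - pos)) < 1.0:
                    wp_i = (wp_i + 1) % len(waypoints)
                    goal = np.asarray(waypoints[wp_i])
            speed = min(policy.travel_speed or cfg.aerial_max_speed, cfg.aerial_max_speed)
            step_len = speed * dt
            delta = goal - pos
            dist = float(np.hypot(*delta))
            if dist > 1e-12:
                pos = pos + delta * min(1.0, step_len / dist)
            discover()
            if target_patch is not None:
                # enter once the patch center is reached (the entry keypress);
                # the aerial position is preserved across the visit
                if np.hypot(*(centers[target_patch] - pos)) <= 2.0:
                    pos = centers[target_patch].copy()
                    cur_patch = target_patch
                    visited.add(cur_patch)
                    events.append(Event(t_next, "patch_enter", cur_patch))
                    view = PATCH
                    hand = np.array([size / 2.0, size / 2.0])
                    heading = float(rng.uniform(0.0, 2 * np.pi))
                    steps_since_turn = 0
                    t_enter = t_next
                    last_reward_t = t_next
                    visit_residence = float(rng.uniform(4.0, 25.0))
                    mvt.enter_visit(mvt.crr(t_next))
                    if policy.within_patch_strategy == "lawnmower":
                        if not mower_path:
                            mower_path = build_mower_path()
                        if cur_patch not in mower_pos:
                            d = [float(np.hypot(*(p - hand))) for p in mower_path]
                            mower_pos[cur_patch] = int(np.argmin(d))
        else:
            # idle while an mvt_offset agent waits out a positive offset:
            # once the pairing crossing has been observed, harvesting more
            # would create a later peak and re-pair the visit
            idle = (
                policy.kind == "mvt_offset"
                and policy.olt_offset_s > 0
                and mvt.crossing_passed is not None
            )
            if not idle:
                step_len = cfg.patch_max_speed * dt
                if policy.within_patch_strategy == "lawnmower" and mower_path:
                    goal = mower_path[mower_pos[cur_patch]]
                    delta = goal - hand
                    dist = float(np.hypot(*delta))
                    if dist <= step_len:
                        hand = goal.copy()
                        mower_pos[cur_patch] = (mower_pos[cur_patch] + 1) % len(mower_path)
                    else:
                        hand = hand + delta * (step_len / dist)
                else:
                    steps_since_turn += 1
                    if steps_since_turn * dt >= policy.turn_interval_s:
                        heading = float(rng.uniform(0.0, 2 * np.pi))
                        steps_since_turn = 0
                    nxt = hand + step_len * np.array([np.cos(heading), np.sin(heading)])
                    if not (0.0 <= nxt[0] <= size and 0.0 <= nxt[1] <= size):
                        heading = float(rng.uniform(0.0, 2 * np.pi))
                        nxt = hand + step_len * np.array([np.cos(heading), np.sin(heading)])
                        nxt = np.clip(nxt, 0.0, size)
                        # clipping can only shorten the step, never exceed the cap
                    hand = nxt
                # reward pickup
                pts = resources[cur_patch]
                if pts.size:
                    d = np.hypot(*(pts - hand).T)
                    hit = np.nonzero((~found[cur_patch]) & (d <= cfg.resource_reveal_radius))[0]
                    for ri in hit:
                        found[cur_patch][ri] = True
                        events.append(Event(t_next, "reward", cur_patch, int(ri)))
                        mvt.add_reward(t_next)
                        last_reward_t = t_next

            if policy.kind == "mvt_offset":
                mvt.step(t_next, duration)

            leave = False
            elapsed = t_next - t_enter
            if policy.kind == "fixed_residence":
                leave = elapsed >= policy.residence_s - 1e-12
            elif policy.kind == "give_up_time":
                leave = t_next - last_reward_t >= policy.giveup_s - 1e-12
            elif policy.kind == "random_walker":
                leave = elapsed >= visit_residence
            elif policy.kind == "mvt_offset":
                tc = mvt.crossing
                if mvt.peak_t is not None and tc is not None:
                    if policy.olt_offset_s >= 0:
                        leave = t_next >= tc + policy.olt_offset_s - 1e-9
                    elif mvt.crossing_passed is None:
                        # crossing still ahead: take the planned head start,
                        # or exit at once if the plan leaves less room (the
                        # in-patch margin only decays once the window has
                        # filled, so waiting for a fatter plan cannot help)
                        leave = t_next >= tc + policy.olt_offset_s - 1e-9
                    # a crossing that already passed cannot be led; keep
                    # harvesting until a fresh peak resets the pairing
                if found[cur_patch].all() or (
                    t_next - last_reward_t >= policy.no_reward_timeout_s
                ):
                    leave = True  # patch exhausted or nothing harvestable
            if leave:
                events.append(Event(t_next, "patch_exit", cur_patch))
                view = AERIAL
                last_left = cur_patch
                cur_patch = -1

    log = ForagingEventLog(
        participant_id=participant_id,
        run_index=run_index,
        duration=duration,
        samples=samples,
        events=events,
    )
    log.validate()
    return log


def simulate_cohort(
    layout_seed_base: int,
    policy: AgentPolicy,
    n: int,
    runs_per_participant: int = 2,
    seed: int = 0,
    config=None,
) -> list[tuple[str, str, ForagingEventLog]]:
    """Simulate ``n`` participants, each playing fresh arenas.

    Every run gets a new random patch layout (as in the task) seeded
    deterministically from ``layout_seed_base``; agent behavior is seeded
    from ``seed``.  Runs are labeled ``pre``/``post``.
    """
    from .environment import EnvironmentConfig, generate_patch_layout

    if n < 1:
        raise ValueError("n must be >= 1")
    if runs_per_participant not in (1, 2):
        raise ValueError("runs_per_participant must be 1 or 2")
    if config is None:
        config = EnvironmentConfig()
    agent_seeds = np.random.SeedSequence(seed).spawn(n * runs_per_participant)
    out: list[tuple[str, str, ForagingEventLog]] = []
    idx = 0
    for i in range(n):
        pid = f"P{i + 1:03d}"
        for j in range(runs_per_participant):
            run_index = "pre" if j == 0 else "post"
            layout = generate_patch_layout(config, layout_seed_base + idx)
            aseed = int(agent_seeds[idx].generate_state(1)[0] % (2**31))
            log = simulate_run(layout, policy, aseed, participant_id=pid, run_index=run_index)
            out.append((pid, run_index, log))
            idx += 1
    return out


def simulate_stationary_harvest_log(
    gain,
    travel_s: float,
    window_s: float,
    duration: float = 3600.0,
    sample_rate_hz: float = 20.0,
    seed: int = 0,
    participant_id: str = "harvest",
) -> ForagingEventLog:
    """Event log of an MVT-following harvester on a stationary gain process.

    Within-patch rewards arrive as an inhomogeneous Poisson process with
    rate f'(T) = A*lam*exp(-lam*T) (the derivative of the saturating gain
    ``gain``), travel between patches takes exactly ``travel_s``, and the
    agent leaves at the first online CRR/ARR crossing after a CRR peak.
    In steady state the realized average rate approaches the optimal rate,
    so detected leave residences converge on the analytic MVT optimum.
    Positions are synthetic (stationary); only the event stream matters.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    n_steps = int(round(duration * sample_rate_hz))
    samples: list[Sample] = []
    events: list[Event] = []
    mvt = _OnlineMVT(window_s, dt)

    view = AERIAL
    patch_id = 0
    t_enter = 0.0
    travel_left = travel_s
    no_cross_cap = 240.0  # safety residence cap before steady state locks in

    for k in range(n_steps + 1):
        t = k / sample_rate_hz
        if view == AERIAL:
            samples.append(Sample(t, AERIAL, None, 300.0, 300.0))
        else:
            samples.append(Sample(t, PATCH, patch_id, 300.0, 300.0))
        if k == n_steps:
            break
        t_next = (k + 1) / sample_rate_hz
        if view == AERIAL:
            travel_left -= dt
            if travel_left <= 1e-9:
                view = PATCH
                events.append(Event(t_next, "patch_enter", patch_id))
                t_enter = t_next
                mvt.enter_visit(mvt.crr(t_next))
        else:
            # inhomogeneous Poisson arrivals, counted per sample step
            T_p = t_next - t_enter
            lam_t = gain.derivative(T_p)
            for _ in range(int(rng.poisson(lam_t * dt))):
                events.append(Event(t_next, "reward", patch_id, None))
                mvt.add_reward(t_next)
            mvt.step(t_next, duration)
            leave = (
                mvt.peak_t is not None
                and mvt.crossing is not None
                and t_next >= mvt.crossing - 1e-9
            )
            if T_p > no_cross_cap:
                leave = True
            if leave:
                events.append(Event(t_next, "patch_exit", patch_id))
                view = AERIAL
                travel_left = travel_s
                patch_id += 1

    log = ForagingEventLog(
        participant_id=participant_id,
        run_index="pre",
        duration=duration,
        samples=samples,
        events=events,
    )
    log.validate()
    return log
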