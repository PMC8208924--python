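"""Marginal-value-theorem leave-time analysis of foraging event logs.

The marginal value theorem (Charnov) prescribes leaving a patch when the
instantaneous intake rate drops to the environment's long-run average
rate.  With discrete rewards the instantaneous rate is estimated as a
*current reward rate* (CRR): rewards collected in a trailing window of
length W divided by W.  The *average reward rate* (ARR) is the running
cumulative reward count divided by elapsed session time (travel included,
T = t + T_P).  An *optimal leave time* (OLT) is the first moment, after a
local peak of the CRR inside a patch visit, at which the CRR falls to
intersect the ARR.  The *leave-time difference* LTD = OLT - ALT compares
it with the forager's actual leave time: negative LTD means overstaying
(exploitation emphasis), positive LTD means leaving early (exploration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .records import AERIAL, ForagingEventLog, PatchVisit, extract_visits

__all__ = [
    "RewardTimeSeries",
    "GainFunction",
    "VisitLTD",
    "LTDResult",
    "compute_crr",
    "compute_arr",
    "detect_crr_peaks",
    "detect_olts",
    "compute_ltd",
    "analytic_optimal_residence",
    "compute_foraging_metrics",
]


@dataclass
class RewardTimeSeries:
    """A reward-rate signal sampled on a log's time grid (rewards/second)."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # "CRR" | "ARR"
    window_s: float | None = None


@dataclass(frozen=True)
class GainFunction:
    """Saturating within-patch gain f(T) = A * (1 - exp(-lam * T)).

    ``A`` is the asymptotic reward count of a patch, ``lam`` (1/s) the
    harvest rate constant; f rises from zero at a negatively accelerated
    rate, as the patch model assumes.
    """

    A: float
    lam: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.lam <= 0:
            raise ValueError("GainFunction requires A > 0 and lam > 0")

    def __call__(self, T):
        return self.A * (1.0 - np.exp(-self.lam * np.asarray(T, dtype=float)))

    def derivative(self, T):
        return self.A * self.lam * np.exp(-self.lam * np.asarray(T, dtype=float))


@dataclass(frozen=True)
class VisitLTD:
    visit: PatchVisit
    olt: float | None
    alt: float
    ltd: float | None  # olt - alt where defined


@dataclass
class LTDResult:
    per_visit: list[VisitLTD]
    participant_ltd: float | None
    n_excluded: int
    window_s: float


def _sample_grid(log: ForagingEventLog) -> np.ndarray:
    return np.array([s.t for s in log.samples], dtype=float)


def compute_crr(log: ForagingEventLog, window_s: float) -> RewardTimeSeries:
    """Current reward rate: rewards in the trailing window (t - W, t] over W.

    Evaluated on the log's sample grid; zero before the first reward.  The
    window is causal — only rewards already collected enter the estimate.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    grid = _sample_grid(log)
    rt = np.asarray(log.reward_times(), dtype=float)
    if rt.size == 0:
        return RewardTimeSeries(grid, np.zeros_like(grid), "CRR", window_s)
    hi = np.searchsorted(rt, grid, side="right")
    lo = np.searchsorted(rt, grid - window_s, side="right")
    return RewardTimeSeries(grid, (hi - lo) / window_s, "CRR", window_s)


def compute_arr(log: ForagingEventLog) -> RewardTimeSeries:
    """Average reward rate: cumulative rewards up to t over elapsed time t.

    Travel time is in the denominator (total session time T = t + T_P);
    ARR(0) is defined as 0.
    """
    grid = _sample_grid(log)
    rt = np.asarray(log.reward_times(), dtype=float)
    counts = np.searchsorted(rt, grid, side="right").astype(float)
    values = np.zeros_like(grid)
    nz = grid > 0
    values[nz] = counts[nz] / grid[nz]
    return RewardTimeSeries(grid, values, "ARR")


def detect_crr_peaks(crr: RewardTimeSeries, visit: PatchVisit) -> list[float]:
    """Times of strict local maxima of the CRR samples within the visit.

    A plateau that is a local maximum reports its first sample.  A
    monotone (or empty) stretch yields no peak.
    """
    mask = (crr.times >= visit.t_enter) & (crr.times <= visit.t_exit)
    t = crr.times[mask]
    v = crr.values[mask]
    if t.size < 3:
        return []
    peaks: list[float] = []
    i = 1
    n = v.size
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append(float(t[i]))
            i = j + 1
        else:
            i += 1
    return peaks


def detect_olts(
    crr: RewardTimeSeries,
    arr: RewardTimeSeries,
    peaks: list[float],
    search_end: float,
) -> list[float]:
    """First CRR-below-ARR crossings after each peak, sub-sample interpolated.

    For each peak time the search scans forward (possibly past the visit's
    exit, where the trailing-window CRR keeps decaying) up to
    ``search_end`` for the first sample pair where CRR - ARR goes from
    positive to <= 0; the crossing time is linearly interpolated between
    the bracketing samples.  Exact ties (CRR == ARR) count as crossings.
    Consecutive peaks sharing one crossing yield a single OLT.
    """
    if not np.array_equal(crr.times, arr.times):
        raise ValueError("CRR and ARR must share a sample grid")
    t = crr.times
    d = crr.values - arr.values
    olts: list[float] = []
    for pk in peaks:
        i0 = int(np.searchsorted(t, pk, side="left"))
        found = None
        for i in range(i0, t.size - 1):
            if t[i] > search_end:
                break
            if d[i] > 0 and d[i + 1] <= 0:
                tc = t[i] + d[i] * (t[i + 1] - t[i]) / (d[i] - d[i + 1])
                if tc <= search_end:
                    found = float(tc)
                break
            if d[i] == 0 and (i == i0 or d[i - 1] > 0):
                found = float(t[i])
                break
        if found is not None and (not olts or found != olts[-1]):
            olts.append(found)
    return olts


def compute_ltd(log: ForagingEventLog, window_s: float) -> LTDResult:
    """Score every patch visit: LTD = OLT - ALT, averaged per participant.

    For each non-censored visit with at least one CRR peak, the OLT is the
    first CRR/ARR crossing at or after the visit's *last* peak, searched up
    to the next visit's entry (or the run's end).  Visits with no peak or
    no crossing are excluded from the mean and counted in ``n_excluded``;
    censored final visits (forced out by the clock) are excluded too.
    """
    crr = compute_crr(log, window_s)
    arr = compute_arr(log)
    visits = extract_visits(log)
    per_visit: list[VisitLTD] = []
    defined: list[float] = []
    n_excluded = 0
    for k, visit in enumerate(visits):
        if visit.censored:
            n_excluded += 1
            per_visit.append(VisitLTD(visit, None, visit.t_exit, None))
            continue
        peaks = detect_crr_peaks(crr, visit)
        if not peaks:
            n_excluded += 1
            per_visit.append(VisitLTD(visit, None, visit.t_exit, None))
            continue
        search_end = visits[k + 1].t_enter if k + 1 < len(visits) else log.duration
        olts = detect_olts(crr, arr, [peaks[-1]], search_end)
        if not olts:
            n_excluded += 1
            per_visit.append(VisitLTD(visit, None, visit.t_exit, None))
            continue
        olt = olts[0]
        ltd = olt - visit.t_exit
        defined.append(ltd)
        per_visit.append(VisitLTD(visit, olt, visit.t_exit, ltd))
    participant_ltd = float(np.mean(defined)) if defined else None
    return LTDResult(per_visit, participant_ltd, n_excluded, window_s)


def analytic_optimal_residence(f: GainFunction, travel_s: float) -> float:
    """Closed-environment MVT optimum: residence T* maximizing f(T)/(travel + T).

    T* solves f'(T) * (travel + T) = f(T); for the saturating gain this
    reduces to exp(lam*T) - 1 = lam*(travel + T), which has a unique
    positive root found by bracketed root finding to < 1e-6 s.
    """
    if travel_s <= 0:
        raise ValueError("travel_s must be positive")

    lam, s = f.lam, travel_s

    def g(T: float) -> float:
        return np.expm1(lam * T) - lam * (s + T)

    # g(0) = -lam*s < 0, g grows exponentially: bracket the unique root
    hi = 1.0
    while g(hi) <= 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("no interior optimum for this gain function")
    return float(brentq(g, 1e-12, hi, xtol=1e-9))


def compute_foraging_metrics(log: ForagingEventLog) -> dict:
    """Seven descriptive foraging metrics for one run.

    Returns unique/total patch-visit ratio, median patch residence time,
    SD of residence times, mean inter-patch travel time, time to first
    patch entry, fraction of the arena revealed (union of aerial reveal
    disks along the trajectory on a 1-px occupancy grid, reveal radius
    15 px), and total rewards.  Metrics undefined on the log are ``None``.
    """
    visits = extract_visits(log)
    total_rewards = len(log.reward_times())
    out: dict = {
        "unique_total_patch_ratio": None,
        "median_residence_s": None,
        "residence_sd_s": None,
        "mean_travel_s": None,
        "time_to_first_patch_s": None,
        "arena_revealed_fraction": None,
        "total_rewards": total_rewards,
    }
    if visits:
        out["unique_total_patch_ratio"] = len({v.patch_id for v in visits}) / len(visits)
        res = np.array([v.t_exit - v.t_enter for v in visits])
        out["median_residence_s"] = float(np.median(res))
        out["residence_sd_s"] = float(np.std(res, ddof=1)) if len(res) > 1 else None
        gaps = [
            visits[i + 1].t_enter - visits[i].t_exit for i in range(len(visits) - 1)
        ]
        out["mean_travel_s"] = float(np.mean(gaps)) if gaps else None
        out["time_to_first_patch_s"] = visits[0].t_enter

    aerial = [(s.x, s.y) for s in log.samples if s.view == AERIAL]
    if aerial:
        # 1-px occupancy grid over a 600x600 arena (arena size is implied
        # by the coordinates; use the max extent rounded up to >= 600)
        size = 600
        reveal = 15
        grid = np.zeros((size, size), dtype=bool)
        r2 = reveal * reveal
        dy, dx = np.mgrid[-reveal : reveal + 1, -reveal : reveal + 1]
        disk = dx * dx + dy * dy <= r2
        ddy, ddx = np.nonzero(disk)
        ddy = ddy - reveal
        ddx = ddx - reveal
        seen = set()
        for x, y in aerial:
            key = (int(round(x)), int(round(y)))
            if key in seen:
                continue
            seen.add(key)
            xs = key[0] + ddx
            ys = key[1] + ddy
            ok = (xs >= 0) & (xs < size) & (ys >= 0) & (ys < size)
            grid[ys[ok], xs[ok]] = True
        out["arena_revealed_fraction"] = float(grid.sum()) / (size * size)
    return out
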