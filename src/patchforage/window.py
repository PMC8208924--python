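"""Grid search for the CRR window that zeroes the cohort's mean LTD.

With discrete rewards the current reward rate needs a trailing window
length W; the analysis chooses W by scanning a grid of candidates and
keeping the one whose cohort-average leave-time difference is closest to
zero.  The canonical procedure runs two iterations: a coarse grid of 200
windows (0-20 s in 100 ms steps, left endpoint excluded) and a fine grid
of 50 windows spanning +-0.25 s around the coarse winner in 10 ms steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .analysis import compute_ltd
from .records import ForagingEventLog

__all__ = ["WindowGrid", "WindowFitResult", "window_grid", "fit_optimal_window", "two_stage_fit", "WindowSelector"]


@dataclass(frozen=True)
class WindowGrid:
    """Half-open window grid (start_s, stop_s] with spacing step_s."""

    start_s: float
    stop_s: float
    step_s: float
    windows: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if not self.stop_s > self.start_s >= 0:
            raise ValueError("need stop_s > start_s >= 0")
        ratio = (self.stop_s - self.start_s) / self.step_s
        k = round(ratio)
        if abs(ratio - k) > 1e-9 * max(1.0, ratio):
            raise ValueError(
                f"span {self.stop_s - self.start_s} is not an integral multiple of step {self.step_s}"
            )
        object.__setattr__(
            self,
            "windows",
            tuple(round(self.start_s + i * self.step_s, 9) for i in range(1, k + 1)),
        )


def window_grid(start_s: float, stop_s: float, step_s: float) -> WindowGrid:
    """Build the half-open candidate-window grid (start_s, stop_s]."""
    return WindowGrid(start_s, stop_s, step_s)


@dataclass
class WindowFitResult:
    grid: WindowGrid
    mean_ltd_by_window: list[tuple[float, float | None]]
    best_window_s: float
    best_mean_ltd: float


def _aggregate_ltd(logs: list[ForagingEventLog], window_s: float) -> float | None:
    """Mean over participants of participant-mean LTD; None if all undefined."""
    vals = [r.participant_ltd for log in logs if (r := compute_ltd(log, window_s)).participant_ltd is not None]
    return float(np.mean(vals)) if vals else None


def fit_optimal_window(logs: list[ForagingEventLog], grid: WindowGrid) -> WindowFitResult:
    """Pick the window whose |cohort mean LTD| is smallest.

    The aggregate per window is the mean of participant means (logs with
    no defined LTD under that window are skipped).  Ties break toward the
    smaller window; deterministic.
    """
    table: list[tuple[float, float | None]] = []
    best_w: float | None = None
    best_val = np.inf
    for w in grid.windows:
        agg = _aggregate_ltd(logs, w)
        table.append((w, agg))
        if agg is not None and abs(agg) < best_val:
            best_val = abs(agg)
            best_w = w
    if best_w is None:
        raise ValueError("no window yields any defined LTD")
    best_agg = next(a for w, a in table if w == best_w)
    return WindowFitResult(grid, table, best_w, float(best_agg))


def _two_stage(
    logs: list[ForagingEventLog],
    stage1: WindowGrid,
    refine_halfwidth_s: float,
    refine_step_s: float,
) -> tuple[WindowFitResult, WindowFitResult]:
    res1 = fit_optimal_window(logs, stage1)
    w1 = res1.best_window_s
    lo = max(w1 - refine_halfwidth_s, 0.0)
    hi = w1 + refine_halfwidth_s
    # snap the span to an integral number of steps
    k = max(1, round((hi - lo) / refine_step_s))
    lo = hi - k * refine_step_s
    if lo < 0:
        lo = 0.0
    stage2 = window_grid(round(lo, 9), round(hi, 9), refine_step_s)
    return res1, fit_optimal_window(logs, stage2)


def two_stage_fit(
    logs: list[ForagingEventLog],
    stage1: WindowGrid | None = None,
    refine_halfwidth_s: float = 0.25,
    refine_step_s: float = 0.01,
) -> WindowFitResult:
    """Two-iteration window fit: coarse 0-20 s grid, then a fine local grid.

    Stage 1 scans (0, 20] s in 100 ms steps (200 windows); stage 2 scans
    +-``refine_halfwidth_s`` around the stage-1 winner in
    ``refine_step_s`` steps (clipped below so windows stay positive).
    With a stage-1 winner of 9.0 s the refinement grid is exactly
    (8.75, 9.25] in 10 ms steps, 50 windows.  Returns the stage-2 result.
    """
    if stage1 is None:
        stage1 = window_grid(0.0, 20.0, 0.1)
    return _two_stage(logs, stage1, refine_halfwidth_s, refine_step_s)[1]


class WindowSelector(BaseEstimator):
    """Estimator wrapper around the two-stage CRR-window grid search.

    Parameters
    ----------
    stage1_start_s, stage1_stop_s, stage1_step_s : float
        Coarse grid bounds (half-open) and spacing.
    refine_halfwidth_s, refine_step_s : float
        Fine grid half-width around the coarse winner, and its spacing.
    two_stage : bool
        If False, only the coarse grid is scanned.

    Attributes
    ----------
    best_window_s_ : float
        Selected CRR window length (seconds).
    best_mean_ltd_ : float
        Cohort mean LTD at the selected window.
    stage1_result_, stage2_result_ : WindowFitResult
        Per-window aggregate tables for each iteration (stage2_result_
        is absent when ``two_stage=False``).
    """

    def __init__(
        self,
        stage1_start_s: float = 0.0,
        stage1_stop_s: float = 20.0,
        stage1_step_s: float = 0.1,
        refine_halfwidth_s: float = 0.25,
        refine_step_s: float = 0.01,
        two_stage: bool = True,
    ):
        self.stage1_start_s = stage1_start_s
        self.stage1_stop_s = stage1_stop_s
        self.stage1_step_s = stage1_step_s
        self.refine_halfwidth_s = refine_halfwidth_s
        self.refine_step_s = refine_step_s
        self.two_stage = two_stage

    def fit(self, X: list[ForagingEventLog], y=None):
        """Fit on a cohort of event logs (one per participant)."""
        if not X:
            raise ValueError("need at least one event log")
        grid1 = window_grid(self.stage1_start_s, self.stage1_stop_s, self.stage1_step_s)
        if self.two_stage:
            self.stage1_result_, self.stage2_result_ = _two_stage(
                X, grid1, self.refine_halfwidth_s, self.refine_step_s
            )
            final = self.stage2_result_
        else:
            self.stage1_result_ = fit_optimal_window(X, grid1)
            final = self.stage1_result_
        self.best_window_s_ = final.best_window_s
        self.best_mean_ltd_ = final.best_mean_ltd
        return self

    def transform(self, X: list[ForagingEventLog]) -> np.ndarray:
        """Participant-mean LTD of each log at the selected window."""
        if not hasattr(self, "best_window_s_"):
            raise RuntimeError("WindowSelector is not fitted")
        out = [compute_ltd(log, self.best_window_s_).participant_ltd for log in X]
        return np.array([np.nan if v is None else v for v in out], dtype=float)
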