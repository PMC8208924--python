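"""Synthetic mood data with a planted linear effect on foraging change.

Participants rate their mood on a 9 x 9 affect grid (arousal x valence,
each an integer from -4 to +4) at six time points: before/after the first
foraging run (1, 2), before/after a mood induction (3, 4), and
before/after the second run (5, 6).  The generator plants a linear model

    delta_LTD = beta_a * delta_arousal + beta_v * delta_valence + eps

on standardized pre-to-post deltas, with the predictors jointly normal at
correlation rho and the residual variance chosen so the population R^2
equals the target.  The continuous deltas are also realized as integer
grid ratings whose time-point (5,6)-minus-(1,2) means reproduce the drawn
deltas up to rounding (means of two integers are multiples of 0.5) and
clipping at the grid edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MoodEffectSpec", "solve_predictor_correlation", "generate_mood_deltas"]


def solve_predictor_correlation(beta_arousal: float, beta_valence: float, r_squared: float) -> float:
    """Correlation rho making the planted model's population R^2 exact.

    Solves r_squared = b_a^2 + b_v^2 + 2*rho*b_a*b_v for rho.
    """
    denom = 2.0 * beta_arousal * beta_valence
    if denom == 0:
        raise ValueError("both betas must be nonzero to solve for rho")
    rho = (r_squared - beta_arousal**2 - beta_valence**2) / denom
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"implied correlation {rho:.4f} outside (-1, 1)")
    return rho


@dataclass(frozen=True)
class MoodEffectSpec:
    """Planted mood-to-behavior effect on standardized delta scores."""

    beta_arousal: float
    beta_valence: float
    predictor_correlation: float
    r_squared: float
    n_participants: int

    def __post_init__(self) -> None:
        if not (-1.0 < self.predictor_correlation < 1.0):
            raise ValueError("predictor_correlation must be in (-1, 1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.r_squared < 1.0):
            raise ValueError("r_squared must be in [0, 1)")
        explained = self.explained_variance
        if explained < -1e-9 or explained > 1.0 + 1e-9:
            raise ValueError(f"explained variance {explained:.4f} outside [0, 1]")
        if abs(explained - self.r_squared) > 1e-6:
            raise ValueError(
                f"inconsistent spec: betas and rho imply R^2 = {explained:.6f}, "
                f"declared r_squared = {self.r_squared:.6f}"
            )

    @property
    def explained_variance(self) -> float:
        ba, bv, rho = self.beta_arousal, self.beta_valence, self.predictor_correlation
        return ba**2 + bv**2 + 2.0 * rho * ba * bv

    @property
    def residual_variance(self) -> float:
        # clamp: float error can leave a tiny negative remainder at R^2 -> 1
        return max(0.0, 1.0 - self.explained_variance)


def _realize_pair(target_mean: float, rng: np.random.Generator) -> tuple[int, int]:
    """Two integers in [-4, 4] whose mean is as close as possible to target."""
    r1 = int(np.clip(round(target_mean), -4, 4))
    r2 = int(np.clip(round(2.0 * target_mean - r1), -4, 4))
    return r1, r2


def _ratings_table(
    deltas: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Integer 9x9 grid ratings at 6 time points realizing the deltas."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in deltas.iterrows():
        pid = rec["participant_id"]
        # baseline near the grid center so +-3 SD deltas rarely clip
        base_a = float(rng.normal(0.0, 0.8))
        base_v = float(rng.normal(0.0, 0.8))
        pre_a = _realize_pair(base_a, rng)
        pre_v = _realize_pair(base_v, rng)
        pre_a_mean = (pre_a[0] + pre_a[1]) / 2.0
        pre_v_mean = (pre_v[0] + pre_v[1]) / 2.0
        post_a = _realize_pair(pre_a_mean + rec["delta_arousal"], rng)
        post_v = _realize_pair(pre_v_mean + rec["delta_valence"], rng)
        post_a_mean = (post_a[0] + post_a[1]) / 2.0
        post_v_mean = (post_v[0] + post_v[1]) / 2.0
        # induction-adjacent ratings interpolate between pre and post
        mid_a = _realize_pair((pre_a_mean + post_a_mean) / 2.0, rng)
        mid_v = _realize_pair((pre_v_mean + post_v_mean) / 2.0, rng)
        arousal = [pre_a[0], pre_a[1], mid_a[0], mid_a[1], post_a[0], post_a[1]]
        valence = [pre_v[0], pre_v[1], mid_v[0], mid_v[1], post_v[0], post_v[1]]
        for tp in range(6):
            rows.append(
                {
                    "participant_id": pid,
                    "time_point": tp + 1,
                    "arousal": arousal[tp],
                    "valence": valence[tp],
                }
            )
    return pd.DataFrame(rows)


def generate_mood_deltas(
    spec: MoodEffectSpec,
    seed: int,
    ltd_deltas: np.ndarray | list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-participant mood deltas carrying the planted LTD effect.

    If ``ltd_deltas`` is None the LTD change scores are synthesized from
    the model; otherwise the provided per-participant LTD deltas are
    standardized and the (arousal, valence) deltas are drawn from their
    conditional distribution given the outcome, so the joint law matches
    the planted model.

    Returns ``(deltas, ratings)``: a tidy table of continuous standardized
    deltas (participant_id, delta_arousal, delta_valence, delta_ltd) and
    the integer mood-grid ratings (participant_id, time_point 1-6,
    arousal, valence).
    """
    rng = np.random.default_rng(seed)
    ba, bv, rho = spec.beta_arousal, spec.beta_valence, spec.predictor_correlation
    sigma = np.array([[1.0, rho], [rho, 1.0]])

    if ltd_deltas is None:
        n = spec.n_participants
        xv = rng.multivariate_normal([0.0, 0.0], sigma, size=n, method="cholesky")
        eps = rng.normal(0.0, np.sqrt(spec.residual_variance), size=n)
        z = ba * xv[:, 0] + bv * xv[:, 1] + eps
    else:
        z_raw = np.asarray(ltd_deltas, dtype=float)
        n = z_raw.size
        if n < 2:
            raise ValueError("need at least 2 ltd_deltas")
        sd = z_raw.std(ddof=0)
        if sd == 0:
            raise ValueError("ltd_deltas have zero variance")
        z = (z_raw - z_raw.mean()) / sd
        # conditional law of (da, dv) given the standardized outcome z:
        # cov(X, z) = c, mean = c*z, cov = sigma - c c^T
        c = np.array([ba + rho * bv, bv + rho * ba])
        cond_cov = sigma - np.outer(c, c)
        chol = np.linalg.cholesky(cond_cov)
        noise = rng.standard_normal((n, 2)) @ chol.T
        xv = np.outer(z, c) + noise

    pids = [f"P{i + 1:03d}" for i in range(n)]
    deltas = pd.DataFrame(
        {
            "participant_id": pids,
            "delta_arousal": xv[:, 0],
            "delta_valence": xv[:, 1],
            "delta_ltd": z,
        }
    )
    ratings_seed = int(rng.integers(0, 2**31))
    ratings = _ratings_table(deltas, ratings_seed)
    return deltas, ratings
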