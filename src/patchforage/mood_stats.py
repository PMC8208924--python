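"""Mood-grid statistics: delta scores, outlier fence, and regressions.

Mood is rated on a 9 x 9 affect grid (arousal and valence, integers -4 to
+4) at six time points.  Pre scores average time points 1-2, post scores
average 5-6; change (delta) scores are post minus pre.  The headline
analysis regresses delta LTD on standardized delta arousal and delta
valence, compares the base model with its interaction-augmented version
(nested F test, BIC fallback), and multiplies p values by 3 for the three
regression analyses of the family.  Participants whose LTD lies outside
Q1 - 2.2*IQR or Q3 + 2.2*IQR on either run are removed beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "DeltaRecord",
    "RegressionResult",
    "mean_mood",
    "delta_scores",
    "iqr_outlier_filter",
    "fit_delta_regression",
    "hierarchical_compare",
    "bonferroni_adjust",
    "MoodDeltaRegression",
]


@dataclass(frozen=True)
class DeltaRecord:
    """Per-participant pre-to-post change scores."""

    participant_id: str
    delta_arousal: float
    delta_valence: float
    delta_ltd: float


@dataclass
class RegressionResult:
    """OLS fit on standardized variables with family-corrected p values."""

    terms: list[str]
    beta: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    p_corrected: dict[str, float]
    r_squared: float
    f_statistic: float
    f_df: tuple[float, float]
    f_pvalue: float
    f_pvalue_corrected: float
    bic: float
    n: int


def mean_mood(
    ratings: pd.DataFrame,
    time_points: list[int] | tuple[int, ...],
    participant_id: str | None = None,
) -> tuple[float, float]:
    """Mean arousal and valence over the requested time points.

    ``ratings`` is a tidy table (participant_id, time_point, arousal,
    valence); a missing requested time point raises, naming the
    participant and the time point.
    """
    df = ratings
    if participant_id is not None:
        df = df[df["participant_id"] == participant_id]
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("mean_mood needs ratings of exactly one participant")
    pid = pids[0]
    sel = df[df["time_point"].isin(time_points)]
    present = set(sel["time_point"])
    for tp in time_points:
        if tp not in present:
            raise ValueError(f"participant {pid}: missing mood rating at time point {tp}")
    return float(sel["arousal"].mean()), float(sel["valence"].mean())


def delta_scores(
    pre: tuple[float, float],
    post: tuple[float, float],
    ltd_pre: float | None,
    ltd_post: float | None,
    participant_id: str = "",
) -> DeltaRecord:
    """Post-minus-pre change scores for arousal, valence, and LTD."""
    if ltd_pre is None or ltd_post is None:
        raise ValueError(f"participant {participant_id or '?'}: undefined LTD")
    return DeltaRecord(
        participant_id=participant_id,
        delta_arousal=post[0] - pre[0],
        delta_valence=post[1] - pre[1],
        delta_ltd=ltd_post - ltd_pre,
    )


def iqr_outlier_filter(values, k: float = 2.2) -> np.ndarray:
    """Keep mask under the k*IQR fence (True = keep).

    Quartiles use linear interpolation; values exactly at a fence are
    kept ("exceeded" is read strictly).  Requires at least 4 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 values for an IQR fence, got {v.size}")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (v >= lo) & (v <= hi)


def bonferroni_adjust(p_values, m: float = 3) -> list[float]:
    """Multiply each p by the family size m, capped at 1."""
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance variable cannot be standardized")
    return (x - x.mean()) / sd


def _fit_ols(
    df: pd.DataFrame,
    with_interaction: bool,
    correction_factor: float,
):
    y = _zscore(df["delta_ltd"].to_numpy(dtype=float))
    xa = _zscore(df["delta_arousal"].to_numpy(dtype=float))
    xv = _zscore(df["delta_valence"].to_numpy(dtype=float))
    cols = {"delta_arousal": xa, "delta_valence": xv}
    if with_interaction:
        cols["delta_arousal:delta_valence"] = _zscore(xa * xv)
    X = sm.add_constant(pd.DataFrame(cols))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    model = sm.OLS(y, X).fit()
    terms = list(cols)
    result = RegressionResult(
        terms=terms,
        beta={t: float(model.params[t]) for t in terms},
        conf_int={
            t: (float(model.conf_int().loc[t, 0]), float(model.conf_int().loc[t, 1]))
            for t in terms
        },
        p_values={t: float(model.pvalues[t]) for t in terms},
        p_corrected={
            t: bonferroni_adjust([float(model.pvalues[t])], correction_factor)[0]
            for t in terms
        },
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        f_df=(float(model.df_model), float(model.df_resid)),
        f_pvalue=float(model.f_pvalue),
        f_pvalue_corrected=bonferroni_adjust([float(model.f_pvalue)], correction_factor)[0],
        bic=float(model.bic),
        n=int(model.nobs),
    )
    return result, model


def fit_delta_regression(records, correction_factor: float = 3.0) -> RegressionResult:
    """OLS of delta LTD on standardized delta arousal and delta valence.

    All three variables are z-scored, so the reported coefficients are
    standardized betas with 95% confidence intervals; the model F test,
    R^2, BIC and family-corrected p values (x ``correction_factor``,
    capped at 1) come along.
    """
    df = _as_frame(records)
    if len(df) < 4:
        raise ValueError("need more observations than predictors + 1")
    result, _ = _fit_ols(df, with_interaction=False, correction_factor=correction_factor)
    return result


def hierarchical_compare(
    records, alpha: float = 0.05, correction_factor: float = 3.0
) -> tuple[RegressionResult, dict]:
    """Base model vs. base + interaction, chosen by nested F then BIC.

    The interaction term is tested with a nested F test at ``alpha``; if
    it does not significantly improve the fit, the model with the lower
    BIC is selected.
    """
    df = _as_frame(records)
    base, base_m = _fit_ols(df, with_interaction=False, correction_factor=correction_factor)
    full, full_m = _fit_ols(df, with_interaction=True, correction_factor=correction_factor)
    rss_b = float(base_m.ssr)
    rss_f = float(full_m.ssr)
    df_num = base_m.df_resid - full_m.df_resid
    f_stat = ((rss_b - rss_f) / df_num) / (rss_f / full_m.df_resid)
    p = float(sps.f.sf(f_stat, df_num, full_m.df_resid))
    if p < alpha:
        chosen = full
        reason = "interaction significant (nested F)"
    else:
        chosen = full if full.bic < base.bic else base
        reason = "lower BIC"
    comparison = {
        "f_statistic": float(f_stat),
        "f_df": (float(df_num), float(full_m.df_resid)),
        "p_value": p,
        "bic_base": base.bic,
        "bic_full": full.bic,
        "chosen": "full" if chosen is full else "base",
        "reason": reason,
    }
    return chosen, comparison


class MoodDeltaRegression(BaseEstimator):
    """Sklearn-style wrapper for the mood-delta regression stage.

    Parameters
    ----------
    with_interaction : {"auto", True, False}
        "auto" runs the hierarchical comparison (nested F at ``alpha``,
        then BIC); True/False force the model.
    alpha : float
        Significance level for the nested F test.
    correction_factor : float
        Multiple-comparison factor applied to reported p values.

    Attributes
    ----------
    result_ : RegressionResult
        Full fit summary of the selected model.
    coef_ : ndarray
        Standardized betas in ``result_.terms`` order.
    comparison_ : dict
        Present when ``with_interaction="auto"``.
    """

    def __init__(self, with_interaction="auto", alpha: float = 0.05, correction_factor: float = 3.0):
        self.with_interaction = with_interaction
        self.alpha = alpha
        self.correction_factor = correction_factor

    def fit(self, X, y=None):
        """Fit on a DataFrame of delta records (or X = predictors, y = delta LTD)."""
        if y is not None:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(
                {
                    "delta_arousal": X[:, 0],
                    "delta_valence": X[:, 1],
                    "delta_ltd": np.asarray(y, dtype=float),
                }
            )
        else:
            df = _as_frame(X)
        if self.with_interaction == "auto":
            self.result_, self.comparison_ = hierarchical_compare(
                df, alpha=self.alpha, correction_factor=self.correction_factor
            )
        else:
            self.result_, _ = _fit_ols(
                df,
                with_interaction=bool(self.with_interaction),
                correction_factor=self.correction_factor,
            )
        self.coef_ = np.array([self.result_.beta[t] for t in self.result_.terms])
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted standardized delta LTD for standardized predictors."""
        if not hasattr(self, "result_"):
            raise RuntimeError("MoodDeltaRegression is not fitted")
        X = np.asarray(X, dtype=float)
        beta = self.coef_[:2]
        return X @ beta
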