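"""Cumulative-gas summaries, dose-response trend, and many-to-one (Dunnett)
comparisons of invaded treatments against a pure-community control.

The many-to-one procedure controls the family-wise error rate with the
multivariate-t distribution of the maximum |t| statistic under the classic
equal-variance model: with a pooled variance estimate on :math:`\\nu`
degrees of freedom, the vector of treatment-vs-control t statistics is
multivariate t with correlations
:math:`\\rho_{ij} = \\sqrt{\\lambda_i \\lambda_j},\\;
\\lambda_i = n_i / (n_i + n_0)`. Adjusted p-values are computed by seeded
Monte-Carlo integration of the max-|t| tail (reproducible and testable,
rather than edition-dependent table lookups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .tables_io import GasSeries, SampleMetadata, TREATMENT_DOSE

__all__ = [
    "GasSummary",
    "summarize_gas",
    "TrendResult",
    "dose_trend",
    "many_to_one",
]


@dataclass
class GasSummary:
    per_sample: pd.DataFrame  # sample_id, treatment, replicate, total_gas
    weekly_treatment_means: pd.DataFrame  # treatment, week, mean_cumulative_gas


def summarize_gas(gas: GasSeries, metadata: SampleMetadata) -> GasSummary:
    """Per-sample final cumulative totals plus per-treatment weekly means.

    ``GasSeries`` validation already guarantees per-sample monotonicity, so
    the final week's cumulative value equals the series maximum.
    """
    meta = metadata.frame.loc[:, ["sample_id", "treatment", "replicate"]]
    merged = gas.frame.merge(meta, on="sample_id", how="left")
    if merged["treatment"].isna().any():
        missing = sorted(merged.loc[merged["treatment"].isna(), "sample_id"].unique())
        raise ValidationError(f"gas sample(s) without metadata: {missing}")
    finals = (
        merged.sort_values("week")
        .groupby(["sample_id", "treatment", "replicate"], as_index=False)
        .last()
        .rename(columns={"cumulative_gas_ml": "total_gas"})
        .loc[:, ["sample_id", "treatment", "replicate", "total_gas"]]
    )
    weekly = (
        merged.groupby(["treatment", "week"], as_index=False)["cumulative_gas_ml"]
        .mean()
        .rename(columns={"cumulative_gas_ml": "mean_cumulative_gas"})
    )
    return GasSummary(per_sample=finals, weekly_treatment_means=weekly)


@dataclass
class TrendResult:
    slope: float
    F: float
    df_num: int
    df_den: int
    p: float
    r2: float
    predictor: str  # "log10_dose" or "dose"


def dose_trend(
    summary: GasSummary,
    doses: dict[str, float] | None = None,
    predictor: str = "log10_dose",
) -> TrendResult:
    """OLS of per-sample total gas on (log10) dose across invaded samples.

    Doses span three orders of magnitude, so the default predictor is
    log10(dose); ``predictor="dose"`` fits the raw scale instead.
    """
    doses = doses or TREATMENT_DOSE
    data = summary.per_sample[summary.per_sample["treatment"].isin(doses)].copy()
    if data["treatment"].nunique() < 3:
        raise ConfigurationError("dose trend needs >= 3 distinct doses")
    x = data["treatment"].map(doses).astype(float)
    if predictor == "log10_dose":
        x = np.log10(x)
    elif predictor != "dose":
        raise ConfigurationError(f"unknown predictor {predictor!r}")
    y = data["total_gas"].to_numpy()
    if np.ptp(y) == 0:  # constant response: no trend, degenerate R2
        return TrendResult(0.0, 0.0, 1, y.size - 2, 1.0, 0.0, predictor)
    model = sm.OLS(y, sm.add_constant(x.to_numpy())).fit()
    return TrendResult(
        slope=float(model.params[1]),
        F=float(model.fvalue),
        df_num=int(model.df_model),
        df_den=int(model.df_resid),
        p=float(model.f_pvalue),
        r2=float(model.rsquared),
        predictor=predictor,
    )


def _max_abs_t_sample(
    lam: np.ndarray, df: int, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    T_i = (sqrt(lam_i) Z0 + sqrt(1-lam_i) Z_i) / (chi_df / sqrt(df)) gives
    exactly the correlation structure rho_ij = sqrt(lam_i lam_j).
    """
    z0 = rng.standard_normal(n_mc)[:, None]
    zi = rng.standard_normal((n_mc, lam.size))
    t = np.sqrt(lam) * z0 + np.sqrt(1.0 - lam) * zi
    denom = np.sqrt(rng.chisquare(df, n_mc) / df)[:, None]
    return np.abs(t / denom).max(axis=1)


def many_to_one(
    summary: GasSummary,
    control_treatment: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare every non-control treatment's mean total gas to the control.

    Returns one row per treatment with the mean difference, t statistic,
    raw and family-wise adjusted p-values, and a verdict at ``alpha``.
    Adjusted p is P(max_i |T_i| >= |t_obs|) under the multivariate-t null.
    """
    data = summary.per_sample
    groups = {t: g["total_gas"].to_numpy() for t, g in data.groupby("treatment")}
    if control_treatment not in groups:
        raise ConfigurationError(f"control treatment {control_treatment!r} missing")
    control = groups.pop(control_treatment)
    if control.size < 2:
        raise ConfigurationError("control needs >= 2 replicates")
    names = sorted(groups)
    ns = np.array([groups[t].size for t in names])
    n0 = control.size
    # pooled within-group variance over all groups including the control
    all_groups = [control] + [groups[t] for t in names]
    df = int(sum(g.size for g in all_groups) - len(all_groups))
    ss = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    s2 = ss / df if df > 0 else 0.0

    diffs = np.array([groups[t].mean() - control.mean() for t in names])
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, diffs / se, np.where(diffs == 0, 0.0, np.inf))

    lam = ns / (ns + n0)
    rng = np.random.default_rng(seed)
    max_t = _max_abs_t_sample(lam, df, n_mc, rng)
    p_adj = np.array([(max_t >= abs(t)).mean() for t in tstats])
    p_raw = 2 * stats.t.sf(np.abs(tstats), df)
    p_adj = np.maximum(p_adj, p_raw)  # MC tail never below the single test
    return pd.DataFrame(
        {
            "treatment": names,
            "control": control_treatment,
            "mean_diff": diffs,
            "t": tstats,
            "df": df,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
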