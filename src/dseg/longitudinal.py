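"""Longitudinal change models and two-stage slope regressions.

Stage one fits a linear mixed-effects model of each outcome on time
(random intercept + random slope per subject, maximum likelihood) and
extracts empirical-Bayes per-subject annualised slopes.  Stage two
regresses those slopes on baseline angle score, angle change and
covariates with ordinary least squares.  Imaging-derived outcomes are
observed on a shorter window than cognition, so each fit takes an optional
``max_time`` truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["LmeFit", "SlopeRegressionFit", "fit_lme_change", "extract_subject_slopes", "regress_slopes"]


@dataclass
class LmeFit:
    outcome: str
    fixed_intercept: float
    fixed_slope: float
    slope_se: float
    wald_stat: float
    wald_p: float
    re_variances: dict[str, float]
    subject_slopes: pd.Series  # empirical-Bayes annualised slope per subject
    subject_intercepts: pd.Series
    converged: bool
    random_slope_dropped: bool = False
    n_subjects: int = 0
    n_obs: int = 0

    def conf_int_slope(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.fixed_slope - z * self.slope_se, self.fixed_slope + z * self.slope_se)


@dataclass
class SlopeRegressionFit:
    outcome: str
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    r_squared: float
    n: int
    model: object = field(repr=False, default=None)


def _mixedlm(df: pd.DataFrame, outcome: str, random_slope: bool, reml: bool):
    model = sm.MixedLM.from_formula(
        f"{outcome} ~ visit_time",
        groups="subject_id",
        re_formula="~visit_time" if random_slope else "~1",
        data=df,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=reml, method=["lbfgs", "bfgs"])


def fit_lme_change(
    cohort: pd.DataFrame,
    outcome: str,
    max_time: float | None = None,
    reml: bool = False,
) -> LmeFit:
    """Random-intercept + random-slope model of ``outcome`` on visit time.

    Maximum-likelihood estimation by default; the Wald statistic is the
    squared z-ratio of the time fixed effect.  A singular random-effects
    covariance triggers a flagged fall-back to a random-intercept-only
    model.
    """
    required = {"subject_id", "visit_time", outcome}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    df = cohort.dropna(subset=[outcome, "visit_time"]).copy()
    if max_time is not None:
        df = df[df["visit_time"] <= max_time + 1e-9]
    n_multi = (df.groupby("subject_id")["visit_time"].nunique() >= 2).sum()
    if df["subject_id"].nunique() < 2 or n_multi < 2:
        raise ValueError("need >=2 subjects with >=2 visits to model change")

    dropped = False
    try:
        result = _mixedlm(df, outcome, random_slope=True, reml=reml)
    except (np.linalg.LinAlgError, ValueError):
        result = None
    degenerate = result is None
    if result is not None:
        try:
            cov_re = np.asarray(result.cov_re)
            se_ok = np.isfinite(float(result.bse_fe["visit_time"]))
            degenerate = (
                not result.converged
                or not se_ok
                or (cov_re.shape[0] > 1 and (cov_re[1, 1] <= 1e-12 or np.linalg.det(cov_re) < 0))
            )
        except Exception:  # pragma: no cover - defensive
            degenerate = True
    if degenerate:
        try:
            result = _mixedlm(df, outcome, random_slope=False, reml=reml)
            dropped = True
        except (np.linalg.LinAlgError, ValueError):
            if result is None:
                raise
            # keep the boundary random-slope fit rather than fail outright

    fe = result.fe_params
    slope = float(fe["visit_time"])
    se = float(result.bse_fe["visit_time"])
    if se > 0 and np.isfinite(se):
        z = slope / se
    else:
        z = 0.0 if abs(slope) < 1e-12 else np.inf
    wald = float(z * z)
    wald_p = float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else 0.0

    subjects = list(df["subject_id"].unique())
    try:
        re = result.random_effects
        intercepts = pd.Series(
            {s: float(fe["Intercept"]) + float(re[s].iloc[0]) for s in subjects}, name="intercept"
        )
        if not dropped:
            slopes = pd.Series({s: slope + float(re[s].iloc[1]) for s in subjects}, name="slope")
        else:
            slopes = pd.Series({s: slope for s in subjects}, name="slope")
    except (ValueError, np.linalg.LinAlgError):
        # degenerate random-effects covariance: EB predictions collapse to
        # the fixed effects
        intercepts = pd.Series({s: float(fe["Intercept"]) for s in subjects}, name="intercept")
        slopes = pd.Series({s: slope for s in subjects}, name="slope")

    cov_re = np.asarray(result.cov_re)
    re_var = {"intercept": float(cov_re[0, 0]), "residual": float(result.scale)}
    if cov_re.shape[0] > 1:
        re_var["slope"] = float(cov_re[1, 1])
        re_var["intercept_slope_cov"] = float(cov_re[0, 1])

    return LmeFit(
        outcome=outcome,
        fixed_intercept=float(fe["Intercept"]),
        fixed_slope=slope,
        slope_se=se,
        wald_stat=wald,
        wald_p=wald_p,
        re_variances=re_var,
        subject_slopes=slopes,
        subject_intercepts=intercepts,
        converged=bool(result.converged),
        random_slope_dropped=dropped,
        n_subjects=int(df["subject_id"].nunique()),
        n_obs=len(df),
    )


def extract_subject_slopes(fit: LmeFit) -> pd.Series:
    """Empirical-Bayes annualised slope per subject (fixed + predicted random)."""
    return fit.subject_slopes.copy()


def regress_slopes(
    cog_slopes: pd.Series,
    theta_baseline: pd.Series,
    theta_slopes: pd.Series,
    covariates: pd.DataFrame,
    outcome_name: str = "slope",
    center_age: bool = True,
) -> SlopeRegressionFit:
    """OLS of per-subject cognitive slopes on baseline angle, angle change
    and covariates (age mean-centred by default, plus premorbid IQ and sex).
    """
    data = pd.DataFrame(
        {
            "y": cog_slopes,
            "theta_baseline": theta_baseline,
            "theta_slope": theta_slopes,
        }
    ).join(covariates, how="inner")
    data = data.dropna()
    if center_age and "age_baseline" in data.columns:
        data["age_baseline"] = data["age_baseline"] - data["age_baseline"].mean()

    predictors = ["theta_baseline", "theta_slope"] + [c for c in covariates.columns]
    X = sm.add_constant(data[predictors])
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = np.corrcoef(data[predictors].values, rowvar=False)
        bad = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or predictors}")

    res = sm.OLS(data["y"], X).fit()
    return SlopeRegressionFit(
        outcome=outcome_name,
        params=res.params,
        pvalues=res.pvalues,
        bse=res.bse,
        r_squared=float(res.rsquared),
        n=len(data),
        model=res,
    )
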