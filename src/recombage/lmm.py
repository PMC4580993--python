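"""Per-cohort linear mixed models and fixed-effects meta-analysis.

Each cohort is fitted separately with a random-intercept model

    Y_ij = mu + beta_age * age_ij + alpha_j + eps_ij,

where alpha_j ~ N(0, sigma2_alpha) is the parent effect and eps_ij ~
N(0, sigma2_eps). Variance components are estimated by REML (statsmodels
MixedLM). Per-cohort slopes are then combined with an inverse-variance
fixed-effects meta-analysis, with Cochran's Q testing homogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm


@dataclass
class LmmFit:
    """REML estimates for one cohort's random-intercept model."""

    cohort: str
    beta_age_hat: float
    se_beta: float
    mu_hat: float
    sigma2_alpha_hat: float
    sigma2_eps_hat: float
    n_meioses: int
    n_parents: int
    p_value: float
    df: float


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects combination of per-cohort slopes."""

    beta_combined: float
    se_combined: float
    z: float
    p_value: float
    cochran_q: float
    q_df: int
    q_p_value: float
    n_cohorts: int


class CohortLMM:
    """Random-intercept linear mixed model for one cohort's meioses.

    Parameters
    ----------
    meioses : DataFrame with columns parent_id, parent_age_years,
        n_crossovers (one cohort; pass a filtered table).
    df_convention : degrees of freedom for the slope t-test; default is the
        within-parent residual convention n_meioses - n_parents - 1.
    """

    def __init__(self, meioses: pd.DataFrame, df_convention: str = "residual"):
        if meioses["parent_id"].nunique() < 2:
            raise ValueError("need >=2 parents to fit a mixed model")
        if not (meioses.groupby("parent_id").size() >= 2).any():
            raise ValueError("need at least one parent with >=2 children")
        ages = meioses["parent_age_years"].to_numpy(dtype=float)
        if np.ptp(ages) == 0:
            raise ValueError("singular design: all parental ages identical")
        self.meioses = meioses.reset_index(drop=True)
        self.df_convention = df_convention

    def fit(self) -> LmmFit:
        df = self.meioses
        y = df["n_crossovers"].to_numpy(dtype=float)
        age = df["parent_age_years"].to_numpy(dtype=float)
        X = sm.add_constant(age)
        groups = df["parent_id"].to_numpy()
        n, n_parents = len(df), df["parent_id"].nunique()

        boundary = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups)
                res = model.fit(reml=True, method=["lbfgs", "powell"])
            sigma2_alpha = float(np.asarray(res.cov_re)[0, 0])
            sigma2_eps = float(res.scale)
            beta, se = float(res.fe_params[1]), float(np.asarray(res.bse_fe)[1])
            mu = float(res.fe_params[0])
            if not np.isfinite(se):
                boundary = True
        except np.linalg.LinAlgError:
            # REML optimum at the zero-variance boundary can make the mixed
            # model information matrix singular; the GLS fit then reduces
            # to OLS.
            boundary = True
            sigma2_alpha = 0.0

        # Boundary truncation: when the REML optimum puts the parent-effect
        # variance at (numerically) zero, the GLS fixed effects reduce to
        # OLS; recompute them there so the zero-variance case is exact.
        if boundary or sigma2_alpha <= 1e-8 * max(sigma2_eps, 1e-12):
            sigma2_alpha = 0.0
            ols = sm.OLS(y, X).fit()
            beta, se = float(ols.params[1]), float(ols.bse[1])
            mu = float(ols.params[0])
            sigma2_eps = float(ols.scale)

        dof = float(n - n_parents - 1) if self.df_convention == "residual" else float(n - 2)
        dof = max(dof, 1.0)
        tstat = beta / se
        p = 2.0 * stats.t.sf(abs(tstat), dof)
        cohort = str(df["cohort"].iloc[0]) if "cohort" in df.columns else ""
        return LmmFit(
            cohort=cohort, beta_age_hat=beta, se_beta=se, mu_hat=mu,
            sigma2_alpha_hat=sigma2_alpha, sigma2_eps_hat=sigma2_eps,
            n_meioses=n, n_parents=n_parents, p_value=float(p), df=dof,
        )


def fit_lmm(meioses: pd.DataFrame, df_convention: str = "residual") -> LmmFit:
    """Fit the random-intercept model to one cohort's meioses."""
    return CohortLMM(meioses, df_convention=df_convention).fit()


def fit_all_cohorts(
    meioses: pd.DataFrame, min_meioses: int = 20, df_convention: str = "residual"
) -> list[LmmFit]:
    """Per-cohort LMM fits, skipping cohorts below the meiosis threshold."""
    fits = []
    for cohort, grp in meioses.groupby("cohort", sort=True):
        if len(grp) < min_meioses:
            continue
        fits.append(fit_lmm(grp, df_convention=df_convention))
    return fits


def meta_fixed_effects(fits: list[LmmFit]) -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis with Cochran's Q."""
    if len(fits) < 2:
        raise ValueError("need >=2 cohort fits for a meta-analysis")
    b = np.array([f.beta_age_hat for f in fits], dtype=float)
    se = np.array([f.se_beta for f in fits], dtype=float)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_comb = float(np.sum(w) ** -0.5)
    z = beta / se_comb
    p = 2.0 * stats.norm.sf(abs(z))
    q = float(np.sum(w * (b - beta) ** 2))
    q_df = len(fits) - 1
    q_p = float(stats.chi2.sf(q, q_df))
    return MetaResult(
        beta_combined=beta, se_combined=se_comb, z=float(z), p_value=float(p),
        cochran_q=q, q_df=q_df, q_p_value=q_p, n_cohorts=len(fits),
    )


def fits_to_frame(fits: list[LmmFit]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fits])
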