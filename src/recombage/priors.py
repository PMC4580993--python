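"""Prior construction for the hierarchical crossover-count models.

Conjugate-family priors with partly empirical-Bayes hyperparameters:

- beta_age ~ N(0, 1) (previously reported effects ranged roughly -0.5..0.2
  crossovers/year, so a unit-normal prior is weakly informative on either
  the additive or the log scale);
- mu_c ~ N(41, 100) for maternal counts under the normal likelihood (41 is
  the canonical female crossover count); under the negative-binomial
  likelihood the mean is log-transformed (log 41 ~ 3.7) while the variance
  is kept large (100): a tight prior on mu_c leaks into beta_age through
  the shared age term, so only the location is transformed; paternal means
  default to the empirical mean;
- sigma2 (variance of parent effects) ~ InverseGamma, scale solved so the
  central 95% prior interval covers the empirical variances of per-parent
  mean counts across cohorts (shape starts at 3 and is relaxed if the
  empirical spread is too wide for that shape);
- tau2 (residual variance, normal model only) ~ InverseGamma with prior
  mean equal to the empirical count variance over fully informative
  meioses;
- omega (overdispersion, negative-binomial only): uniform prior on 1/omega
  over (0, 1), constraining omega to (1, inf);
- per-cohort age-effect models add beta_global ~ N(0,1) and sigma2_beta ~
  InverseGamma with prior mean (0.1)^2 (additive scale; delta-adjusted for
  the log scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import FULLY_INFORMATIVE_CONFIGS

MATERNAL_MEAN_COUNT = 41.0
MU_PRIOR_VARIANCE = 100.0
DEFAULT_SHAPE = 3.0


@dataclass
class PriorSet:
    """Numeric hyperparameters plus prior-family switches.

    ``sigma_prior`` is "invgamma" (default) or "flat_sigma" (improper flat
    on sigma, used in robustness reruns); ``omega_prior`` is "uniform_inv"
    (default U(0,1) on 1/omega) or "half_cauchy" (on omega-1, robustness);
    ``mu_prior``/``beta_prior`` stay normal with the given moments.
    """

    beta_mean: float = 0.0
    beta_var: float = 1.0
    mu_mean: float = MATERNAL_MEAN_COUNT
    mu_var: float = MU_PRIOR_VARIANCE
    sigma2_shape: float = DEFAULT_SHAPE
    sigma2_scale: float = 2.0
    tau2_shape: float = DEFAULT_SHAPE
    tau2_scale: float = 2.0
    beta_global_mean: float = 0.0
    beta_global_var: float = 1.0
    sigma2_beta_shape: float = DEFAULT_SHAPE
    sigma2_beta_scale: float = 0.02
    sigma_prior: str = "invgamma"
    omega_prior: str = "uniform_inv"
    omega_cauchy_scale: float = 25.0

    def __post_init__(self) -> None:
        for name in ("beta_var", "mu_var", "sigma2_shape", "sigma2_scale",
                     "tau2_shape", "tau2_scale", "beta_global_var",
                     "sigma2_beta_shape", "sigma2_beta_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _invgamma_scale_covering(
    variances: np.ndarray, shape: float = DEFAULT_SHAPE
) -> tuple[float, float]:
    """Shape/scale of an inverse-gamma whose central 95% interval covers
    the given empirical variances.

    Inverse-gamma quantiles scale linearly in the scale parameter, so for a
    fixed shape the 2.5% condition bounds the scale above and the 97.5%
    condition bounds it below; if the spread is too wide for the starting
    shape, the shape is relaxed (heavier tails) until feasible.
    """
    v_lo, v_hi = float(np.min(variances)), float(np.max(variances))
    a = float(shape)
    for _ in range(40):
        q_lo = stats.invgamma.ppf(0.025, a)  # scale-1 quantiles
        q_hi = stats.invgamma.ppf(0.975, a)
        b_min = v_hi / q_hi  # 97.5% quantile must reach v_hi
        b_max = v_lo / q_lo  # 2.5% quantile must stay below v_lo
        if b_min <= b_max:
            return a, float(np.sqrt(b_min * b_max))
        a *= 0.8
        if a < 1.05:
            a = 1.05
            break
    q_lo = stats.invgamma.ppf(0.025, a)
    q_hi = stats.invgamma.ppf(0.975, a)
    b = float(np.sqrt((v_hi / q_hi) * (v_lo / q_lo)))
    warnings.warn(
        "inverse-gamma hyperprior could not cover the empirical variance "
        "range at any shape >= 1.05; using best-effort scale", stacklevel=2
    )
    return a, b


def build_priors(meioses: pd.DataFrame, spec) -> PriorSet:
    """Empirical-Bayes prior set for a model spec on a meiosis table.

    ``spec`` is a :class:`~recombage.hierarchical.ModelSpec`. The table
    should already be restricted to the relevant parent sex and filtered by
    the exclusion rules.
    """
    if meioses.empty:
        raise ValueError("meiosis table is empty")
    if meioses["cohort"].nunique() < 2:
        raise ValueError(
            "need >=2 cohorts to construct the sigma2 hyperprior empirically"
        )
    negbin = spec.likelihood == "negative_binomial"
    counts = meioses["n_crossovers"].to_numpy(dtype=float)

    # mu prior: canonical maternal mean, empirical paternal mean.
    if spec.parent_sex == "F":
        mu_mean = MATERNAL_MEAN_COUNT
    else:
        mu_mean = float(counts.mean())
    mu_var = MU_PRIOR_VARIANCE
    if negbin:
        # only the location is transformed; the variance stays large so the
        # mu prior cannot leak into the age effect
        mu_mean = float(np.log(mu_mean))

    # sigma2 hyperprior: cover the empirical variances of per-parent mean
    # counts, per cohort (log scale for the negative-binomial models).
    per_parent = meioses.groupby(["cohort", "parent_id"])["n_crossovers"].mean()
    if negbin:
        per_parent = np.log(np.maximum(per_parent, 0.5))
    emp_vars = per_parent.groupby(level="cohort").var(ddof=1).dropna()
    emp_vars = emp_vars[emp_vars > 0]
    if len(emp_vars) < 2:
        raise ValueError("need >=2 cohorts with estimable parent-mean variances")
    s_shape, s_scale = _invgamma_scale_covering(emp_vars.to_numpy())

    # tau2 prior mean = empirical count variance over fully informative
    # meioses (falls back to all meioses if none are fully informative).
    fully = meioses[meioses["configuration"].isin(FULLY_INFORMATIVE_CONFIGS)]
    var_src = fully if len(fully) >= 2 else meioses
    emp_var = float(var_src["n_crossovers"].to_numpy(dtype=float).var(ddof=1))
    tau2_shape = DEFAULT_SHAPE
    tau2_scale = (tau2_shape - 1.0) * emp_var

    # Per-cohort age-effect spread: prior mean (0.1)^2, delta-adjusted on
    # the log scale (0.1 / baseline)^2.
    sb_shape = DEFAULT_SHAPE
    sb_mean = (0.1 / np.exp(mu_mean)) ** 2 if negbin else 0.01
    sb_scale = (sb_shape - 1.0) * sb_mean

    return PriorSet(
        mu_mean=mu_mean, mu_var=mu_var,
        sigma2_shape=s_shape, sigma2_scale=s_scale,
        tau2_shape=tau2_shape, tau2_scale=tau2_scale,
        sigma2_beta_shape=sb_shape, sigma2_beta_scale=sb_scale,
    )


def uninformative_variant(priors: PriorSet, parameter: str) -> PriorSet:
    """Replace one block's prior with a flat/very-wide alternative.

    Used by the robustness reruns: "beta" -> N(0, 100^2); "mu" -> same mean,
    variance 1e4; "sigma" -> improper flat on sigma; "omega" -> half-Cauchy
    on omega-1 in place of U(0,1) on 1/omega.
    """
    if parameter == "beta":
        return replace(priors, beta_var=1e4, beta_global_var=1e4)
    if parameter == "mu":
        return replace(priors, mu_var=1e4)
    if parameter == "sigma":
        return replace(priors, sigma_prior="flat_sigma")
    if parameter == "omega":
        return replace(priors, omega_prior="half_cauchy")
    raise ValueError(f"unknown relaxable parameter {parameter!r}")
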