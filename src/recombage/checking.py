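"""Posterior predictive checks and frequentist calibration of the
Bayesian credible intervals.

Posterior predictive checks re-simulate datasets of the same size and
design as the observed data — starting from the top of the hierarchy, so
parent effects are redrawn from their group distribution — either from the
single highest-posterior draw or from many draws of the joint posterior,
and compare summary statistics (median, minimum, skewness as the asymmetry
measure) and ECDF envelopes between observed and replicated data.

Calibration estimates coverage (gamma: the credible interval contains the
simulating beta_age) and power (pi: the interval excludes 0) by repeated
simulate-and-refit, with parameter sets resampled either from binned
posterior draws (the frequentist-properties assessment) or from the prior
(simulation-based calibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchical import (
    ConvergenceError,
    CrossoverAgeResults,
    HierarchicalCrossoverModel,
)
from .posterior import CrossoverLogPosterior

DEFAULT_STATS = ("median", "min", "skewness")

_STAT_FUNCS = {
    "median": np.median,
    "min": np.min,
    "max": np.max,
    "mean": np.mean,
    "skewness": lambda x: float(stats.skew(x)),
}


@dataclass
class PpcResult:
    """Observed-vs-replicated summary statistics and ECDF envelopes."""

    observed_stats: dict[str, float]
    replicate_stats: dict[str, np.ndarray]
    ecdf_grid: np.ndarray
    ecdf_low: np.ndarray
    ecdf_high: np.ndarray
    ecdf_observed: np.ndarray
    tail_probabilities: dict[str, float]
    n_replicates: int
    mode: str

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for name, obs in self.observed_stats.items():
            rep = self.replicate_stats[name]
            rows.append({
                "statistic": name, "observed": obs,
                "replicate_mean": float(np.mean(rep)),
                "replicate_q2.5": float(np.quantile(rep, 0.025)),
                "replicate_q97.5": float(np.quantile(rep, 0.975)),
                "tail_probability": self.tail_probabilities[name],
            })
        return pd.DataFrame(rows)


def simulate_replicate(
    post: CrossoverLogPosterior, params: dict, rng: np.random.Generator
) -> np.ndarray:
    """One replicated dataset from the top of the hierarchy.

    Parent effects are redrawn from N(mu_g, sigma2_g); counts then follow
    the model likelihood on the observed design (ages, family structure).
    Normal-model replicates are left continuous and unbounded, as the model
    itself is.
    """
    d = post.data
    mu = np.asarray(params["mu"], dtype=float)
    sigma = np.sqrt(np.asarray(params["sigma2"], dtype=float))
    alpha = rng.normal(mu[d.group_of_parent], sigma[d.group_of_parent])
    beta = params["beta"]
    if post.per_cohort_beta:
        beta_m = np.asarray(beta)[post.cohort_of_meiosis]
    else:
        beta_m = float(beta)
    eta = beta_m * d.age + alpha[d.parent_of_meiosis]
    if post.likelihood == "normal":
        return rng.normal(eta, np.sqrt(params["tau2"]))
    from .simulate import negative_binomial_counts

    mean = np.exp(np.clip(eta, -30, 30))
    return negative_binomial_counts(mean, float(params["omega"]), rng).astype(float)


def posterior_predictive_check(
    results: CrossoverAgeResults,
    n_replicates: int = 1000,
    mode: str = "map_draw",
    statistics: tuple[str, ...] = DEFAULT_STATS,
    seed: int = 0,
) -> PpcResult:
    """Compare observed counts to model-replicated datasets.

    ``mode`` is "map_draw" (all replicates from the single highest-log-
    posterior draw) or "posterior_draws" (each replicate from a distinct
    draw of the joint posterior).
    """
    if mode not in ("map_draw", "posterior_draws"):
        raise ValueError(f"unknown mode {mode!r}")
    post = results.model.posterior
    observed = post.data.y
    rng = np.random.default_rng(seed)

    if mode == "map_draw":
        param_sets = [results.map_draw()] * n_replicates
    else:
        n_c, n_d = results.lp.shape
        total = n_c * n_d
        replace = total < n_replicates
        idx = rng.choice(total, size=n_replicates, replace=replace)
        param_sets = [
            post.unpack(results.raw_draws[c, i])
            for c, i in zip(idx // n_d, idx % n_d)
        ]

    funcs = {name: _STAT_FUNCS[name] for name in statistics}
    obs_stats = {name: float(f(observed)) for name, f in funcs.items()}
    rep_stats = {name: np.empty(n_replicates) for name in statistics}

    lo = np.floor(observed.min()) - 1
    hi = np.ceil(observed.max()) + 1
    grid = np.linspace(lo, hi, 101)
    ecdf_obs = np.searchsorted(np.sort(observed), grid, side="right") / len(observed)
    ecdf_min = np.ones_like(grid)
    ecdf_max = np.zeros_like(grid)

    for r in range(n_replicates):
        y_rep = simulate_replicate(post, param_sets[r], rng)
        for name, f in funcs.items():
            rep_stats[name][r] = f(y_rep)
        e = np.searchsorted(np.sort(y_rep), grid, side="right") / len(y_rep)
        ecdf_min = np.minimum(ecdf_min, e)
        ecdf_max = np.maximum(ecdf_max, e)

    tails = {
        name: float(np.mean(rep_stats[name] >= obs_stats[name]))
        for name in statistics
    }
    return PpcResult(
        observed_stats=obs_stats, replicate_stats=rep_stats,
        ecdf_grid=grid, ecdf_low=ecdf_min, ecdf_high=ecdf_max,
        ecdf_observed=ecdf_obs, tail_probabilities=tails,
        n_replicates=n_replicates, mode=mode,
    )


# ---------------------------------------------------------------------------
# Coverage / power
# ---------------------------------------------------------------------------


def credible_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Central credible interval at the given level."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(draws).ravel(), [a, 1.0 - a])
    return float(lo), float(hi)


def interval_covers(lo: float, hi: float, value: float) -> bool:
    return lo <= value <= hi


def interval_excludes_zero(lo: float, hi: float) -> bool:
    return lo > 0.0 or hi < 0.0


@dataclass
class CalibrationResult:
    """Per-bin (or overall) coverage gamma and power pi at each level."""

    table: pd.DataFrame
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def coverage(self, level: float) -> float:
        sub = self.table[np.isclose(self.table["level"], level)]
        w = sub["n_sims"].to_numpy(dtype=float)
        return float(np.sum(sub["gamma"].to_numpy() * w) / np.sum(w))

    def power(self, level: float) -> float:
        sub = self.table[np.isclose(self.table["level"], level)]
        w = sub["n_sims"].to_numpy(dtype=float)
        return float(np.sum(sub["pi"].to_numpy() * w) / np.sum(w))


def _refit_and_score(
    template: HierarchicalCrossoverModel,
    y_new: np.ndarray,
    beta_true: float,
    levels: tuple[float, ...],
    seed: int,
    n_chains: int,
    n_draws: int,
) -> dict | None:
    meioses = template.meioses.copy()
    meioses["n_crossovers"] = (
        y_new if template.spec.likelihood == "negative_binomial"
        else np.asarray(y_new, dtype=float)
    )
    model = HierarchicalCrossoverModel(
        meioses, template.spec, priors=template.priors, apply_selection=False
    )
    try:
        res = model.fit(n_chains=n_chains, n_draws=n_draws, seed=seed, max_extensions=1)
    except (ConvergenceError, ValueError) as exc:
        warnings.warn(f"calibration refit failed: {exc}", stacklevel=2)
        return None
    beta_name = (
        "beta_age" if not model.posterior.per_cohort_beta else "beta_age_global"
    )
    draws = res.get(beta_name)
    rec: dict = {"beta_true": beta_true}
    for lv in levels:
        lo, hi = credible_interval(draws, lv)
        rec[f"covered_{lv}"] = interval_covers(lo, hi, beta_true)
        rec[f"excludes0_{lv}"] = interval_excludes_zero(lo, hi)
    return rec


def _records_to_table(records: pd.DataFrame, levels, by_bin: bool) -> pd.DataFrame:
    rows = []
    groups = records.groupby("bin") if by_bin else [(0, records)]
    for b, grp in groups:
        for lv in levels:
            rows.append({
                "bin": b, "level": lv,
                "gamma": float(grp[f"covered_{lv}"].mean()),
                "pi": float(grp[f"excludes0_{lv}"].mean()),
                "n_sims": len(grp),
            })
    return pd.DataFrame(rows)


def coverage_power_assessment(
    results: CrossoverAgeResults,
    levels: tuple[float, ...] = (0.95,),
    n_bins: int = 10,
    sets_per_bin: int = 100,
    seed: int = 0,
    min_draws_per_bin: int = 1000,
    refit_chains: int = 2,
    refit_draws: int = 2000,
) -> CalibrationResult:
    """Frequentist coverage/power of the credible intervals.

    beta_age draws are split into ``n_bins`` equal-count bins (each must
    hold at least ``min_draws_per_bin`` draws); within each bin,
    ``sets_per_bin`` full parameter sets are resampled with replacement,
    each simulates a dataset on the observed design, the model is refitted
    (reduced MCMC by default, R-hat rule intact), and the credible interval
    is scored against the simulating beta_age (coverage) and against zero
    (power).
    """
    post = results.model.posterior
    beta_name = "beta_age" if not post.per_cohort_beta else "beta_age_global"
    beta_flat = results.get(beta_name).ravel()
    n_total = beta_flat.size
    if n_total < n_bins * min_draws_per_bin:
        raise ValueError(
            f"insufficient draws: {n_total} < {n_bins} bins x "
            f"{min_draws_per_bin} draws/bin"
        )
    order = np.argsort(beta_flat)
    bin_assign = np.minimum((np.arange(n_total) * n_bins) // n_total, n_bins - 1)
    rng = np.random.default_rng(seed)
    n_d = results.raw_draws.shape[1]

    records = []
    sim_seed = 0
    for b in range(n_bins):
        flat_idx = order[bin_assign == b]
        pick = rng.choice(flat_idx, size=sets_per_bin, replace=True)
        for k in pick:
            params = post.unpack(results.raw_draws[k // n_d, k % n_d])
            beta_true = (
                float(params["beta_global"]) if post.per_cohort_beta
                else float(params["beta"])
            )
            y_new = simulate_replicate(post, params, rng)
            sim_seed += 1
            rec = _refit_and_score(
                results.model, y_new, beta_true, levels,
                seed=int(rng.integers(2**31 - 1)),
                n_chains=refit_chains, n_draws=refit_draws,
            )
            if rec is not None:
                rec["bin"] = b
                records.append(rec)
    records = pd.DataFrame(records)
    return CalibrationResult(
        table=_records_to_table(records, levels, by_bin=True), records=records
    )


def simulation_based_calibration(
    template: HierarchicalCrossoverModel,
    n_sims: int = 100,
    levels: tuple[float, ...] = (0.9, 0.95),
    seed: int = 0,
    beta_true: float | None = None,
    n_chains: int = 2,
    n_draws: int = 1000,
) -> CalibrationResult:
    """Coverage/power with parameter sets drawn from the prior.

    For each simulation, all hyperparameters (beta_age, mu_g, sigma2_g and
    tau2 or omega) are drawn from the model's priors (``beta_true`` pins
    the age effect instead, e.g. 0 for type-I assessment), a dataset is
    simulated on the template design, the model is refitted with the same
    priors, and the credible intervals are scored. If the priors are
    calibrated — i.e. data really do arise from them — the level-L interval
    covers the simulating beta_age in a fraction L of runs.
    """
    post = template.posterior
    pr = template.priors
    if post.per_cohort_beta:
        raise ValueError("simulation-based calibration supports common-beta specs")
    rng = np.random.default_rng(seed)
    G = post.data.n_groups
    records = []
    for _ in range(n_sims):
        beta = (
            float(rng.normal(pr.beta_mean, np.sqrt(pr.beta_var)))
            if beta_true is None else float(beta_true)
        )
        params = {
            "beta": beta,
            "mu": rng.normal(pr.mu_mean, np.sqrt(pr.mu_var), size=G),
            "sigma2": stats.invgamma.rvs(
                pr.sigma2_shape, scale=pr.sigma2_scale, size=G, random_state=rng),
        }
        if post.likelihood == "normal":
            params["tau2"] = float(stats.invgamma.rvs(
                pr.tau2_shape, scale=pr.tau2_scale, random_state=rng))
        else:
            params["omega"] = float(1.0 / rng.uniform(0.0, 1.0))
        y_new = simulate_replicate(post, params, rng)
        rec = _refit_and_score(
            template, y_new, beta, levels,
            seed=int(rng.integers(2**31 - 1)),
            n_chains=n_chains, n_draws=n_draws,
        )
        if rec is not None:
            rec["bin"] = 0
            records.append(rec)
    records = pd.DataFrame(records)
    return CalibrationResult(
        table=_records_to_table(records, levels, by_bin=False), records=records
    )
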