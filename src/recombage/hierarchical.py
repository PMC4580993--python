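"""Bayesian hierarchical models for parental-age effects on crossover counts.

Six model variants are supported, combining a normal or negative-binomial
likelihood, a common or per-cohort age effect, and parent-effect hierarchies
at the cohort level (fully informative meioses only) or the cohort-by-
family-configuration level (all families with at least two children, which
absorbs configuration-dependent under-calling):

==========  ==================  ============  ==============================
model id    likelihood          age effect    hierarchy / data
==========  ==================  ============  ==============================
M1          normal              common        cohort; fully informative
M1.2        normal              per cohort    cohort; fully informative
M2          negative binomial   common        cohort; fully informative
M2.2        negative binomial   per cohort    cohort; fully informative
M2*         negative binomial   common        cohort x configuration; all
M2.2*       negative binomial   per cohort    cohort x configuration; all
==========  ==================  ============  ==============================

Under the negative-binomial models the expected count is
exp(beta_age * age + alpha), so the count grows by a factor exp(beta_age)
per year of parental age; under the normal model it grows by beta_age
crossovers per year. Fitting uses the package's NUTS sampler: four chains
of 10,000 draws by default, first half discarded as burn-in, with chains
extended while any split R-hat exceeds 1.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import arviz as az

from .posterior import CrossoverLogPosterior, ModelArrays
from .priors import PriorSet, build_priors, uninformative_variant
from .sampler import NutsSampler, split_rhat
from .simulate import FULLY_INFORMATIVE_CONFIGS

_MODEL_IDS = {"M1", "M1.2", "M2", "M2.2", "M2star", "M2.2star"}
_ALIASES = {"M2*": "M2star", "M2.2*": "M2.2star"}

SUMMARY_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


class ConvergenceError(RuntimeError):
    """Raised when R-hat stays above threshold after the extension cap."""


@dataclass(frozen=True)
class ModelSpec:
    """Which hierarchical model to fit, and for which parent."""

    model_id: str
    parent_sex: str = "F"

    def __post_init__(self) -> None:
        mid = _ALIASES.get(self.model_id, self.model_id)
        object.__setattr__(self, "model_id", mid)
        if mid not in _MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.parent_sex not in ("M", "F"):
            raise ValueError("parent_sex must be 'M' or 'F'")

    @property
    def likelihood(self) -> str:
        return "normal" if self.model_id.startswith("M1") else "negative_binomial"

    @property
    def age_effect(self) -> str:
        return "per_cohort" if ".2" in self.model_id else "common"

    @property
    def hierarchy_level(self) -> str:
        return "cohort_by_configuration" if self.model_id.endswith("star") else "cohort"

    @property
    def multiplicative(self) -> bool:
        return self.likelihood == "negative_binomial"


def select_meioses(
    meioses: pd.DataFrame, spec: ModelSpec, min_meioses: int = 20
) -> pd.DataFrame:
    """Apply the spec's data-selection and exclusion rules.

    Restricts to the spec's parent sex; non-star models keep only fully
    informative meioses (configurations 2 and 6); parents with a single
    meiosis are dropped (their effect is not estimable); cohorts (or
    cohort-configuration cells for star models) with fewer than
    ``min_meioses`` meioses are excluded.
    """
    from .calls import apply_exclusion_rules

    df = meioses[meioses["parent_sex"] == spec.parent_sex]
    if spec.hierarchy_level == "cohort":
        df = df[df["configuration"].isin(FULLY_INFORMATIVE_CONFIGS)]
    sizes = df.groupby("parent_id")["child_id"].transform("size")
    n_single = int((sizes < 2).sum())
    if n_single:
        warnings.warn(
            f"dropping {n_single} meioses from single-child parents "
            "(parent effect not estimable)", stacklevel=2
        )
        df = df[sizes >= 2]
    df = apply_exclusion_rules(
        df, min_meioses=min_meioses,
        per_configuration=spec.hierarchy_level == "cohort_by_configuration",
    )
    return df.reset_index(drop=True)


def _build_arrays(meioses: pd.DataFrame, spec: ModelSpec) -> ModelArrays:
    parents, parent_idx = np.unique(meioses["parent_id"].to_numpy(), return_inverse=True)
    n_parents = len(parents)
    first = np.zeros(n_parents, dtype=int)
    first[parent_idx[::-1]] = np.arange(len(meioses) - 1, -1, -1)
    cohort_per_parent = meioses["cohort"].to_numpy()[first]
    cfg_per_parent = meioses["configuration"].to_numpy()[first]
    cohorts = sorted(set(cohort_per_parent))
    cohort_index = {c: i for i, c in enumerate(cohorts)}
    if spec.hierarchy_level == "cohort_by_configuration":
        keys = [f"{c}|{int(f)}" for c, f in zip(cohort_per_parent, cfg_per_parent)]
    else:
        keys = list(cohort_per_parent)
    group_labels = sorted(set(keys))
    group_index = {k: i for i, k in enumerate(group_labels)}
    return ModelArrays(
        y=meioses["n_crossovers"].to_numpy(dtype=float),
        age=meioses["parent_age_years"].to_numpy(dtype=float),
        parent_of_meiosis=parent_idx,
        group_of_parent=np.array([group_index[k] for k in keys], dtype=int),
        cohort_of_parent=np.array([cohort_index[c] for c in cohort_per_parent], dtype=int),
        group_labels=group_labels,
        cohort_labels=cohorts,
    )


class HierarchicalCrossoverModel:
    """Hierarchical Bayesian model of crossover counts vs parental age.

    Parameters
    ----------
    meioses : per-meiosis table (``MEIOSIS_COLUMNS`` dialect).
    spec : which model variant and parent sex.
    priors : optional :class:`PriorSet`; built empirically from the selected
        data when omitted.
    apply_selection : apply the spec's data-selection/exclusion rules
        (default). Pass False if the table is already exactly the analysis
        set.
    """

    def __init__(
        self,
        meioses: pd.DataFrame,
        spec: ModelSpec,
        priors: PriorSet | None = None,
        apply_selection: bool = True,
        min_meioses: int = 20,
        fixed: dict | None = None,
    ):
        self.spec = spec
        self.meioses = (
            select_meioses(meioses, spec, min_meioses) if apply_selection
            else meioses.reset_index(drop=True)
        )
        if self.meioses.empty and len(meioses):
            raise ValueError("no meioses left after selection/exclusion rules")
        self.data = _build_arrays(self.meioses, spec) if len(self.meioses) else ModelArrays(
            y=np.zeros(0), age=np.zeros(0),
            parent_of_meiosis=np.zeros(0, dtype=int),
            group_of_parent=np.zeros(0, dtype=int),
            cohort_of_parent=np.zeros(0, dtype=int),
            group_labels=[], cohort_labels=[],
        )
        if priors is None:
            if self.meioses.empty:
                priors = PriorSet()
            else:
                priors = build_priors(self.meioses, spec)
        self.priors = priors
        self.posterior = CrossoverLogPosterior(
            self.data, priors,
            likelihood=spec.likelihood,
            per_cohort_beta=spec.age_effect == "per_cohort",
            fixed=fixed,
        )

    def fit(
        self,
        n_chains: int = 4,
        n_draws: int = 10_000,
        seed: int = 0,
        burn_in_fraction: float = 0.5,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
        rhat_threshold: float = 1.05,
        max_extensions: int = 2,
        extension_draws: int | None = None,
        thin: int = 1,
    ) -> "CrossoverAgeResults":
        """Run NUTS and return posterior draws.

        ``n_draws`` is per chain; the first ``burn_in_fraction`` of each
        chain is discarded. If any parameter's split R-hat exceeds
        ``rhat_threshold``, each chain is extended by ``extension_draws``
        (default ``n_draws``) further draws, up to ``max_extensions`` times;
        a :class:`ConvergenceError` (with the R-hat report) is raised if the
        threshold is still not met.
        """
        sampler = NutsSampler(
            self.posterior.logp_and_grad, self.posterior.n_params,
            target_accept=target_accept, max_treedepth=max_treedepth,
        )
        n_warmup = int(n_draws * burn_in_fraction)
        n_keep = n_draws - n_warmup
        seeds = np.random.SeedSequence(seed).spawn(n_chains)
        rngs = [np.random.Generator(np.random.PCG64(s)) for s in seeds]

        chain_draws, chain_lps, states = [], [], []
        for k in range(n_chains):
            theta0 = self.posterior.initial_position(rngs[k])
            res = sampler.run(theta0, n_keep, n_warmup, rngs[k])
            chain_draws.append(res.draws)
            chain_lps.append(res.logp)
            states.append(res)

        draws = np.stack(chain_draws)          # (chains, kept, dim)
        lps = np.stack(chain_lps)
        n_ext = 0
        while True:
            rhat = _split_rhat(draws)
            if not len(rhat) or np.nanmax(rhat) <= rhat_threshold:
                break
            if n_ext >= max_extensions:
                worst = int(np.nanargmax(rhat))
                raise ConvergenceError(
                    f"R-hat {np.nanmax(rhat):.3f} > {rhat_threshold} for "
                    f"parameter index {worst} "
                    f"({_param_names(self.posterior)[worst]}) after "
                    f"{max_extensions} extensions"
                )
            n_ext += 1
            n_more = extension_draws if extension_draws is not None else n_draws
            extra_draws, extra_lps = [], []
            for k in range(n_chains):
                res = sampler.run_fixed(
                    draws[k, -1], n_more, states[k].step_size,
                    states[k].inv_mass, rngs[k],
                )
                extra_draws.append(res.draws)
                extra_lps.append(res.logp)
            draws = np.concatenate([draws, np.stack(extra_draws)], axis=1)
            lps = np.concatenate([lps, np.stack(extra_lps)], axis=1)

        if thin > 1:
            draws = draws[:, ::thin]
            lps = lps[:, ::thin]
        return CrossoverAgeResults(
            model=self, raw_draws=draws, lp=lps,
            burn_in_fraction=burn_in_fraction, n_extensions=n_ext, seed=seed,
        )


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    if draws.shape[1] < 4:
        return np.full(draws.shape[2], np.nan)
    return split_rhat(draws)


def _param_names(post: CrossoverLogPosterior) -> list[str]:
    names = [""] * post.n_params
    d = post.data
    for block, sl in post.slices.items():
        size = sl.stop - sl.start
        if block == "beta":
            labels = (
                [f"beta_age[{c}]" for c in d.cohort_labels]
                if post.per_cohort_beta else ["beta_age"]
            )
        elif block == "mu":
            labels = [f"mu[{g}]" for g in d.group_labels]
        elif block == "log_sigma2":
            labels = [f"log_sigma2[{g}]" for g in d.group_labels]
        elif block == "z":
            labels = [f"z[{j}]" for j in range(size)]
        else:
            labels = [block]
        names[sl.start:sl.stop] = labels
    return names


class CrossoverAgeResults:
    """Posterior draws with chain structure, diagnostics and summaries.

    Draws are stored post burn-in, unconstrained; accessors return
    natural-scale parameters. ``quantile``/``prob_positive``/``summary``
    pool draws across chains.
    """

    def __init__(self, model, raw_draws, lp, burn_in_fraction, n_extensions, seed):
        self.model = model
        self.spec = model.spec
        self.raw_draws = raw_draws
        self.lp = lp
        self.burn_in_fraction = burn_in_fraction
        self.n_extensions = n_extensions
        self.seed = seed
        self._names = _param_names(model.posterior)

    # -- basic structure -------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return self.raw_draws.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.raw_draws.shape[1]

    def parameters(self) -> list[str]:
        """Natural-scale parameter names available to accessors."""
        post = self.model.posterior
        d = post.data
        out = []
        if post.per_cohort_beta:
            out += [f"beta_age[{c}]" for c in d.cohort_labels]
            out += ["beta_age_global", "sigma2_beta"]
        else:
            out.append("beta_age")
        out += [f"mu[{g}]" for g in d.group_labels]
        if "log_sigma2" in post.slices:
            out += [f"sigma2[{g}]" for g in d.group_labels]
        if "logit_inv_omega" in post.slices:
            out.append("omega")
        if "log_tau2" in post.slices:
            out.append("tau2")
        return out

    def get(self, parameter: str) -> np.ndarray:
        """Pooled-shape (chains, draws) natural-scale draws of a parameter."""
        post = self.model.posterior
        s = post.slices
        d = post.data
        th = self.raw_draws
        if parameter == "beta_age" and not post.per_cohort_beta:
            return th[:, :, s["beta"].start]
        if parameter.startswith("beta_age[") and post.per_cohort_beta:
            c = parameter[len("beta_age["):-1]
            return th[:, :, s["beta"].start + d.cohort_labels.index(c)]
        if parameter == "beta_age_global":
            return th[:, :, s["beta_global"].start]
        if parameter == "sigma2_beta":
            return np.exp(th[:, :, s["log_sigma2_beta"].start])
        if parameter.startswith("mu["):
            g = parameter[3:-1]
            gi = d.group_labels.index(g)
            mu_tilde = th[:, :, s["mu"].start + gi]
            # map the internally age-centered group mean back to raw-age scale
            if "beta" in post.fixed:
                beta_g = post.fixed["beta"]
            elif post.per_cohort_beta:
                beta_g = th[:, :, s["beta"].start + int(post.cohort_of_group[gi])]
            else:
                beta_g = th[:, :, s["beta"].start]
            return mu_tilde - beta_g * post.age_center
        if parameter.startswith("sigma2["):
            g = parameter[7:-1]
            return np.exp(th[:, :, s["log_sigma2"].start + d.group_labels.index(g)])
        if parameter == "tau2" and post.likelihood == "normal":
            return np.exp(th[:, :, s["log_tau2"].start])
        if parameter == "omega" and post.likelihood == "negative_binomial":
            v = th[:, :, s["logit_inv_omega"].start]
            return 1.0 + np.exp(-v)  # 1/sigmoid(v)
        raise KeyError(f"unknown parameter {parameter!r}")

    # -- diagnostics -----------------------------------------------------------

    def rhat(self) -> pd.Series:
        """Split R-hat for every sampled (unconstrained) parameter."""
        return pd.Series(_split_rhat(self.raw_draws), index=self._names)

    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat().to_numpy()))

    def ess(self, parameter: str) -> float:
        x = self.get(parameter)
        return float(az.ess(az.convert_to_dataset(x[:, :, None]))["x"].values[0])

    # -- summaries -------------------------------------------------------------

    def quantile(self, parameter: str, q) -> np.ndarray | float:
        """Posterior quantile(s) F^{-1}(q), pooled across chains."""
        vals = np.quantile(self.get(parameter).ravel(), q)
        return float(vals) if np.isscalar(q) else vals

    def prob_positive(self, parameter: str) -> float:
        return float(np.mean(self.get(parameter) > 0))

    def summary_row(self, parameter: str, exp_transform: bool | None = None) -> pd.Series:
        """Quantiles (2.5/25/50/75/97.5%) and Pr(>0) for one parameter.

        For the multiplicative (negative-binomial) models, age-effect rows
        report exp(beta_age) quantiles by default; Pr(>0) always refers to
        beta_age itself.
        """
        draws = self.get(parameter).ravel()
        if exp_transform is None:
            exp_transform = self.spec.multiplicative and parameter.startswith("beta_age")
        qs = np.quantile(draws, SUMMARY_QUANTILES)
        if exp_transform:
            qs = np.exp(qs)
        row = {f"{100 * q:g}%": v for q, v in zip(SUMMARY_QUANTILES, qs)}
        row["Pr(>0)"] = float(np.mean(draws > 0))
        return pd.Series(row, name=parameter)

    def summary(self, parameters: list[str] | None = None) -> pd.DataFrame:
        if parameters is None:
            parameters = self.parameters()
        return pd.DataFrame([self.summary_row(p) for p in parameters])

    # -- point estimates -------------------------------------------------------

    def map_draw(self) -> dict:
        """Natural-scale parameters of the highest-log-posterior draw."""
        flat = self.lp.reshape(-1)
        k = int(np.argmax(flat))
        c, i = divmod(k, self.raw_draws.shape[1])
        return self.model.posterior.unpack(self.raw_draws[c, i])

    def posterior_mean(self, parameter: str) -> float:
        return float(self.get(parameter).mean())

    def posterior_sd(self, parameter: str) -> float:
        return float(self.get(parameter).std(ddof=1))

    # -- export ----------------------------------------------------------------

    def to_tidy_frame(self, parameters: list[str] | None = None) -> pd.DataFrame:
        """Tidy draws (chain, iteration, parameter, value)."""
        if parameters is None:
            parameters = self.parameters()
        frames = []
        for p in parameters:
            x = self.get(p)
            n_c, n_d = x.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_c), n_d),
                "iteration": np.tile(np.arange(n_d), n_c),
                "parameter": p,
                "value": x.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


# Spec-facing functional aliases -------------------------------------------------

def fit_model(
    meioses: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSet | None = None,
    n_chains: int = 4,
    n_draws: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> CrossoverAgeResults:
    """Fit a hierarchical model (convenience wrapper around the class)."""
    model = HierarchicalCrossoverModel(meioses, spec, priors=priors)
    return model.fit(n_chains=n_chains, n_draws=n_draws, seed=seed, **kwargs)


def summarize(results: CrossoverAgeResults, parameter: str) -> pd.Series:
    """Table-2-style summary row for one parameter."""
    return results.summary_row(parameter)


def multiplicative_to_percent(rate_per_year: float, years: float = 10.0) -> float:
    """Percent increase in the expected count over ``years`` at a per-year
    multiplicative rate: 100 * (rate^years - 1)."""
    if rate_per_year <= 0:
        raise ValueError("rate must be > 0")
    return 100.0 * (rate_per_year**years - 1.0)


def multiplicative_to_additive(rate: float, baseline: float = 38.0) -> float:
    """Additive crossovers/year equivalent of a multiplicative per-year
    rate at a given baseline count: baseline * ln(rate)."""
    if rate <= 0 or baseline <= 0:
        raise ValueError("rate and baseline must be > 0")
    return baseline * float(np.log(rate))


RELAXABLE_PARAMETERS = ("beta", "mu", "sigma", "omega")


def robustness_reruns(
    meioses: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSet | None = None,
    parameters: tuple[str, ...] = RELAXABLE_PARAMETERS,
    **fit_kwargs,
) -> dict[str, CrossoverAgeResults]:
    """Refit with an uninformative prior on each parameter in turn.

    Only defined for the configuration-aware negative-binomial model (M2*),
    whose inference the reruns are meant to stress. Returns one results
    object per relaxed parameter; compare Pr(beta_age > 0) across them.
    """
    if spec.model_id != "M2star":
        raise ValueError("robustness reruns are defined for spec M2star")
    base_model = HierarchicalCrossoverModel(meioses, spec, priors=priors)
    base_priors = base_model.priors
    out: dict[str, CrossoverAgeResults] = {}
    for p in parameters:
        relaxed = uninformative_variant(base_priors, p)
        model = HierarchicalCrossoverModel(meioses, spec, priors=relaxed)
        out[p] = model.fit(**fit_kwargs)
    return out
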