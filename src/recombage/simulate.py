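"""Synthetic multi-cohort pedigrees and crossover counts.

Generates the inputs every downstream stage consumes: families in the six
pedigree configurations, parental ages at each birth, true per-meiosis
crossover counts from either a normal or a negative-binomial generative
model with parent-specific baseline effects, binomial under-calling for
partially informative configurations, and (optionally) call-level tables
with injected artifacts for exercising the call filters.

The generator starts at true crossovers; there is no genotype- or
SNP-level simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

FULLY_INFORMATIVE_CONFIGS = (2, 6)
ALL_CONFIGS = (1, 2, 3, 4, 5, 6)

#: Column order of the per-meiosis table written/read everywhere.
MEIOSIS_COLUMNS = [
    "cohort", "family_id", "parent_id", "child_id", "parent_sex",
    "parent_age_years", "configuration", "n_crossovers",
]

CALL_COLUMNS = [
    "cohort", "parent_id", "child_id", "chrom", "start_bp", "end_bp",
    "posterior_prob", "left_snp_index", "right_snp_index",
]


@dataclass
class CohortSpec:
    """Pedigree structure and age distribution for one cohort.

    ``maternal_age_distribution`` is (mean, sd, min, max) in years for the
    mother's age at a child's birth; paternal ages are offset from maternal
    ones. ``snps_per_mb`` drives the double-crossover filter threshold X
    downstream.
    """

    cohort_id: str
    n_families_per_configuration: Mapping[int, int]
    maternal_age_distribution: tuple[float, float, float, float] = (28.0, 5.0, 16.0, 45.0)
    paternal_age_offset: float = 3.0
    snps_per_mb: float = 150.0

    def __post_init__(self) -> None:
        for cfg, n in self.n_families_per_configuration.items():
            if cfg not in ALL_CONFIGS:
                raise ValueError(f"invalid family configuration {cfg!r}")
            if n < 0:
                raise ValueError("family counts must be >= 0")
        mean, sd, lo, hi = self.maternal_age_distribution
        if sd <= 0:
            raise ValueError("age sd must be > 0")
        if lo >= hi:
            raise ValueError("age min must be < max")
        if self.snps_per_mb <= 0:
            raise ValueError("snps_per_mb must be > 0")


@dataclass
class GenerativeParams:
    """True parameters of the count-generating process.

    ``beta_age`` is crossovers/year for the normal family and per-year on
    the log scale for the negative-binomial family. ``mu_cf``/``sigma2_cf``
    map (cohort_id, configuration) to the mean and variance of the parent
    baseline effects alpha. ``detection_prob_cf`` thins each true crossover
    binomially, modelling under-calling in partially informative meioses;
    it must be exactly 1 for the fully informative configurations (2, 6).
    """

    model_family: str  # "normal" | "negative_binomial"
    beta_age: float
    mu_cf: Mapping[tuple[str, int], float]
    sigma2_cf: Mapping[tuple[str, int], float]
    tau2: float = 0.0
    omega: float = 1.0
    detection_prob_cf: Mapping[tuple[str, int], float] = field(default_factory=dict)
    parent_sex: str = "F"

    def __post_init__(self) -> None:
        if self.model_family not in ("normal", "negative_binomial"):
            raise ValueError(f"unknown model family {self.model_family!r}")
        if any(v < 0 for v in self.sigma2_cf.values()):
            raise ValueError("sigma2_cf entries must be >= 0")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        for (cohort, cfg), p in self.detection_prob_cf.items():
            if not (0 < p <= 1):
                raise ValueError("detection probabilities must lie in (0, 1]")
            if cfg in FULLY_INFORMATIVE_CONFIGS and p != 1.0:
                raise ValueError(
                    "fully informative configurations (2, 6) must have detection_prob 1"
                )

    def detection_prob(self, cohort: str, cfg: int) -> float:
        return self.detection_prob_cf.get((cohort, cfg), 1.0)


@dataclass
class SimulationTruth:
    """Ledger of the true generative quantities behind a simulated table."""

    params: GenerativeParams
    parent_effects: dict[str, float]
    true_counts: dict[tuple[str, str], int]  # (parent_id, child_id) -> count
    seed: int


def _cohort_seed(seed: int, cohort_id: str) -> np.random.SeedSequence:
    # Stable per-cohort stream: adding or reordering other cohorts does not
    # perturb this cohort's draws.
    return np.random.SeedSequence([int(seed), zlib.crc32(cohort_id.encode())])


def negative_binomial_counts(mean: np.ndarray, omega: float, rng: np.random.Generator) -> np.ndarray:
    """Counts with E(Y)=mean and Var(Y)=omega*mean.

    Uses shape a = mean/(omega-1) and success probability 1/omega; omega=1
    falls back to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if omega <= 1.0 + 1e-12:
        return rng.poisson(mean)
    a = mean / (omega - 1.0)
    return rng.negative_binomial(a, 1.0 / omega)


def _emit_counts(
    params: GenerativeParams, alpha: np.ndarray, ages: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """True counts for one family given its parent effect and child ages."""
    if params.model_family == "normal":
        y = rng.normal(params.beta_age * ages + alpha, np.sqrt(params.tau2))
        return np.maximum(np.rint(y), 0.0).astype(int)
    mean = np.exp(params.beta_age * ages + alpha)
    return negative_binomial_counts(mean, params.omega, rng)


def _family_ages(
    spec: CohortSpec, n_children: int, rng: np.random.Generator
) -> np.ndarray:
    """Maternal ages at each birth, strictly increasing, >=1 year apart."""
    mean, sd, lo, hi = spec.maternal_age_distribution
    # Age at first birth: truncated normal shifted young of the all-birth mean.
    for _ in range(100):
        first = rng.normal(mean - 2.0, sd)
        if lo <= first <= hi - n_children:
            break
    else:
        first = np.clip(mean - 2.0, lo, hi - n_children)
    gaps = 1.0 + rng.exponential(1.5, size=n_children - 1)
    ages = first + np.concatenate([[0.0], np.cumsum(gaps)])
    # Keep within the stated range while preserving strict increase.
    overshoot = ages[-1] - hi
    if overshoot > 0:
        ages = lo + (ages - lo) * (hi - lo) / (ages[-1] - lo)
    return ages


def simulate_cohorts(
    specs: list[CohortSpec],
    params: GenerativeParams,
    seed: int,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate per-meiosis crossover counts for a set of cohorts.

    For each parent j in cohort c with family configuration f, the baseline
    effect alpha is drawn from Normal(mu_cf, sigma2_cf); each child's true
    count comes from the normal or negative-binomial emission around
    beta_age*age + alpha; the observed count is a Binomial(true count,
    detection_prob_cf) thinning. Same seed => identical output.

    Returns the meiosis table (``MEIOSIS_COLUMNS``) and a
    :class:`SimulationTruth` ledger.
    """
    if not specs:
        raise ValueError("need at least one cohort spec")
    rows: list[tuple] = []
    parent_effects: dict[str, float] = {}
    true_counts: dict[tuple[str, str], int] = {}
    sex = params.parent_sex

    for spec in specs:
        base_ss = _cohort_seed(seed, spec.cohort_id)
        fam_counter = 0
        for cfg in ALL_CONFIGS:
            n_fam = spec.n_families_per_configuration.get(cfg, 0)
            for _ in range(n_fam):
                fam_counter += 1
                rng = np.random.Generator(
                    np.random.PCG64(
                        np.random.SeedSequence(
                            [int(seed), zlib.crc32(spec.cohort_id.encode()), fam_counter]
                        )
                    )
                )
                fam_id = f"{spec.cohort_id}_F{fam_counter:05d}"
                parent_id = f"{fam_id}_{'M' if sex == 'F' else 'P'}"
                key = (spec.cohort_id, cfg)
                try:
                    mu = params.mu_cf[key]
                    s2 = params.sigma2_cf[key]
                except KeyError as exc:
                    raise KeyError(
                        f"mu_cf/sigma2_cf missing entry for {key}"
                    ) from exc
                alpha = rng.normal(mu, np.sqrt(s2))
                parent_effects[parent_id] = alpha

                n_children = 2 if cfg in (3, 4, 5, 6) else 3 + rng.poisson(0.8)
                mat_ages = _family_ages(spec, n_children, rng)
                ages = mat_ages if sex == "F" else mat_ages + spec.paternal_age_offset
                true = _emit_counts(params, alpha, ages, rng)
                det = params.detection_prob(spec.cohort_id, cfg)
                obs = true if det == 1.0 else rng.binomial(true, det)
                for k in range(n_children):
                    child_id = f"{fam_id}_C{k + 1}"
                    true_counts[(parent_id, child_id)] = int(true[k])
                    rows.append(
                        (
                            spec.cohort_id, fam_id, parent_id, child_id, sex,
                            round(float(ages[k]), 2), cfg, int(obs[k]),
                        )
                    )

    table = pd.DataFrame(rows, columns=MEIOSIS_COLUMNS)
    truth = SimulationTruth(
        params=params, parent_effects=parent_effects,
        true_counts=true_counts, seed=int(seed),
    )
    return table, truth


def simulate_counts_given_design(
    design: pd.DataFrame,
    model_family: str,
    beta_by_cohort: Mapping[str, float],
    mu_g: Mapping[tuple[str, int], float],
    sigma2_g: Mapping[tuple[str, int], float],
    rng: np.random.Generator,
    tau2: float = 0.0,
    omega: float = 1.0,
) -> np.ndarray:
    """Re-simulate counts on an existing design (ages, parents, groups).

    Starts from the top of the hierarchy: draws a fresh alpha per parent
    from its (cohort, configuration) group, then counts per meiosis. Used
    by posterior predictive checks and the calibration machinery.
    """
    parents, inv = np.unique(design["parent_id"].to_numpy(), return_inverse=True)
    first_row = np.zeros(len(parents), dtype=int)
    first_row[inv[::-1]] = np.arange(len(design) - 1, -1, -1)
    cohorts = design["cohort"].to_numpy()[first_row]
    cfgs = design["configuration"].to_numpy()[first_row]
    mu = np.array([mu_g[(c, int(f))] for c, f in zip(cohorts, cfgs)])
    s2 = np.array([sigma2_g[(c, int(f))] for c, f in zip(cohorts, cfgs)])
    alpha = rng.normal(mu, np.sqrt(s2))[inv]
    beta = np.array([beta_by_cohort[c] for c in design["cohort"]])
    eta = beta * design["parent_age_years"].to_numpy() + alpha
    if model_family == "normal":
        y = rng.normal(eta, np.sqrt(tau2))
        return np.maximum(np.rint(y), 0.0).astype(int)
    return negative_binomial_counts(np.exp(eta), omega, rng)


def simulate_call_table(
    meioses: pd.DataFrame,
    truth: SimulationTruth,
    artifact_rate: float = 0.0,
    seed: int = 0,
    low_conf_rate: float = 0.0,
    x_snps_by_cohort: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand per-meiosis counts into a call-level table with artifacts.

    Every observed crossover becomes one call with posterior probability
    above 0.5. With probability ``artifact_rate`` per meiosis a tight pair
    of spurious calls (SNP separation below the cohort's X) is injected;
    with probability ``low_conf_rate`` a low-confidence call (P <= 0.5) is
    injected. Returns (calls, injected) where ``injected`` records the
    coordinates and kind of every artifact so filters can be scored.
    """
    if not (0 <= artifact_rate < 1):
        raise ValueError("artifact_rate must be in [0, 1)")
    if not (0 <= low_conf_rate < 1):
        raise ValueError("low_conf_rate must be in [0, 1)")
    missing = [
        (p, c)
        for p, c in zip(meioses["parent_id"], meioses["child_id"])
        if (p, c) not in truth.true_counts
    ]
    if missing:
        raise ValueError(f"meiosis table/truth mismatch: {missing[:3]} not in truth ledger")

    x_by_cohort = dict(x_snps_by_cohort or {})
    rows: list[tuple] = []
    injected: list[tuple] = []
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 0xC0DE])))

    for rec in meioses.itertuples(index=False):
        x = int(x_by_cohort.get(rec.cohort, 150))
        bp_per_snp = 1_000_000.0 / max(x, 1)
        spacing = 2 * x + 100
        real_start = 3 * x + 200

        def add_call(left: int, prob: float, chrom: str) -> tuple:
            right = left + 1
            row = (
                rec.cohort, rec.parent_id, rec.child_id, chrom,
                int(left * bp_per_snp) + 1, int(right * bp_per_snp) + 1,
                round(float(prob), 4), left, right,
            )
            rows.append(row)
            return row

        k = int(rec.n_crossovers)
        for t in range(k):
            chrom = f"chr{1 + t % 22}"
            left = real_start + (t // 22) * spacing
            add_call(left, rng.uniform(0.55, 0.999), chrom)

        if artifact_rate > 0 and rng.random() < artifact_rate:
            gap = int(rng.integers(1, max(x - 1, 2)))  # inner separation < X
            first_left = 100
            second_left = first_left + 1 + gap
            chrom = "chr1"
            r1 = add_call(first_left, rng.uniform(0.55, 0.999), chrom)
            r2 = add_call(second_left, rng.uniform(0.55, 0.999), chrom)
            for r in (r1, r2):
                injected.append(r + ("tight_pair",))

        if low_conf_rate > 0 and rng.random() < low_conf_rate:
            chrom = "chr22"
            left = real_start + (k // 22 + 2) * spacing
            r = add_call(left, rng.uniform(0.05, 0.5), chrom)
            injected.append(r + ("low_prob",))

    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    audit = pd.DataFrame(injected, columns=CALL_COLUMNS + ["kind"])
    return calls, audit


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# Nine cohorts; family counts per configuration chosen to echo the published
# multi-cohort structure (a few large twin-registry cohorts, several small
# isolate cohorts), scaled by `scale`. Configuration key: 1/2 = >=3 children
# with one/both parents, 3/4 = 2 children with one/both parents, 5/6 = 2
# children + grandparents with one/both parents.
_DEFAULT_COHORTS: list[tuple[str, dict[int, int], tuple[float, float, float, float], float]] = [
    ("QTR610", {2: 100, 6: 8, 1: 20, 3: 60, 4: 120, 5: 10}, (28.5, 5.0, 17.0, 44.0), 180.0),
    ("QTR370", {2: 60, 6: 6, 1: 12, 3: 30, 4: 60, 5: 6}, (28.0, 5.0, 17.0, 44.0), 110.0),
    ("QTRCoreExome", {2: 19, 6: 7, 1: 8, 3: 20, 4: 40, 5: 4}, (29.0, 5.0, 17.0, 44.0), 90.0),
    ("NTR", {2: 24, 6: 9, 1: 10, 3: 30, 4: 55, 5: 6}, (29.5, 4.5, 18.0, 44.0), 160.0),
    ("ORCADES", {2: 4, 6: 6, 1: 4, 3: 10, 4: 14, 5: 2}, (27.5, 5.5, 17.0, 45.0), 100.0),
    ("FC", {2: 7, 6: 5, 1: 4, 3: 8, 4: 10, 5: 2}, (27.0, 5.5, 16.0, 45.0), 120.0),
    ("VB", {2: 2, 6: 4, 1: 3, 3: 10, 4: 12, 5: 2}, (28.0, 6.0, 16.0, 45.0), 120.0),
    ("FVG", {2: 1, 6: 5, 1: 3, 3: 8, 4: 10, 5: 2}, (28.5, 6.0, 16.0, 45.0), 120.0),
    ("CARL", {2: 1, 6: 2, 1: 2, 3: 4, 4: 5, 5: 1}, (28.0, 6.0, 16.0, 45.0), 120.0),
]


def default_cohort_specs(scale: float = 1.0) -> list[CohortSpec]:
    """Cohort specs emulating a nine-cohort SNP-chip pedigree study.

    ``scale`` multiplies every family count (rounded, floor 0) so tests can
    run on smaller replicas of the same structure.
    """
    specs = []
    for name, fams, agedist, snps in _DEFAULT_COHORTS:
        scaled = {cfg: int(round(n * scale)) for cfg, n in fams.items()}
        scaled = {cfg: n for cfg, n in scaled.items() if n > 0}
        if not scaled:
            continue
        specs.append(
            CohortSpec(
                cohort_id=name,
                n_families_per_configuration=scaled,
                maternal_age_distribution=agedist,
                snps_per_mb=snps,
            )
        )
    return specs


# Default per-configuration detection probabilities: fully informative
# configurations are complete by definition; single-parent and two-child
# configurations are attenuated (duoHMM-style under-calling).
_DEFAULT_DETECTION = {1: 0.90, 2: 1.0, 3: 0.75, 4: 0.85, 5: 0.80, 6: 1.0}


def default_generative_params(
    specs: list[CohortSpec],
    model_family: str = "negative_binomial",
    beta_age: float | None = None,
    parent_sex: str = "F",
) -> GenerativeParams:
    """Generative parameters matching the default study conditions.

    Maternal baselines centre the expected count near 38-41 crossovers with
    modest cohort-to-cohort spread; counts are overdispersed (omega=1.3 for
    the negative-binomial family; between-mother variance ~6 and residual
    variance ~22 for the normal family). The default age effect is the
    small positive maternal effect scale: 0.082 crossovers/year additive,
    0.002/year on the log scale.
    """
    if beta_age is None:
        beta_age = 0.082 if model_family == "normal" else 0.002
    base_count = 38.0 if parent_sex == "F" else 25.0
    mu_cf: dict[tuple[str, int], float] = {}
    sigma2_cf: dict[tuple[str, int], float] = {}
    det: dict[tuple[str, int], float] = {}
    for i, spec in enumerate(specs):
        cohort_shift = 0.5 * ((i % 5) - 2)  # fixed, deterministic spread
        for cfg in spec.n_families_per_configuration:
            true_mean = base_count + cohort_shift
            age_part = beta_age * 28.0  # baselines quoted at the typical age
            if model_family == "normal":
                mu_cf[(spec.cohort_id, cfg)] = true_mean - age_part
                sigma2_cf[(spec.cohort_id, cfg)] = 6.0
            else:
                mu_cf[(spec.cohort_id, cfg)] = float(np.log(true_mean)) - age_part
                sigma2_cf[(spec.cohort_id, cfg)] = 0.01
            det[(spec.cohort_id, cfg)] = _DEFAULT_DETECTION[cfg]
    return GenerativeParams(
        model_family=model_family,
        beta_age=beta_age,
        mu_cf=mu_cf,
        sigma2_cf=sigma2_cf,
        tau2=22.0 if model_family == "normal" else 0.0,
        omega=1.0 if model_family == "normal" else 1.3,
        detection_prob_cf=det,
        parent_sex=parent_sex,
    )
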