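"""Crossover-call post-processing: thresholds, double-crossover filters,
family-configuration classification, and per-meiosis count assembly.

The pipeline mirrors standard pedigree crossover-calling practice: keep
calls with posterior probability strictly above 0.5, remove tight double
crossovers (likely genotyping or phase-switch errors) whose flanking-SNP
separation is below a per-cohort threshold X (the cohort's average number
of SNPs per megabase), classify each family into one of six pedigree
configurations that determine detection completeness, drop one member of
each monozygotic twin pair, and exclude cohorts (or cohort-configuration
cells) with fewer than 20 meioses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import FULLY_INFORMATIVE_CONFIGS, MEIOSIS_COLUMNS


@dataclass
class FilterParams:
    """Thresholds for call-level filtering.

    ``x_snps`` maps cohort -> X, the SNP-index separation below which a
    consecutive pair of calls is treated as one artifact and removed.
    """

    prob_threshold: float = 0.5
    x_snps: Mapping[str, int] = field(default_factory=dict)
    nftools_marker_window: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.prob_threshold <= 1):
            raise ValueError("prob_threshold must be in [0, 1]")
        if any(x < 1 for x in self.x_snps.values()):
            raise ValueError("x_snps entries must be >= 1")


@dataclass(frozen=True)
class FamilyConfiguration:
    """One of the six pedigree shapes; 2 and 6 are fully informative."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"invalid configuration code {self.code}")

    @property
    def fully_informative(self) -> bool:
        return self.code in FULLY_INFORMATIVE_CONFIGS


def threshold_calls(calls: pd.DataFrame, prob_threshold: float = 0.5) -> pd.DataFrame:
    """Keep only calls with posterior probability strictly above threshold."""
    return calls[calls["posterior_prob"] > prob_threshold].reset_index(drop=True)


def _pairwise_removal(
    group: pd.DataFrame, window: int, left_col: str, right_col: str
) -> tuple[list[int], list[tuple[int, int]]]:
    """Stack scan removing both members of any tight consecutive pair.

    Calls are taken in position order; when the current call's left index is
    fewer than ``window`` units beyond the previous surviving call's right
    index, both are removed and scanning continues against the call that now
    precedes them (left-to-right cascade).
    Returns (kept row positions, removed pairs of row positions).
    """
    order = np.argsort(group[left_col].to_numpy(), kind="stable")
    lefts = group[left_col].to_numpy()[order]
    rights = group[right_col].to_numpy()[order]
    kept: list[int] = []
    removed: list[tuple[int, int]] = []
    for pos in range(len(order)):
        if kept and lefts[pos] - rights[kept[-1]] < window:
            removed.append((int(order[kept[-1]]), int(order[pos])))
            kept.pop()
        else:
            kept.append(pos)
    return [int(order[p]) for p in kept], removed


def filter_double_crossovers(
    calls: pd.DataFrame, x_snps: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove tight double crossovers within each meiosis and chromosome.

    Within each (cohort, parent, child, chromosome), any two consecutive
    calls whose inner flanking-SNP separation (later call's left index minus
    earlier call's right index) is below the cohort's X are both removed;
    removal cascades left to right. Returns (surviving calls, removed calls
    annotated with reason "tight_pair").
    """
    kept_parts: list[pd.DataFrame] = []
    removed_parts: list[pd.DataFrame] = []
    for (cohort, _, _, _), grp in calls.groupby(
        ["cohort", "parent_id", "child_id", "chrom"], sort=False
    ):
        if cohort not in x_snps:
            raise KeyError(f"no X (SNPs/Mb) entry for cohort {cohort!r}")
        keep_idx, removed_pairs = _pairwise_removal(
            grp, int(x_snps[cohort]), "left_snp_index", "right_snp_index"
        )
        kept_parts.append(grp.iloc[keep_idx])
        if removed_pairs:
            flat = [i for pair in removed_pairs for i in pair]
            removed_parts.append(grp.iloc[flat].assign(reason="tight_pair"))
    kept = (
        pd.concat(kept_parts).sort_index().reset_index(drop=True)
        if kept_parts else calls.iloc[0:0].copy()
    )
    removed = (
        pd.concat(removed_parts).sort_index().reset_index(drop=True)
        if removed_parts else calls.iloc[0:0].assign(reason=pd.Series(dtype=str))
    )
    return kept, removed


def nftools_window_filter(calls: pd.DataFrame, marker_window: int = 5) -> pd.DataFrame:
    """Double-crossover filter in informative-marker units (window 5).

    Same pairwise-removal semantics as :func:`filter_double_crossovers`, but
    distances are measured on informative-marker indices (columns
    ``left_marker_index``/``right_marker_index``).
    """
    for col in ("left_marker_index", "right_marker_index"):
        if col not in calls.columns:
            raise KeyError(f"calls lack informative-marker column {col!r}")
    kept_parts = []
    for _, grp in calls.groupby(["cohort", "parent_id", "child_id", "chrom"], sort=False):
        keep_idx, _ = _pairwise_removal(
            grp, int(marker_window), "left_marker_index", "right_marker_index"
        )
        kept_parts.append(grp.iloc[keep_idx])
    if not kept_parts:
        return calls.iloc[0:0].copy()
    return pd.concat(kept_parts).sort_index().reset_index(drop=True)


def classify_family(family: pd.DataFrame, target_parent: str) -> FamilyConfiguration:
    """Classify a pedigree subtree into one of the six configurations.

    ``family`` is a FAM-dialect frame (family_id, individual_id, father_id,
    mother_id, sex, phenotype); genotyped individuals are those with a row.
    Configurations: >=3 children with one/both parents genotyped (1/2), two
    children with one/both parents (3/4), two children plus the target
    parent's own parents with one/both parents (5/6). Families with >=3
    children and grandparents get the >=3-children codes, since the
    grandparent configurations are defined only for two-child families.
    """
    ids = set(family["individual_id"])
    if target_parent not in ids:
        raise ValueError(f"target parent {target_parent!r} not genotyped in family")
    is_child = (family["father_id"] == target_parent) | (family["mother_id"] == target_parent)
    children = family[is_child]
    n_children = len(children)
    if n_children < 2:
        raise ValueError(
            "family has <2 genotyped children of the target parent; "
            "the parent effect cannot be estimated"
        )
    other_parents = set(children["father_id"]) | set(children["mother_id"])
    other_parents -= {target_parent, "0"}
    both_parents = any(p in ids for p in other_parents)
    target_row = family[family["individual_id"] == target_parent].iloc[0]
    grandparents = (
        target_row["father_id"] in ids and target_row["mother_id"] in ids
        and target_row["father_id"] != "0" and target_row["mother_id"] != "0"
    )
    if n_children >= 3:
        code = 2 if both_parents else 1
    elif grandparents:
        code = 6 if both_parents else 5
    else:
        code = 4 if both_parents else 3
    return FamilyConfiguration(code)


def deduplicate_monozygotic(
    meioses: pd.DataFrame, mz_pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Keep one child of each monozygotic pair (lexicographically smaller id)."""
    present = set(meioses["child_id"])
    drop: set[str] = set()
    for a, b in mz_pairs:
        if a not in present or b not in present:
            warnings.warn(f"MZ pair ({a}, {b}) not fully present; skipped", stacklevel=2)
            continue
        drop.add(max(a, b))
    return meioses[~meioses["child_id"].isin(drop)].reset_index(drop=True)


def apply_exclusion_rules(
    meioses: pd.DataFrame, min_meioses: int = 20, per_configuration: bool = False
) -> pd.DataFrame:
    """Drop cohorts (or cohort-configuration cells) with too few meioses."""
    if per_configuration:
        sizes = meioses.groupby(["cohort", "configuration"])["child_id"].transform("size")
    else:
        sizes = meioses.groupby("cohort")["child_id"].transform("size")
    return meioses[sizes >= min_meioses].reset_index(drop=True)


def aggregate_counts(calls: pd.DataFrame, meioses: pd.DataFrame) -> pd.DataFrame:
    """Per-meiosis crossover counts from a filtered call table.

    ``meioses`` provides the meiosis universe (one row per parent-child
    pair, any n_crossovers column is ignored); meioses with no surviving
    calls get count 0.
    """
    counted = (
        calls.groupby(["parent_id", "child_id"]).size().rename("n_crossovers").reset_index()
    )
    base = meioses.drop(columns=["n_crossovers"], errors="ignore")
    out = base.merge(counted, on=["parent_id", "child_id"], how="left")
    out["n_crossovers"] = out["n_crossovers"].fillna(0).astype(int)
    return out[[c for c in MEIOSIS_COLUMNS if c in out.columns]]


def binned_age_summary(
    meioses: pd.DataFrame,
    bin_width: int = 5,
    reference_bin: tuple[float, float] = (20.0, 25.0),
) -> pd.DataFrame:
    """Mean crossover count per parental-age bin, relative to a reference bin.

    Ages are grouped into ``bin_width``-year bins aligned to the reference
    bin; each bin's mean is reported as the difference from the reference
    bin's mean, with a 95% CI of mean +/- 1.96*sd/sqrt(n) (normal
    approximation for the bin mean).
    """
    lo_ref, hi_ref = reference_bin
    ages = meioses["parent_age_years"].to_numpy(dtype=float)
    counts = meioses["n_crossovers"].to_numpy(dtype=float)
    bin_idx = np.floor((ages - lo_ref) / bin_width).astype(int)
    ref_mask = bin_idx == 0
    if not ref_mask.any():
        raise ValueError(f"no meioses in the reference bin {reference_bin}")
    ref_mean = counts[ref_mask].mean()
    rows = []
    for b in sorted(set(bin_idx)):
        mask = bin_idx == b
        vals = counts[mask]
        n = int(mask.sum())
        mean_diff = vals.mean() - ref_mean
        sd = vals.std(ddof=1) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n)
        rows.append(
            {
                "bin_low": lo_ref + b * bin_width,
                "bin_high": lo_ref + (b + 1) * bin_width,
                "n": n,
                "mean_diff": mean_diff,
                "ci_low": mean_diff - half,
                "ci_high": mean_diff + half,
            }
        )
    return pd.DataFrame(rows)
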