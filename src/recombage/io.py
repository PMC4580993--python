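"""Readers/writers for the plain-text table formats used throughout.

All tables are tab-separated with a header row. Pedigrees are written in
the PLINK FAM dialect (family_id, individual_id, father_id, mother_id,
sex, phenotype) with a sidecar TSV carrying cohort labels and parental
ages, since FAM has no column for either.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import CALL_COLUMNS, MEIOSIS_COLUMNS

FAM_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]


def write_meiosis_table(table: pd.DataFrame, path: str | Path) -> None:
    table[MEIOSIS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_meiosis_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cohort": str, "family_id": str,
                                            "parent_id": str, "child_id": str})
    missing = set(MEIOSIS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"meiosis table missing columns: {sorted(missing)}")
    return df


def write_call_table(calls: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in calls.columns if c in CALL_COLUMNS] + [
        c for c in calls.columns if c not in CALL_COLUMNS
    ]
    calls[cols].to_csv(path, sep="\t", index=False)


def read_call_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cohort": str, "parent_id": str,
                                            "child_id": str, "chrom": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    return df


def write_fam(meioses: pd.DataFrame, fam_path: str | Path, sidecar_path: str | Path) -> None:
    """Write a FAM pedigree plus an age/cohort sidecar from a meiosis table.

    Each meiosis contributes its child with the recorded parent placed in
    the father or mother slot according to parent_sex; the parent also gets
    a founder row. Phenotype is -9 (missing) throughout.
    """
    fam_rows: list[tuple] = []
    seen: set[str] = set()
    side_rows: list[tuple] = []
    for rec in meioses.itertuples(index=False):
        father = rec.parent_id if rec.parent_sex == "M" else "0"
        mother = rec.parent_id if rec.parent_sex == "F" else "0"
        if rec.parent_id not in seen:
            seen.add(rec.parent_id)
            fam_rows.append((rec.family_id, rec.parent_id, "0", "0",
                             1 if rec.parent_sex == "M" else 2, -9))
        fam_rows.append((rec.family_id, rec.child_id, father, mother, 0, -9))
        side_rows.append((rec.child_id, rec.cohort, rec.parent_id,
                          rec.parent_sex, rec.parent_age_years, rec.configuration))
    pd.DataFrame(fam_rows, columns=FAM_COLUMNS).to_csv(
        fam_path, sep="\t", index=False, header=False
    )
    pd.DataFrame(
        side_rows,
        columns=["child_id", "cohort", "parent_id", "parent_sex",
                 "parent_age_years", "configuration"],
    ).to_csv(sidecar_path, sep="\t", index=False)


def read_fam(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                     dtype={"family_id": str, "individual_id": str,
                            "father_id": str, "mother_id": str})
    return df
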