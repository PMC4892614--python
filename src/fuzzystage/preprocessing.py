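"""Clinical-variable grouping ("normalisation") for the staging predictor.

Raw pre-operative variables — biopsy Gleason patterns, pre-treatment PSA,
age at diagnosis and the DRE-derived clinical T stage — are mapped onto
small ordinal scales before they enter the fuzzy predictor, and the
post-prostatectomy pathological T stage is reduced to the binary target:
1 = Organ-Confined Disease (OCD, pT2 family), 2 = Extra-Prostatic Disease
(ED, pT3/pT4 family).

The bin edges follow the published grouping tables; printed ranges leave
small gaps (e.g. 2.5 → 2.6 ng/mL), which are closed by half-open intervals
using the next group's lower bound, so every positive value has a group.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RawPatientRecord",
    "GroupedPatientRecord",
    "GroupingError",
    "VocabularyError",
    "CohortSchemaError",
    "group_psa",
    "group_age",
    "group_clinical_t",
    "group_pathological_t",
    "normalize_record",
    "normalize_cohort",
    "read_cohort",
    "write_grouped_cohort",
    "grouped_to_frame",
    "cohort_summary",
    "CLINICAL_T_CODES",
    "PATHOLOGICAL_T_CODES",
    "INPUT_NAMES",
    "GROUP_RANGES",
]


class GroupingError(ValueError):
    """A raw value is outside the domain of its grouping function."""


class VocabularyError(GroupingError):
    """A T-stage code is not in the closed vocabulary."""


class CohortSchemaError(ValueError):
    """A cohort CSV is missing required columns or has unparsable cells."""


CLINICAL_T_CODES = ("T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4")
PATHOLOGICAL_T_CODES = ("T2", "T2a", "T2b", "T2c", "T3a", "T3b", "T4")

#: Input variable order used throughout the package (matrix columns).
INPUT_NAMES = ("primary_gleason", "secondary_gleason", "psa_group",
               "age_group", "clinical_t_group")

#: Inclusive ordinal range of each grouped input.
GROUP_RANGES = {
    "primary_gleason": (3, 5),
    "secondary_gleason": (3, 5),
    "psa_group": (1, 6),
    "age_group": (1, 11),
    "clinical_t_group": (1, 5),
}

# Lower bounds of PSA groups 2..6 (group 1 starts at 0); half-open bins.
_PSA_EDGES = (2.6, 4.1, 6.1, 10.0, 20.0)
# Age groups are five-year bins: group 1 is <25, group 11 is >=70.
_AGE_EDGES = tuple(25 + 5 * i for i in range(10))  # 25,30,...,70

_CLINICAL_T_GROUP = {
    "T1a": 1, "T1b": 1, "T1c": 1,
    "T2a": 2, "T2b": 3, "T2c": 4,
    "T3a": 5, "T3b": 5, "T4": 5,
}
_PT_GROUP = {"T2": 1, "T2a": 1, "T2b": 1, "T2c": 1, "T3a": 2, "T3b": 2, "T4": 2}


@dataclass(frozen=True)
class RawPatientRecord:
    """One patient's unnormalised clinical variables.

    ``pathological_t`` is optional: it is absent in prediction mode.
    """

    primary_gleason: int
    secondary_gleason: int
    psa_ng_ml: float
    age_years: float
    clinical_t: str
    pathological_t: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("primary_gleason", "secondary_gleason"):
            v = getattr(self, name)
            if v not in (3, 4, 5):
                raise GroupingError(f"{name} must be a Gleason pattern 3-5, got {v!r}")
        if not (np.isfinite(self.psa_ng_ml) and self.psa_ng_ml > 0):
            raise GroupingError(f"psa_ng_ml must be positive, got {self.psa_ng_ml!r}")
        if not (np.isfinite(self.age_years) and self.age_years > 0):
            raise GroupingError(f"age_years must be positive, got {self.age_years!r}")


@dataclass(frozen=True)
class GroupedPatientRecord:
    """The five ordinal inputs, plus the binary target when known."""

    primary_gleason: int
    secondary_gleason: int
    psa_group: int
    age_group: int
    clinical_t_group: int
    pt_group: Optional[int] = None

    def as_vector(self) -> np.ndarray:
        return np.array([self.primary_gleason, self.secondary_gleason,
                         self.psa_group, self.age_group,
                         self.clinical_t_group], dtype=float)


def group_psa(psa_ng_ml: float) -> int:
    """Map a pre-treatment PSA level (ng/mL) to ordinal group 1-6.

    Bins: [0, 2.6) -> 1, [2.6, 4.1) -> 2, [4.1, 6.1) -> 3, [6.1, 10) -> 4,
    [10, 20) -> 5, [20, inf) -> 6.
    """
    psa = float(psa_ng_ml)
    if not np.isfinite(psa) or psa <= 0:
        raise GroupingError(f"PSA must be a positive number, got {psa_ng_ml!r}")
    return int(np.searchsorted(_PSA_EDGES, psa, side="right")) + 1


def group_age(age_years: float) -> int:
    """Map age at diagnosis (years) to ordinal group 1-11 (five-year bins).

    Group 1 is under 25; group 11 is 70 and above.
    """
    age = float(age_years)
    if not np.isfinite(age) or age <= 0:
        raise GroupingError(f"age must be a positive number, got {age_years!r}")
    return int(np.searchsorted(_AGE_EDGES, age, side="right")) + 1


def group_clinical_t(code: str) -> int:
    """Map a clinical T stage code to ordinal group 1-5.

    T1a-c -> 1, T2a -> 2, T2b -> 3, T2c -> 4, T3a/T3b/T4 -> 5.  An
    unknown-laterality "T2" is not in the published grouping; it is mapped
    to group 2 (the most conservative T2 subgroup) with a warning.
    """
    code = _canon_t(code)
    if code == "T2":
        warnings.warn("clinical stage 'T2' without laterality: assigning the "
                      "most conservative T2 group (2)", stacklevel=2)
        return 2
    try:
        return _CLINICAL_T_GROUP[code]
    except KeyError:
        raise VocabularyError(f"unknown clinical T code {code!r}; "
                              f"expected one of {CLINICAL_T_CODES}") from None


def group_pathological_t(code: str) -> int:
    """Map a pathological T (pT) stage code to the binary target.

    pT2 family -> 1 (Organ-Confined Disease); pT3a/pT3b/pT4 -> 2
    (Extra-Prostatic Disease).  There is no pT1 classification.
    """
    code = _canon_t(code)
    if code.startswith("T1"):
        raise VocabularyError("there is no pT1 classification")
    try:
        return _PT_GROUP[code]
    except KeyError:
        raise VocabularyError(f"unknown pathological T code {code!r}; "
                              f"expected one of {PATHOLOGICAL_T_CODES}") from None


def _canon_t(code) -> str:
    """Canonicalise a T code: strip a leading 'p', upper-case the T."""
    if not isinstance(code, str) or not code.strip():
        raise VocabularyError(f"T stage code must be a non-empty string, got {code!r}")
    c = code.strip()
    if c[0] in "pP":
        c = c[1:]
    return c[:1].upper() + c[1:].lower() if len(c) > 1 else c.upper()


def normalize_record(raw: RawPatientRecord) -> GroupedPatientRecord:
    """Apply all grouping rules to one raw record.

    Gleason patterns pass through unchanged (already ordinal 3-5).
    """
    pt = None if raw.pathological_t is None else group_pathological_t(raw.pathological_t)
    return GroupedPatientRecord(
        primary_gleason=raw.primary_gleason,
        secondary_gleason=raw.secondary_gleason,
        psa_group=group_psa(raw.psa_ng_ml),
        age_group=group_age(raw.age_years),
        clinical_t_group=group_clinical_t(raw.clinical_t),
        pt_group=pt,
    )


def normalize_cohort(records: Iterable[RawPatientRecord]) -> list[GroupedPatientRecord]:
    return [normalize_record(r) for r in records]


_REQUIRED_COLUMNS = ("primary_gleason", "secondary_gleason", "psa", "age", "clinical_t")


def read_cohort(path, column_map: Optional[dict] = None) -> list[RawPatientRecord]:
    """Read a raw cohort CSV into records.

    The file must be comma-separated UTF-8 with a header naming the columns
    primary_gleason, secondary_gleason, psa, age, clinical_t and optionally
    pathological_t.  ``column_map`` renames file columns to these canonical
    names (canonical -> file column).  Unparsable cells raise with the
    1-based CSV line number.
    """
    column_map = column_map or {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = [c for c in _REQUIRED_COLUMNS
                   if column_map.get(c, c) not in reader.fieldnames]
        if missing:
            raise CohortSchemaError(f"cohort file {path} is missing columns: {missing}")
        has_pt = column_map.get("pathological_t", "pathological_t") in reader.fieldnames
        records = []
        for lineno, row in enumerate(reader, start=2):
            def cell(name, _row=row):
                return _row[column_map.get(name, name)]
            try:
                pt = cell("pathological_t").strip() if has_pt else ""
                records.append(RawPatientRecord(
                    primary_gleason=int(cell("primary_gleason")),
                    secondary_gleason=int(cell("secondary_gleason")),
                    psa_ng_ml=float(cell("psa")),
                    age_years=float(cell("age")),
                    clinical_t=cell("clinical_t").strip(),
                    pathological_t=pt or None,
                ))
            except (ValueError, KeyError, TypeError) as exc:
                raise CohortSchemaError(f"{path}, line {lineno}: {exc}") from exc
    return records


def grouped_to_frame(records: Iterable[GroupedPatientRecord]) -> pd.DataFrame:
    """Tabulate grouped records (columns in the standard input order + pt_group)."""
    rows = [{**{n: getattr(r, n) for n in INPUT_NAMES}, "pt_group": r.pt_group}
            for r in records]
    return pd.DataFrame(rows, columns=list(INPUT_NAMES) + ["pt_group"])


def write_grouped_cohort(records: Iterable[GroupedPatientRecord], path) -> None:
    grouped_to_frame(records).to_csv(path, index=False)


def cohort_summary(records: list[GroupedPatientRecord]) -> pd.DataFrame:
    """Per-variable min/max/mean/SD on the grouped scale, plus discordance.

    The clinical-vs-pathological discordance count is the number of patients
    found extra-prostatic at pathology (pt_group 2) minus the number already
    extra-prostatic clinically (clinical T group 5), floored at zero — the
    patients whose extra-prostatic disease the DRE missed.
    """
    if not records:
        raise ValueError("cannot summarise an empty cohort")
    if any(r.pt_group is None for r in records):
        raise ValueError("cohort summary requires pathological outcomes on every record")
    df = grouped_to_frame(records)
    stats = df.agg(["min", "max", "mean", "std"]).T
    stats.columns = ["min", "max", "mean", "sd"]
    n = len(df)
    ed = int((df["pt_group"] == 2).sum())
    clin_ed = int((df["clinical_t_group"] == 5).sum())
    discordant = max(ed - clin_ed, 0)
    stats.attrs["n"] = n
    stats.attrs["discordant_count"] = discordant
    stats.attrs["discordant_percent"] = 100.0 * discordant / n
    return stats
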