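"""Seeded synthetic cohorts with the published dataset's structure.

The study table itself is not redistributable, but its grouped-variable
marginals, the 179/220 organ-confined vs extra-prostatic prevalence, and
the class-conditional means are all printed.  The generator draws a class
label first, then each grouped variable from a class-conditional
categorical obtained by exponentially tilting the published marginal
(tilt +delta*(1-pi)*g for ED, -delta*pi*g for OCD, which preserves the
marginal to first order), and finally draws a raw value uniformly within
the group's numeric interval, so grouping the raw cohort returns exactly
the sampled groups.

The default tilts were calibrated once against the published
class-conditional means (ED minus OCD differences 0.16 / 0.16 / 0.32 for
primary Gleason, secondary Gleason and clinical T); PSA and age tilts are
zero because the study found no significant class difference for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fis import SugenoFIS, infer_batch
from .preprocessing import (GROUP_RANGES, INPUT_NAMES, RawPatientRecord)

__all__ = ["CohortSpec", "generate_cohort", "raw_from_group",
           "generate_from_fis", "MARGINALS", "DEFAULT_CLASS_SHIFT",
           "ED_PREVALENCE", "calibrate_shift"]

#: Published grouped-variable marginal frequencies (counts out of 399).
MARGINALS = {
    "primary_gleason": {3: 205, 4: 173, 5: 21},
    "secondary_gleason": {3: 159, 4: 185, 5: 55},
    "psa_group": {1: 16, 2: 33, 3: 124, 4: 124, 5: 67, 6: 35},
    "age_group": {1: 0, 2: 0, 3: 0, 4: 0, 5: 5, 6: 22, 7: 68, 8: 97,
                  9: 100, 10: 76, 11: 31},
    "clinical_t_group": {1: 204, 2: 53, 3: 53, 4: 42, 5: 47},
}

ED_PREVALENCE = 220 / 399

#: Per-variable exponential-tilt shifts (log-odds per ordinal step between
#: the ED and OCD conditionals), calibrated once against the published
#: class-conditional means; zero where no class difference was reported.
DEFAULT_CLASS_SHIFT = {
    "primary_gleason": 0.4569,
    "secondary_gleason": 0.3439,
    "psa_group": 0.0,
    "age_group": 0.0,
    "clinical_t_group": 0.1547,
}

# Raw-value intervals per group.  Top groups are capped just above the
# published maxima (PSA 107.00 -> 110; age 78.0 -> 90); PSA group 1 starts
# at 0.1 since PSA must be positive.
_PSA_INTERVALS = {1: (0.1, 2.6), 2: (2.6, 4.1), 3: (4.1, 6.1),
                  4: (6.1, 10.0), 5: (10.0, 20.0), 6: (20.0, 110.0)}
_AGE_INTERVALS = {1: (18.0, 25.0), 11: (70.0, 90.0)}
for _g in range(2, 11):  # five-year bins [25,30) .. [65,70)
    _AGE_INTERVALS[_g] = (20.0 + 5.0 * (_g - 1), 20.0 + 5.0 * _g)

_CLINICAL_T_BY_GROUP = {1: ("T1a", "T1b", "T1c"), 2: ("T2a",), 3: ("T2b",),
                        4: ("T2c",), 5: ("T3a", "T3b", "T4")}
# Relative frequencies within group 5 (29/16/2) and within group 1
# (T1 subcodes are not broken down in the published table: uniform).
_GROUP5_WEIGHTS = np.array([29, 16, 2]) / 47.0

_PT_BY_CLASS = {1: ("T2", "T2a", "T2b", "T2c"), 2: ("T3a", "T3b", "T4")}
_PT_WEIGHTS = {1: np.array([1, 14, 47, 117]) / 179.0,
               2: np.array([142, 72, 6]) / 220.0}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n: int = 399
    ed_prevalence: float = ED_PREVALENCE
    marginals: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in MARGINALS.items()})
    class_shift: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SHIFT))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        if not 0.0 < self.ed_prevalence < 1.0:
            raise ValueError("ed_prevalence must be in (0, 1)")
        for name, freq in self.marginals.items():
            total = float(sum(freq.values()))
            if total <= 0 or any(v < 0 for v in freq.values()):
                raise ValueError(f"invalid marginal frequencies for {name}")


def _conditionals(probs: np.ndarray, cats: np.ndarray, shift: float,
                  prevalence: float):
    """OCD- and ED-conditional categoricals by exponential tilting."""
    q_ed = probs * np.exp(shift * (1.0 - prevalence) * cats)
    q_ocd = probs * np.exp(-shift * prevalence * cats)
    return q_ocd / q_ocd.sum(), q_ed / q_ed.sum()


def calibrate_shift(probs: np.ndarray, cats: np.ndarray, target_diff: float,
                    prevalence: float = ED_PREVALENCE) -> float:
    """Solve for the tilt giving a target ED-minus-OCD conditional mean
    difference (used once to fix the package defaults)."""
    from scipy.optimize import brentq
    cats = np.asarray(cats, float)

    def gap(d):
        q_ocd, q_ed = _conditionals(probs, cats, d, prevalence)
        return float(q_ed @ cats - q_ocd @ cats) - target_diff

    return float(brentq(gap, -5.0, 5.0))


def raw_from_group(variable: str, group: int, rng: np.random.Generator):
    """Draw a raw value uniformly within a group's numeric interval.

    Gleason patterns are returned unchanged; clinical T group 5 draws a
    code from T3a/T3b/T4 with the published relative frequencies.
    """
    if variable in ("primary_gleason", "secondary_gleason"):
        if group not in (3, 4, 5):
            raise ValueError(f"invalid Gleason pattern {group}")
        return int(group)
    if variable == "psa_group":
        try:
            lo, hi = _PSA_INTERVALS[group]
        except KeyError:
            raise ValueError(f"invalid PSA group {group}") from None
        return float(rng.uniform(lo, hi))
    if variable == "age_group":
        try:
            lo, hi = _AGE_INTERVALS[group]
        except KeyError:
            raise ValueError(f"invalid age group {group}") from None
        return float(rng.uniform(lo, hi))
    if variable == "clinical_t_group":
        try:
            codes = _CLINICAL_T_BY_GROUP[group]
        except KeyError:
            raise ValueError(f"invalid clinical T group {group}") from None
        if group == 5:
            return str(rng.choice(codes, p=_GROUP5_WEIGHTS))
        return str(rng.choice(codes))
    raise ValueError(f"unknown variable {variable!r}")


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[RawPatientRecord]:
    """Generate a seeded raw cohort with the study's statistical structure.

    For each patient the outcome class is drawn first (ED with probability
    ``ed_prevalence``), each grouped input from the class-conditional
    categorical, the raw value uniformly within the group's interval, and
    a pathological T code from the published within-class pT frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    # precompute conditional distributions per variable
    cond = {}
    for name in INPUT_NAMES:
        freq = spec.marginals[name]
        cats = np.array(sorted(freq))
        probs = np.array([freq[c] for c in cats], float)
        probs /= probs.sum()
        shift = spec.class_shift.get(name, 0.0)
        q_ocd, q_ed = _conditionals(probs, cats.astype(float), shift,
                                    spec.ed_prevalence)
        cond[name] = (cats, q_ocd, q_ed)

    records = []
    for _ in range(spec.n):
        cls = 2 if rng.random() < spec.ed_prevalence else 1
        groups = {}
        for name in INPUT_NAMES:
            cats, q_ocd, q_ed = cond[name]
            q = q_ed if cls == 2 else q_ocd
            groups[name] = int(rng.choice(cats, p=q))
        pt_codes = _PT_BY_CLASS[cls]
        pt = str(rng.choice(pt_codes, p=_PT_WEIGHTS[cls]))
        records.append(RawPatientRecord(
            primary_gleason=raw_from_group("primary_gleason",
                                           groups["primary_gleason"], rng),
            secondary_gleason=raw_from_group("secondary_gleason",
                                             groups["secondary_gleason"], rng),
            psa_ng_ml=raw_from_group("psa_group", groups["psa_group"], rng),
            age_years=raw_from_group("age_group", groups["age_group"], rng),
            clinical_t=raw_from_group("clinical_t_group",
                                      groups["clinical_t_group"], rng),
            pathological_t=pt,
        ))
    return records


def generate_from_fis(fis: SugenoFIS, n: int, noise_sd: float = 0.0,
                      seed: int = 0):
    """Simulate (inputs, targets) from a known Sugeno system.

    Inputs are uniform over each input's declared range; targets are the
    inference outputs plus Gaussian noise of sd ``noise_sd``.  Supports the
    parameter-recovery experiments for the training loop.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = fis.n_inputs
    X = np.empty((n, d))
    for j, name in enumerate(fis.input_names):
        lo, hi = fis.input_ranges[name]
        X[:, j] = rng.uniform(lo, hi, size=n)
    if n == 0:
        return X, np.empty(0)
    y = infer_batch(fis, X)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return X, y
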