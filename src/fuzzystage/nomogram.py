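"""AJCC 2010 anatomic stage / prognostic groups for prostate cancer.

The clinical baseline: a rule table combining clinical T, N and M codes
with PSA and the Gleason score sum into stage groups I, IIA, IIB, III and
IV.  Stages I and II are organ-confined; III and IV are extra-prostatic,
which gives the binary reduction used for comparison with the neuro-fuzzy
predictor, and the stage's ordinal rank (1-5) serves as a 5-level score
for ROC analysis.

Rows are evaluated in the published top-to-bottom order, first match wins.
Rows whose PSA or Gleason column reads "X" apply only when that marker is
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = ["TNMInput", "StageGroup", "UnstageableError", "anatomic_stage",
           "binary_stage", "nomogram_score", "N_CODES", "M_CODES"]

N_CODES = ("NX", "N0", "N1")
M_CODES = ("M0", "M1", "M1a", "M1b", "M1c")
T_CODES = ("TX", "T0", "T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4")


class UnstageableError(ValueError):
    """No stage-group row matches the given TNM input."""


class StageGroup(Enum):
    I = 1
    IIA = 2
    IIB = 3
    III = 4
    IV = 5

    @property
    def score(self) -> int:
        """Ordinal rank 1-5 (the 5-level ROC score)."""
        return self.value

    def __lt__(self, other):
        if isinstance(other, StageGroup):
            return self.value < other.value
        return NotImplemented


@dataclass(frozen=True)
class TNMInput:
    t_code: str
    n_code: str = "N0"
    m_code: str = "M0"
    psa: Optional[float] = None          # ng/mL; None = unknown
    gleason_sum: Optional[int] = None    # 6-10; None = unknown

    def __post_init__(self) -> None:
        if self.t_code not in T_CODES:
            raise ValueError(f"unknown clinical T code {self.t_code!r}")
        if self.n_code not in N_CODES:
            raise ValueError(f"unknown N code {self.n_code!r}")
        if self.m_code not in M_CODES:
            raise ValueError(f"unknown M code {self.m_code!r}")
        if self.psa is not None and not (np.isfinite(self.psa) and self.psa > 0):
            raise ValueError("known PSA must be positive")
        if self.gleason_sum is not None and self.gleason_sum not in range(2, 11):
            raise ValueError("known Gleason sum must be an integer 2-10")


# T-code families used by the table rows
_T1AC = ("T1a", "T1b", "T1c")
_T12A = _T1AC + ("T2a",)
_T12 = _T1AC + ("T2a", "T2b", "T2c")

# PSA predicates: None argument means "unknown"
def _psa_lt(bound):
    return lambda psa: psa is not None and psa < bound

def _psa_10_20(psa):
    return psa is not None and 10 <= psa < 20

def _psa_ge20(psa):
    return psa is not None and psa >= 20

def _psa_any(psa):
    return True

def _psa_unknown(psa):
    return psa is None

def _gs_le(bound):
    return lambda gs: gs is not None and gs <= bound

def _gs_eq(value):
    return lambda gs: gs is not None and gs == value

def _gs_ge(bound):
    return lambda gs: gs is not None and gs >= bound

def _gs_any(gs):
    return True

def _gs_unknown(gs):
    return gs is None


# The stage table: (group, T family, N, M, PSA predicate, GS predicate),
# in published order; "ANY_T" matches every T code including TX/T0.
_ROWS = [
    (StageGroup.I,   _T1AC,   "N0", "M0", _psa_lt(10), _gs_le(6)),
    (StageGroup.I,   ("T2a",), "N0", "M0", _psa_lt(10), _gs_le(6)),
    (StageGroup.I,   _T12A,   "N0", "M0", _psa_unknown, _gs_unknown),
    (StageGroup.IIA, _T1AC,   "N0", "M0", _psa_lt(20), _gs_eq(7)),
    (StageGroup.IIA, _T1AC,   "N0", "M0", _psa_10_20,  _gs_le(6)),
    (StageGroup.IIA, ("T2a",), "N0", "M0", _psa_lt(20), _gs_le(7)),
    (StageGroup.IIA, ("T2b",), "N0", "M0", _psa_lt(20), _gs_le(7)),
    (StageGroup.IIA, ("T2b",), "N0", "M0", _psa_unknown, _gs_unknown),
    (StageGroup.IIB, ("T2c",), "N0", "M0", _psa_any, _gs_any),
    (StageGroup.IIB, _T12,    "N0", "M0", _psa_ge20, _gs_any),
    (StageGroup.IIB, _T12,    "N0", "M0", _psa_any, _gs_ge(8)),
    (StageGroup.III, ("T3a", "T3b"), "N0", "M0", _psa_any, _gs_any),
    (StageGroup.IV,  ("T4",), "N0", "M0", _psa_any, _gs_any),
    (StageGroup.IV,  "ANY_T", "N1", "M0", _psa_any, _gs_any),
    (StageGroup.IV,  "ANY_T", "ANY_N", "M1", _psa_any, _gs_any),
]


def anatomic_stage(tnm: TNMInput) -> StageGroup:
    """Stage a patient by the first matching row of the AJCC 2010 table."""
    for group, t_fam, n_req, m_req, psa_pred, gs_pred in _ROWS:
        if t_fam != "ANY_T" and tnm.t_code not in t_fam:
            continue
        if n_req != "ANY_N" and tnm.n_code != n_req:
            continue
        if m_req == "M1":
            if not tnm.m_code.startswith("M1"):
                continue
        elif tnm.m_code != m_req:
            continue
        if psa_pred(tnm.psa) and gs_pred(tnm.gleason_sum):
            return group
    raise UnstageableError(f"no anatomic stage group matches {tnm}")


def binary_stage(group: StageGroup) -> str:
    """Binary reduction: stages I-II organ-confined, III-IV extra-prostatic."""
    return "OCD" if group in (StageGroup.I, StageGroup.IIA, StageGroup.IIB) else "ED"


def nomogram_score(tnm: TNMInput) -> int:
    """The stage group's ordinal rank (1-5), used as a classifier score."""
    return anatomic_stage(tnm).score
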