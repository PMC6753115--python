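"""Clinical classification rules and classification-consistent covariates.

The five-group continuum (CH, SCD, eMCI, lMCI, AD) is defined by a
complaint question ("Do you feel like your memory is becoming worse?"),
the MoCA screen, the Clinical Dementia Rating (CDR) and an
education-stratified Logical Memory (LM) story-recall cutoff. Rules are
evaluated CDR-first: CDR 1.0 can only be AD, CDR 0.5 only eMCI/lMCI,
CDR 0 only SCD/CH — this resolves every overlap between the LM bands
(the eMCI "borderline" band is a strict subset of the SCD/CH "normal"
range at every education level).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

COMPLAINTS = ("none", "yes_no_worry", "yes_worry")
CDR_VALUES = (0.0, 0.5, 1.0)

GROUPS = ["CH", "SCD", "eMCI", "lMCI", "AD"]
UNCLASSIFIED = "UNCLASSIFIED"


class LmBand(str, Enum):
    IMPAIRED = "impaired_AD_lMCI"
    BORDERLINE = "borderline_eMCI"
    NORMAL = "normal"


@dataclass(frozen=True)
class ClinicalRecord:
    complaint: str
    moca: int
    cdr: float
    lm_score: int
    education_years: int

    def __post_init__(self) -> None:
        if self.complaint not in COMPLAINTS:
            raise ValueError(f"unknown complaint {self.complaint!r}")
        if not 0 <= self.moca <= 30:
            raise ValueError("MoCA must lie in [0, 30]")
        if self.cdr not in CDR_VALUES:
            raise ValueError(f"CDR must be one of {CDR_VALUES}")
        if self.lm_score < 0 or self.education_years < 0:
            raise ValueError("LM score and education must be nonnegative")


def _lm_cuts(education_years: int) -> tuple[int, tuple[int, int], int]:
    """(impaired max, borderline range, normal min) for the education stratum."""
    if education_years >= 16:
        return 8, (9, 11), 9
    if education_years >= 8:
        return 4, (5, 9), 5
    return 2, (3, 6), 3


def lm_band(education_years: int, lm_score: int) -> LmBand:
    """Primary LM band, by severity priority impaired > borderline > normal.

    The borderline range is a subset of the normal range, so band membership
    as used by :func:`classify_participant` is tested with explicit
    predicates rather than this single label.
    """
    if education_years < 0 or lm_score < 0:
        raise ValueError("education and LM score must be nonnegative")
    imp, (b_lo, b_hi), _ = _lm_cuts(education_years)
    if lm_score <= imp:
        return LmBand.IMPAIRED
    if b_lo <= lm_score <= b_hi:
        return LmBand.BORDERLINE
    return LmBand.NORMAL


def _lm_impaired(edu: int, lm: int) -> bool:
    imp, _, _ = _lm_cuts(edu)
    return lm <= imp


def _lm_borderline(edu: int, lm: int) -> bool:
    _, (lo, hi), _ = _lm_cuts(edu)
    return lo <= lm <= hi


def _lm_normal(edu: int, lm: int) -> bool:
    _, _, norm = _lm_cuts(edu)
    return lm >= norm


def classify_participant(rec: ClinicalRecord) -> str:
    """Map a complete clinical record to exactly one group label.

    Any record matching no rule falls through to ``UNCLASSIFIED``.
    """
    has_complaint = rec.complaint in ("yes_no_worry", "yes_worry")
    edu, lm = rec.education_years, rec.lm_score
    if rec.cdr == 1.0:
        if has_complaint and 13 <= rec.moca <= 25 and _lm_impaired(edu, lm):
            return "AD"
        return UNCLASSIFIED
    if rec.cdr == 0.5:
        if has_complaint and 20 <= rec.moca <= 25 and _lm_impaired(edu, lm):
            return "lMCI"
        if has_complaint and 20 <= rec.moca <= 26 and _lm_borderline(edu, lm):
            return "eMCI"
        return UNCLASSIFIED
    # CDR 0
    if rec.moca >= 26 and _lm_normal(edu, lm):
        if rec.complaint == "yes_worry":
            return "SCD"
        return "CH"
    return UNCLASSIFIED


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a cohort table; adds ``predicted_group``."""
    preds = []
    for _, row in table.iterrows():
        rec = ClinicalRecord(
            complaint=row["complaint"],
            moca=int(row["moca"]),
            cdr=float(row["cdr"]),
            lm_score=int(row["lm_score"]),
            education_years=int(row["education_years"]),
        )
        preds.append(classify_participant(rec))
    out = table.copy()
    out["predicted_group"] = preds
    return out


# ---------------------------------------------------------------------------
# covariate generation
# ---------------------------------------------------------------------------

#: per-group covariate distributions of the emulated study sample:
#: age / anxiety (GAI) / depression (GDS) / MoCA / delayed recall (RAVLT)
#: as (mean, sd); female fraction from the reported sex counts.
GROUP_COVARIATES: dict[str, dict] = {
    "CH": dict(age=(70, 6.3), female=17 / 29, gai=(1.3, 2.5), gds=(2.2, 2.9),
               moca=(28.0, 1.94), ravlt=(11.2, 2.3)),
    "SCD": dict(age=(71, 6.4), female=37 / 66, gai=(2.9, 3.5), gds=(5.6, 4.4),
                moca=(27.7, 1.38), ravlt=(9.5, 2.7)),
    "eMCI": dict(age=(73, 8.4), female=11 / 22, gai=(3.1, 4.6), gds=(6.6, 5.3),
                 moca=(25.2, 1.82), ravlt=(7.9, 3.1)),
    "lMCI": dict(age=(76, 6.9), female=4 / 8, gai=(4.6, 7.5), gds=(7.1, 6.5),
                 moca=(23.1, 3.09), ravlt=(3.4, 2.4)),
    "AD": dict(age=(75, 7.7), female=6 / 12, gai=(1.6, 2.5), gds=(4.6, 2.6),
               moca=(17.2, 5.36), ravlt=(0.6, 1.2)),
}

#: admissible MoCA range per group (classification rules)
_MOCA_RANGE = {
    "CH": (26, 30),
    "SCD": (26, 30),
    "eMCI": (20, 26),
    "lMCI": (20, 25),
    "AD": (13, 25),
}

_CDR = {"CH": 0.0, "SCD": 0.0, "eMCI": 0.5, "lMCI": 0.5, "AD": 1.0}


from functools import lru_cache


@lru_cache(maxsize=64)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter such that the truncated normal's mean hits the
    target (truncation would otherwise shift it)."""
    loc = mean
    for _ in range(8):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        loc -= sps.truncnorm.mean(a, b, loc=loc, scale=sd) - mean
    return loc


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    loc = _matched_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(sps.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


def sample_covariates(group: str, rng: np.random.Generator) -> dict:
    """Draw one subject's covariates, consistent with the group's rules.

    Continuous scores use truncated normals with the study-sample moments,
    truncated to each group's admissible classification range so that
    generated records round-trip through :func:`classify_participant`.
    """
    if group not in GROUP_COVARIATES:
        raise ValueError(f"unknown group {group!r}")
    p = GROUP_COVARIATES[group]
    age = _trunc_normal(rng, *p["age"], 65.0, 95.0)
    sex = "F" if rng.random() < p["female"] else "M"
    education = int(np.clip(round(rng.normal(14.0, 3.0)), 7, 20))
    lo, hi = _MOCA_RANGE[group]
    moca = int(np.clip(round(_trunc_normal(rng, *p["moca"], lo, hi)), lo, hi))
    if group == "CH":
        complaint = str(rng.choice(["none", "yes_no_worry"]))
    elif group == "SCD":
        complaint = "yes_worry"
    else:
        complaint = str(rng.choice(["yes_no_worry", "yes_worry"]))
    imp, (b_lo, b_hi), norm = _lm_cuts(education)
    if group in ("CH", "SCD"):
        lm = int(rng.integers(norm, 26))
    elif group == "eMCI":
        lm = int(rng.integers(b_lo, b_hi + 1))
    else:
        lm = int(rng.integers(0, imp + 1))
    gai = int(np.clip(round(rng.normal(*p["gai"])), 0, 20))
    gds = int(np.clip(round(rng.normal(*p["gds"])), 0, 30))
    ravlt = int(np.clip(round(rng.normal(*p["ravlt"])), 0, 15))
    return {
        "age": age,
        "sex": sex,
        "education_years": education,
        "moca": moca,
        "cdr": _CDR[group],
        "lm_score": lm,
        "complaint": complaint,
        "gai": gai,
        "gds": gds,
        "ravlt": ravlt,
    }


def exhaustive_partition_check(max_lm: int = 25) -> int:
    """Scan the discrete clinical grid and count records matching >1 group.

    Each rule is evaluated independently (ignoring the CDR-first dispatch) so
    a non-zero count would mean the rule set is not a partition. Returns the
    number of multiply-matched records (expected 0).
    """
    multi = 0
    edus = (6, 10, 16)  # one representative per education stratum
    for complaint in COMPLAINTS:
        has = complaint != "none"
        for moca in range(31):
            for cdr in CDR_VALUES:
                for edu in edus:
                    for lm in range(max_lm + 1):
                        hits = 0
                        if cdr == 1.0 and has and 13 <= moca <= 25 and _lm_impaired(edu, lm):
                            hits += 1
                        if cdr == 0.5 and has and 20 <= moca <= 25 and _lm_impaired(edu, lm):
                            hits += 1
                        if cdr == 0.5 and has and 20 <= moca <= 26 and _lm_borderline(edu, lm):
                            hits += 1
                        if cdr == 0.0 and complaint == "yes_worry" and moca >= 26 and _lm_normal(edu, lm):
                            hits += 1
                        if cdr == 0.0 and complaint in ("none", "yes_no_worry") and moca >= 26 and _lm_normal(edu, lm):
                            hits += 1
                        if hits > 1:
                            multi += 1
    return multi
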