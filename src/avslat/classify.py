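"""Rule-based subtype classification and cohort eligibility filtering.

Decision rules for primary-aldosteronism subtyping from AVS indices:

* catheterization success: selectivity index >= 5.0 (inclusive),
* conventional rule: lateralized index >= 4.0 diagnoses a unilateral
  aldosterone-producing adenoma (UAPA) on the dominant side; LI < 4.0
  diagnoses idiopathic hyperaldosteronism (IHA),
* modified rule: tri-class call on the modified LI — at or below the low
  threshold (default 0.7) right APA, at or above the high threshold
  (default 2.2) left APA, otherwise IHA,
* fallback adjudication: when right adrenal-vein sampling is unselective
  (SI < 5), the modified rule substitutes for the conventional one,
* cohort eligibility filter reproducing the study-style exclusion cascade
  (incomplete right sampling, unoperated UAPA, post-operative ARR not
  normalized, post-operative blood pressure not normalized, lost follow-up).

Threshold boundaries attach to the abnormal class throughout (<= low /
>= high), mirroring the inclusive "LI >= 4.0" convention.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .indices import IndexSet, Measurement, Side

__all__ = [
    "Subtype",
    "Rule",
    "ExclusionReason",
    "Thresholds",
    "PatientMeta",
    "PatientRecord",
    "SubtypeCall",
    "IncompleteMetadataError",
    "catheterization_success",
    "subtype_conventional",
    "subtype_modified",
    "adjudicate",
    "cohort_filter",
]


class Subtype(str, enum.Enum):
    RT_APA = "rt_APA"
    LT_APA = "lt_APA"
    IHA = "IHA"
    UAPA_UNSPECIFIED = "UAPA_unspecified"


class Rule(str, enum.Enum):
    CONVENTIONAL = "conventional"
    MODIFIED = "modified"
    FALLBACK = "fallback"


class ExclusionReason(str, enum.Enum):
    """Eligibility exclusions, checked in this order; first failure counts."""

    INCOMPLETE_RT_SAMPLING = "incomplete_rt_sampling"
    UAPA_WITHOUT_SURGERY = "uapa_without_surgery"
    POSTOP_ARR_NOT_NORMALIZED = "postop_arr_not_normalized"
    POSTOP_BP_NOT_NORMALIZED = "postop_bp_not_normalized"
    NO_FOLLOWUP = "no_followup"


class IncompleteMetadataError(ValueError):
    """A required eligibility flag is missing from a patient record."""


# ARR normal range upper bound after surgery (PAC/PRA, dimensionless).
ARR_NORMAL_UPPER = 200.0


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the classification rules.

    si_success : SI at or above which catheterization counts as successful.
    li_uapa    : conventional LI at or above which UAPA is diagnosed.
    mli_rt     : modified LI at or below which right APA is called.
    mli_lt     : modified LI at or above which left APA is called.
    """

    si_success: float = 5.0
    li_uapa: float = 4.0
    mli_rt: float = 0.7
    mli_lt: float = 2.2

    def __post_init__(self) -> None:
        if not (0 < self.mli_rt < self.mli_lt):
            raise ValueError(f"require 0 < mli_rt < mli_lt, got {self.mli_rt}, {self.mli_lt}")
        if not self.si_success > 1:
            raise ValueError(f"si_success must be > 1, got {self.si_success}")
        if not self.li_uapa > 1:
            raise ValueError(f"li_uapa must be > 1, got {self.li_uapa}")


@dataclass(frozen=True)
class PatientMeta:
    """Eligibility metadata and screening labs for one patient.

    ARR = PAC/PRA (aldosterone-renin ratio); screening-positive when > 200.
    Post-operative fields are absent (None) for patients without surgery.
    ``subtype`` carries the ground-truth class for synthetic patients.
    """

    age: Optional[float] = None
    sex: Optional[str] = None
    pac: Optional[float] = None  # plasma aldosterone concentration, pg/mL
    pra: Optional[float] = None  # plasma renin activity, ng/mL/hr
    arr: Optional[float] = None  # PAC/PRA
    rt_sampling_complete: Optional[bool] = None
    surgery_done_if_uapa: Optional[bool] = None
    postop_arr: Optional[float] = None
    postop_bp_normal: Optional[bool] = None
    followup_available: Optional[bool] = None
    ct_lesion: str = "none"  # none | right | left | bilateral
    subtype: Optional[Subtype] = None

    def __post_init__(self) -> None:
        if self.pac is not None and self.pra is not None and self.arr is not None:
            if self.pra > 0 and not math.isclose(self.arr, self.pac / self.pra, rel_tol=1e-6):
                raise ValueError(
                    f"inconsistent ARR: arr={self.arr} but pac/pra={self.pac / self.pra}"
                )


@dataclass
class PatientRecord:
    patient_id: str
    measurements: list[Measurement] = field(default_factory=list)
    meta: PatientMeta = field(default_factory=PatientMeta)


@dataclass(frozen=True)
class SubtypeCall:
    label: Subtype
    rule: Rule
    indices_used: Optional[IndexSet] = None


def catheterization_success(si: float, thresholds: Thresholds = Thresholds()) -> bool:
    """True iff the selectivity index meets the success cutoff (inclusive)."""
    if not si > 0:
        raise ValueError(f"si must be > 0, got {si!r}")
    return si >= thresholds.si_success


def subtype_conventional(
    index_set: IndexSet, thresholds: Thresholds = Thresholds()
) -> SubtypeCall:
    """Conventional call: LI >= cutoff lateralizes to the dominant side, else IHA.

    A tied LI equals 1 and can never reach the cutoff, so a lateralized call
    always has a resolved side.
    """
    if index_set.conventional_li >= thresholds.li_uapa:
        if index_set.dominant_side is Side.LEFT:
            label = Subtype.LT_APA
        elif index_set.dominant_side is Side.RIGHT:
            label = Subtype.RT_APA
        else:  # unreachable for li_uapa > 1; kept for defensive completeness
            label = Subtype.UAPA_UNSPECIFIED
        return SubtypeCall(label, Rule.CONVENTIONAL, index_set)
    return SubtypeCall(Subtype.IHA, Rule.CONVENTIONAL, index_set)


def subtype_modified(
    modified_li: float,
    thresholds: Thresholds = Thresholds(),
    index_set: Optional[IndexSet] = None,
    rule: Rule = Rule.MODIFIED,
) -> SubtypeCall:
    """Tri-class call on the modified LI; partitions (0, inf) exhaustively."""
    if not modified_li > 0:
        raise ValueError(f"modified_li must be > 0, got {modified_li!r}")
    if modified_li <= thresholds.mli_rt:
        label = Subtype.RT_APA
    elif modified_li >= thresholds.mli_lt:
        label = Subtype.LT_APA
    else:
        label = Subtype.IHA
    return SubtypeCall(label, rule, index_set)


def adjudicate(
    index_set: IndexSet, si_right_ok: bool, thresholds: Thresholds = Thresholds()
) -> SubtypeCall:
    """Dispatch: conventional rule when right sampling is selective, else the
    modified rule as fallback."""
    if si_right_ok:
        return subtype_conventional(index_set, thresholds)
    return subtype_modified(
        index_set.modified_li, thresholds, index_set, rule=Rule.FALLBACK
    )


def _require(flag, name: str, patient_id: str):
    if flag is None:
        raise IncompleteMetadataError(f"patient {patient_id}: missing eligibility flag {name!r}")
    return flag


def cohort_filter(
    records: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], dict[ExclusionReason, int]]:
    """Apply the eligibility cascade; each record counts under its first failure.

    Order: (1) right adrenal-vein sampling incomplete; (2) diagnosed UAPA but
    not operated; (3) post-operative ARR not below 200; (4) post-operative
    blood pressure not normalized; (5) follow-up unavailable.  Post-operative
    checks pass vacuously when the field is absent (no surgery performed).
    Returns the survivors and a per-reason tally;
    ``len(included) + sum(tally.values()) == len(records)`` always.
    """
    tally: dict[ExclusionReason, int] = {r: 0 for r in ExclusionReason}
    included: list[PatientRecord] = []
    for rec in records:
        m = rec.meta
        if not _require(m.rt_sampling_complete, "rt_sampling_complete", rec.patient_id):
            tally[ExclusionReason.INCOMPLETE_RT_SAMPLING] += 1
        elif not _require(m.surgery_done_if_uapa, "surgery_done_if_uapa", rec.patient_id):
            tally[ExclusionReason.UAPA_WITHOUT_SURGERY] += 1
        elif m.postop_arr is not None and m.postop_arr >= ARR_NORMAL_UPPER:
            tally[ExclusionReason.POSTOP_ARR_NOT_NORMALIZED] += 1
        elif m.postop_bp_normal is not None and not m.postop_bp_normal:
            tally[ExclusionReason.POSTOP_BP_NOT_NORMALIZED] += 1
        elif not _require(m.followup_available, "followup_available", rec.patient_id):
            tally[ExclusionReason.NO_FOLLOWUP] += 1
        else:
            included.append(rec)
    return included, tally
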