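"""Per-patient derived indices for adrenal venous sampling (AVS).

AVS localizes autonomous aldosterone secretion in primary aldosteronism by
comparing cortisol-normalized aldosterone concentrations across venous
sampling sites.  This module computes the standard derived quantities:

* selectivity index (SI) — adrenal-vein cortisol over lowest-IVC cortisol;
  SI >= 5 under ACTH stimulation indicates the catheter actually sampled
  adrenal effluent rather than caval blood,
* aldosterone/cortisol (A/C) ratio — cortisol normalization corrects for
  the unknown dilution of adrenal effluent at each site,
* conventional lateralized index (LI) — larger A/C over smaller A/C across
  the two adrenal veins,
* modified LI — left adrenal-vein A/C over the A/C of a substitute
  right-adrenal-vein sample drawn from the IVC one vertebral level above the
  right adrenal-vein confluence.  Because the substitute site carries the
  summed output of both glands (the left adrenal vein drains into the IVC
  below it, via the renal vein), low values point to a right-sided lesion,
  high values to a left-sided lesion, and intermediate values to bilateral
  (idiopathic) disease,
* a dilution-free "unit" calculator expressing the same principle with
  gland secretion counted in abstract units.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Site",
    "Phase",
    "Side",
    "Measurement",
    "IndexSet",
    "InvalidMeasurementError",
    "IncompleteSamplingError",
    "selectivity_index",
    "ac_ratio",
    "conventional_li",
    "modified_li",
    "toy_modified_li",
    "compute_index_set",
]


class Site(str, enum.Enum):
    """The four AVS sampling sites."""

    IVC_LOW = "ivc_low"  # lowest point of the inferior vena cava
    LT_ADV = "lt_adv"  # left adrenal vein
    RT_ADV = "rt_adv"  # right adrenal vein
    S_RT_ADV = "s_rt_adv"  # substitute right adrenal vein (IVC above the rt.AdV confluence)


class Phase(str, enum.Enum):
    """Sampling phase relative to the ACTH (cosyntropin) bolus."""

    PRE_ACTH = "pre_acth"
    POST_ACTH = "post_acth"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    TIE = "tie"


class InvalidMeasurementError(ValueError):
    """A hormone value violates its positivity precondition."""


class IncompleteSamplingError(ValueError):
    """A patient lacks measurements for one or more required (site, phase) pairs."""

    def __init__(self, missing: list[tuple[str, str]]):
        self.missing = list(missing)
        pairs = ", ".join(f"({s}, {p})" for s, p in self.missing)
        super().__init__(f"incomplete sampling; missing: {pairs}")


@dataclass(frozen=True)
class Measurement:
    """One cortisol/aldosterone pair at one site and phase for one patient.

    Units are fixed by convention: cortisol in µg/dL, aldosterone in pg/mL.
    """

    patient_id: str
    site: Site
    phase: Phase
    cortisol: float  # µg/dL, > 0
    aldosterone: float  # pg/mL, >= 0

    def __post_init__(self) -> None:
        if not (self.cortisol > 0) or not math.isfinite(self.cortisol):
            raise InvalidMeasurementError(
                f"cortisol must be positive and finite, got {self.cortisol!r} "
                f"({self.patient_id}, {self.site}, {self.phase})"
            )
        if self.aldosterone < 0 or not math.isfinite(self.aldosterone):
            raise InvalidMeasurementError(
                f"aldosterone must be non-negative and finite, got {self.aldosterone!r} "
                f"({self.patient_id}, {self.site}, {self.phase})"
            )


@dataclass(frozen=True)
class IndexSet:
    """All derived indices for one patient at one phase.

    A/C ratios (pg/mL per µg/dL) are treated as unitless scores; every
    index built from them is a ratio of such scores, so units cancel.
    """

    phase: Phase
    si_left: float
    si_right: float
    ac_ivc: float
    ac_left: float
    ac_right: float
    ac_srt: float
    conventional_li: float  # >= 1 by construction
    dominant_side: Side
    modified_li: float  # > 0


def selectivity_index(cortisol_adv: float, cortisol_ivc_low: float) -> float:
    """Selectivity index: adrenal-vein cortisol over lowest-IVC cortisol."""
    if not cortisol_adv > 0:
        raise InvalidMeasurementError(f"cortisol_adv must be > 0, got {cortisol_adv!r}")
    if not cortisol_ivc_low > 0:
        raise InvalidMeasurementError(f"cortisol_ivc_low must be > 0, got {cortisol_ivc_low!r}")
    return cortisol_adv / cortisol_ivc_low


def ac_ratio(aldosterone: float, cortisol: float) -> float:
    """Aldosterone/cortisol ratio at one sampling site."""
    if not cortisol > 0:
        raise InvalidMeasurementError(f"cortisol must be > 0, got {cortisol!r}")
    return aldosterone / cortisol


def conventional_li(ac_left: float, ac_right: float) -> tuple[float, Side]:
    """Conventional lateralized index: (larger A/C)/(smaller A/C).

    Returns the index (>= 1) together with the side of the larger A/C ratio.
    Equal ratios yield (1.0, Side.TIE) — no lateralization.
    """
    if not ac_left > 0:
        raise InvalidMeasurementError(f"ac_left must be > 0, got {ac_left!r}")
    if not ac_right > 0:
        raise InvalidMeasurementError(f"ac_right must be > 0, got {ac_right!r}")
    if ac_left == ac_right:
        return 1.0, Side.TIE
    if ac_left > ac_right:
        return ac_left / ac_right, Side.LEFT
    return ac_right / ac_left, Side.RIGHT


def modified_li(ac_left: float, ac_srt: float) -> float:
    """Modified lateralized index: left adrenal-vein A/C over substitute-right A/C."""
    if not ac_left > 0:
        raise InvalidMeasurementError(f"ac_left must be > 0, got {ac_left!r}")
    if not ac_srt > 0:
        raise InvalidMeasurementError(f"ac_srt must be > 0, got {ac_srt!r}")
    return ac_left / ac_srt


def toy_modified_li(left_units: float, right_units: float) -> float:
    """Dilution-free unit-model modified LI.

    Counting gland secretion in abstract units (a normal gland secretes 1, an
    aldosterone-producing lesion 10), the substitute right-adrenal-vein site
    detects the sum of both glands, so the modified LI reduces to
    ``left/(left + right)``.  The value is always in (0, 1]: 1/11 ≈ 0.1 for a
    right-sided lesion, 10/20 = 0.5 for bilateral lesions, 10/11 ≈ 0.9 for a
    left-sided lesion.
    """
    if not left_units > 0:
        raise InvalidMeasurementError(f"left_units must be > 0, got {left_units!r}")
    if right_units < 0:
        raise InvalidMeasurementError(f"right_units must be >= 0, got {right_units!r}")
    return left_units / (left_units + right_units)


def compute_index_set(
    measurements: Iterable[Measurement], phase: Phase = Phase.POST_ACTH
) -> IndexSet:
    """Aggregate one patient's measurements at the given phase into an IndexSet.

    All four sites must be present for the requested phase.  Indices default
    to the post-ACTH phase: SI >= 5 is a stimulated-sampling criterion.
    """
    phase = Phase(phase)
    by_site: dict[Site, Measurement] = {}
    for m in measurements:
        if m.phase is not phase and Phase(m.phase) is not phase:
            continue
        site = Site(m.site)
        if site in by_site:
            raise InvalidMeasurementError(
                f"duplicate measurement for ({m.patient_id}, {site.value}, {phase.value})"
            )
        by_site[site] = m

    missing = [(s.value, phase.value) for s in Site if s not in by_site]
    if missing:
        raise IncompleteSamplingError(missing)

    ivc = by_site[Site.IVC_LOW]
    lt = by_site[Site.LT_ADV]
    rt = by_site[Site.RT_ADV]
    srt = by_site[Site.S_RT_ADV]

    ac_l = ac_ratio(lt.aldosterone, lt.cortisol)
    ac_r = ac_ratio(rt.aldosterone, rt.cortisol)
    ac_s = ac_ratio(srt.aldosterone, srt.cortisol)
    li, side = conventional_li(ac_l, ac_r)
    return IndexSet(
        phase=phase,
        si_left=selectivity_index(lt.cortisol, ivc.cortisol),
        si_right=selectivity_index(rt.cortisol, ivc.cortisol),
        ac_ivc=ac_ratio(ivc.aldosterone, ivc.cortisol),
        ac_left=ac_l,
        ac_right=ac_r,
        ac_srt=ac_s,
        conventional_li=li,
        dominant_side=side,
        modified_li=modified_li(ac_l, ac_s),
    )
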