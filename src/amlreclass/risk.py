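"""ELN 2017 / 2022 risk assignment restricted to this cohort's genetic space.

The cohort excludes recurrent favorable abnormalities (CBF, NPM1, bZIP
CEBPA) and adverse cytogenetics by eligibility, so only the intermediate
and adverse tiers are reachable.  The 2022 revision added the
myelodysplasia-related genes beyond ASXL1 (and RUNX1) to the adverse tier
and dropped the FLT3-ITD allelic-ratio distinction, so ELN2017-adverse
implies ELN2022-adverse on this genetic space.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

from .genesets import MR_WHO22
from .types import (
    PatientRecord,
    RiskCall,
    RiskGroup,
    RiskSystem,
    VariantCall,
    VariantClass,
)

log = logging.getLogger(__name__)

ELN2017_ADVERSE_GENES = frozenset({"RUNX1", "ASXL1", "TP53"})
ELN2022_ADVERSE_GENES = frozenset({"TP53"}) | MR_WHO22 | {"RUNX1"}


def _olo(vs: Sequence[VariantCall]) -> List[VariantCall]:
    return [v for v in vs if v.is_olo]


def eln2017(
    p: PatientRecord,
    vs: Sequence[VariantCall],
    flt3_itd_high_ratio: Optional[bool] = None,
) -> RiskCall:
    """ELN 2017: adverse on RUNX1/ASXL1/TP53 mutation, adverse cytogenetics,
    or FLT3-ITD with high allelic ratio without NPM1 (no NPM1 in this cohort)."""
    lesions: List[str] = []
    olo = _olo(vs)
    for g in sorted({v.gene for v in olo if v.gene in ELN2017_ADVERSE_GENES}):
        lesions.append(g)
    has_itd = any(v.variant_class is VariantClass.FLT3_ITD for v in olo)
    if has_itd:
        if flt3_itd_high_ratio is None:
            log.warning(
                "%s: FLT3-ITD present with unknown allelic ratio; treated as not high",
                p.patient_id,
            )
        elif flt3_itd_high_ratio:
            lesions.append("FLT3-ITD(high)")
    if p.has_eln_adverse_cytogenetics:
        lesions.append("adverse_cytogenetics")
    risk = RiskGroup.ADVERSE if lesions else RiskGroup.INTERMEDIATE
    return RiskCall(p.patient_id, RiskSystem.ELN2017, risk, tuple(lesions))


def eln2022(p: PatientRecord, vs: Sequence[VariantCall]) -> RiskCall:
    """ELN 2022: adverse on TP53 or any MR gene (incl. RUNX1); FLT3-ITD alone
    is intermediate (allelic ratio dropped from the recommendations)."""
    olo = _olo(vs)
    lesions = sorted({v.gene for v in olo if v.gene in ELN2022_ADVERSE_GENES})
    if p.has_eln_adverse_cytogenetics:
        lesions.append("adverse_cytogenetics")
    risk = RiskGroup.ADVERSE if lesions else RiskGroup.INTERMEDIATE
    return RiskCall(p.patient_id, RiskSystem.ELN2022, risk, tuple(lesions))
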