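"""WHO17 / WHO22 / ICC22 diagnostic rule engines and reclassification flows.

The three engines cover the diagnostic space of a cytogenetically
intermediate-risk cohort without recurrent WHO17 abnormalities:

* WHO17: AML-MRC (MDS or MDS/MPN history, MDS-defining cytogenetics, or
  multilineage dysplasia) takes precedence over the provisional
  AML-RUNX1m entity; everything else is AML-NOS.
* WHO22: AML with NUP98 rearrangement, then AML-MR (mutation in one of the
  eight MR genes, MDS-defining cytogenetics, or MDS / MDS-MPN history),
  else AML defined by differentiation (AML-DD).  MLD is no longer a
  criterion and RUNX1 is not an MR gene.
* ICC22: NUP98 rearrangement, then AML with mutated TP53 (O/LO at
  VAF >= 0.10), then AML-MR (eight MR genes *plus* RUNX1, or MDS-defining
  cytogenetics), else AML-NOS.  Ontogeny (MDS history) is recorded as a
  qualifier but never changes the category.

Only oncogenic / likely-oncogenic variants can trigger a category; VUS
are ignored here regardless of what the caller passes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .genesets import MR_ICC22, MR_WHO22
from .types import (
    Category,
    Criterion,
    Diagnosis,
    PatientRecord,
    System,
    VariantCall,
    VariantClass,
)

TP53_VAF_CUTOFF = 0.10


class EligibilityError(ValueError):
    """Patient violates cohort eligibility (e.g. therapy-related AML)."""


def _check_eligibility(p: PatientRecord) -> None:
    if p.prior_cytotoxic_therapy:
        raise EligibilityError(
            f"{p.patient_id}: therapy-related AML is excluded from this cohort"
        )


def _olo(vs: Sequence[VariantCall]) -> List[VariantCall]:
    return [v for v in vs if v.is_olo]


def _has_nup98_rearrangement(vs: Sequence[VariantCall]) -> bool:
    return any(
        v.variant_class is VariantClass.FUSION
        and ("NUP98" in (v.gene, v.fusion_partner))
        for v in _olo(vs)
    )


def _genes_hit(vs: Sequence[VariantCall], genes: Iterable[str]) -> frozenset:
    gs = frozenset(genes)
    return frozenset(v.gene for v in _olo(vs) if v.gene in gs)


def classify_who17(p: PatientRecord, vs: Sequence[VariantCall]) -> Diagnosis:
    """WHO 2017: AML-MRC > AML-RUNX1m (provisional) > AML-NOS."""
    _check_eligibility(p)
    criteria: List[Criterion] = []
    if p.mds_history:
        criteria.append(Criterion.MDS_HISTORY)
    if p.mds_mpn_history:
        criteria.append(Criterion.MDS_MPN_HISTORY)
    if p.has_mds_defining_cytogenetics:
        criteria.append(Criterion.MR_CYTOGENETICS)
    if p.has_mld:
        criteria.append(Criterion.MLD)
    if criteria:
        return Diagnosis(p.patient_id, System.WHO17, Category.AML_MRC, tuple(criteria))
    runx1 = _genes_hit(vs, {"RUNX1"})
    if runx1:
        return Diagnosis(
            p.patient_id, System.WHO17, Category.AML_RUNX1M,
            (Criterion.RUNX1_MUTATION,), runx1,
        )
    return Diagnosis(p.patient_id, System.WHO17, Category.AML_NOS)


def classify_who22(p: PatientRecord, vs: Sequence[VariantCall]) -> Diagnosis:
    """WHO 2022: NUP98 > AML-MR (MR genes | cytogenetics | ontogeny) > AML-DD."""
    _check_eligibility(p)
    if _has_nup98_rearrangement(vs):
        return Diagnosis(
            p.patient_id, System.WHO22, Category.AML_NUP98,
            (Criterion.NUP98_REARRANGEMENT,),
        )
    criteria: List[Criterion] = []
    mr_hit = _genes_hit(vs, MR_WHO22)
    if mr_hit:
        criteria.append(Criterion.MR_MUTATION)
    if p.has_mds_defining_cytogenetics:
        criteria.append(Criterion.MR_CYTOGENETICS)
    if p.mds_history:
        criteria.append(Criterion.MDS_HISTORY)
    if p.mds_mpn_history:
        criteria.append(Criterion.MDS_MPN_HISTORY)
    if criteria:
        return Diagnosis(p.patient_id, System.WHO22, Category.AML_MR, tuple(criteria), mr_hit)
    return Diagnosis(p.patient_id, System.WHO22, Category.AML_DD)


def classify_icc22(p: PatientRecord, vs: Sequence[VariantCall]) -> Diagnosis:
    """ICC 2022: NUP98 > TP53 (VAF >= 0.10) > AML-MR (MR genes + RUNX1 |
    cytogenetics) > AML-NOS; ontogeny is a qualifier only."""
    _check_eligibility(p)
    if _has_nup98_rearrangement(vs):
        return Diagnosis(
            p.patient_id, System.ICC22, Category.AML_NUP98,
            (Criterion.NUP98_REARRANGEMENT,),
        )
    if any(
        v.gene == "TP53" and v.vaf is not None and v.vaf >= TP53_VAF_CUTOFF
        for v in _olo(vs)
    ):
        return Diagnosis(
            p.patient_id, System.ICC22, Category.AML_TP53M, (Criterion.TP53_MUTATION,),
        )
    criteria: List[Criterion] = []
    mr_hit = _genes_hit(vs, MR_ICC22)
    if mr_hit:
        criteria.append(Criterion.MR_MUTATION)
        if "RUNX1" in mr_hit:
            criteria.append(Criterion.RUNX1_MUTATION)
    if p.has_mds_defining_cytogenetics:
        criteria.append(Criterion.MR_CYTOGENETICS)
    if criteria:
        # the ontogeny qualifier is recorded but never classifying under ICC22
        if p.mds_history:
            criteria.append(Criterion.MDS_HISTORY)
        if p.mds_mpn_history:
            criteria.append(Criterion.MDS_MPN_HISTORY)
        return Diagnosis(p.patient_id, System.ICC22, Category.AML_MR, tuple(criteria), mr_hit)
    return Diagnosis(p.patient_id, System.ICC22, Category.AML_NOS)


_CLASSIFIERS = {
    System.WHO17: classify_who17,
    System.WHO22: classify_who22,
    System.ICC22: classify_icc22,
}


def variants_by_patient(
    variants: Sequence[VariantCall],
) -> Dict[str, List[VariantCall]]:
    out: Dict[str, List[VariantCall]] = {}
    for v in variants:
        out.setdefault(v.patient_id, []).append(v)
    return out


def classify_cohort(
    patients: Sequence[PatientRecord],
    variants: Sequence[VariantCall],
    system: System,
) -> Dict[str, Diagnosis]:
    """Assign one diagnosis per patient under ``system``."""
    by_pid = variants_by_patient(variants)
    fn = _CLASSIFIERS[System(system)]
    return {p.patient_id: fn(p, by_pid.get(p.patient_id, [])) for p in patients}


#: categories regarded as "the same bucket" across systems when counting
#: unchanged patients (AML-MRC corresponds to AML-MR; AML-NOS to AML-DD/NOS)
_BUCKET = {
    Category.AML_MRC: "MR",
    Category.AML_MR: "MR",
    Category.AML_NOS: "NOS",
    Category.AML_DD: "NOS",
    Category.AML_RUNX1M: "RUNX1m",
    Category.AML_NUP98: "NUP98",
    Category.AML_TP53M: "TP53",
}


@dataclass(frozen=True)
class FlowTable:
    """Patient counts flowing between the categories of two systems."""

    from_system: System
    to_system: System
    counts: Mapping[Tuple[Category, Category], int]
    n_total: int
    n_unchanged: int

    def get(self, from_cat: Category, to_cat: Category) -> int:
        return self.counts.get((Category(from_cat), Category(to_cat)), 0)


def reclassification_flow(
    patients: Sequence[PatientRecord],
    variants: Sequence[VariantCall],
    from_system: System,
    to_system: System,
) -> FlowTable:
    src = classify_cohort(patients, variants, from_system)
    dst = classify_cohort(patients, variants, to_system)
    counts: Counter = Counter()
    unchanged = 0
    for p in patients:
        a, b = src[p.patient_id].category, dst[p.patient_id].category
        counts[(a, b)] += 1
        if _BUCKET[a] == _BUCKET[b]:
            unchanged += 1
    return FlowTable(
        from_system=System(from_system),
        to_system=System(to_system),
        counts=dict(counts),
        n_total=len(patients),
        n_unchanged=unchanged,
    )


@dataclass(frozen=True)
class DisparityReport:
    fraction: float
    discordant: Tuple[Tuple[str, str], ...]  # (patient_id, reason)


def disparity_rate(
    patients: Sequence[PatientRecord], variants: Sequence[VariantCall]
) -> DisparityReport:
    """WHO22-vs-ICC22 discordance under the DD<->NOS correspondence.

    Reasons: ``RUNX1_only`` (ICC22 MR via RUNX1, WHO22 DD), ``ontogeny_only``
    (WHO22 MR via history alone, ICC22 NOS), ``TP53_reassignment`` (ICC22
    TP53 entity absent from WHO22).
    """
    who22 = classify_cohort(patients, variants, System.WHO22)
    icc22 = classify_cohort(patients, variants, System.ICC22)
    discordant: List[Tuple[str, str]] = []
    for p in patients:
        a, b = who22[p.patient_id], icc22[p.patient_id]
        if _BUCKET[a.category] == _BUCKET[b.category]:
            continue
        if b.category is Category.AML_TP53M:
            reason = "TP53_reassignment"
        elif b.category is Category.AML_MR and a.category is Category.AML_DD:
            reason = "RUNX1_only"
        elif a.category is Category.AML_MR and b.category is Category.AML_NOS:
            reason = "ontogeny_only"
        else:
            reason = "other"
        discordant.append((p.patient_id, reason))
    n = len(patients)
    return DisparityReport(
        fraction=(len(discordant) / n) if n else 0.0,
        discordant=tuple(discordant),
    )
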