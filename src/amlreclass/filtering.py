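"""Somatic-variant filtering cascade and the clinical (O/LO-only) subset.

Rules, with their boundary semantics fixed deliberately:

* ``impact``         — annotation impact must be MODERATE or HIGH;
* ``min_reads``      — at least 8 reads supporting the altered allele (inclusive);
* ``min_vaf``        — tumor allele fraction strictly > 0.05 (unpaired samples only);
* ``max_popaf``      — population allele frequency <= 0.001 (unpaired samples only);
* ``cadd_extended``  — CADD strictly > 15 for genes on the extended low-frequency
  list; a missing CADD on such a gene fails the rule (conservative) and is logged;
* ``benign_excluded``— benign / likely-benign curation calls are dropped.

Special events (FLT3-ITD/TKD, KMT2A-PTD, fusions) are detected orthogonally
to exome SNV calling, so they bypass the impact and CADD rules but keep the
oncogenicity gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .genesets import GeneSetRegistry
from .types import OLO, Impact, Oncogenicity, SPECIAL_EVENT_CLASSES, VariantCall

log = logging.getLogger(__name__)

RULES = ("impact", "min_reads", "min_vaf", "max_popaf", "cadd_extended", "benign_excluded")


class FilterInputError(ValueError):
    """A rule could not be evaluated for a variant (missing annotation)."""


@dataclass(frozen=True)
class FilterDecision:
    variant: VariantCall
    kept: bool
    failed_rules: Tuple[str, ...]

    def __post_init__(self):
        if self.kept != (not self.failed_rules):
            raise ValueError("kept must hold iff failed_rules is empty")


def filter_variant(v: VariantCall, genes: GeneSetRegistry) -> FilterDecision:
    """Evaluate every rule on one variant; failed_rules lists all violations."""
    special = v.variant_class in SPECIAL_EVENT_CLASSES
    failed: List[str] = []

    if not special and v.impact not in (Impact.MODERATE, Impact.HIGH):
        failed.append("impact")
    if v.alt_reads < 8:
        failed.append("min_reads")
    if not v.paired_normal:
        if v.vaf is None:
            raise FilterInputError(
                f"{v.patient_id}/{v.gene}: unpaired variant without vaf; min_vaf rule "
                "cannot be evaluated"
            )
        if not v.vaf > 0.05:
            failed.append("min_vaf")
        if v.pop_af is None:
            raise FilterInputError(
                f"{v.patient_id}/{v.gene}: unpaired variant without pop_af; max_popaf "
                "rule cannot be evaluated"
            )
        if not v.pop_af <= 0.001:
            failed.append("max_popaf")
    if not special and v.gene in genes.extended_lowfreq:
        if v.cadd is None:
            log.warning(
                "%s/%s: extended-list gene without CADD score; treated as failing "
                "cadd_extended", v.patient_id, v.gene,
            )
            failed.append("cadd_extended")
        elif not v.cadd > 15:
            failed.append("cadd_extended")
    if v.oncogenicity in (Oncogenicity.BENIGN, Oncogenicity.LIKELY_BENIGN):
        failed.append("benign_excluded")

    return FilterDecision(variant=v, kept=not failed, failed_rules=tuple(failed))


def filter_table(
    variants: Sequence[VariantCall], genes: GeneSetRegistry
) -> Tuple[List[VariantCall], List[FilterDecision]]:
    """Batch filter preserving input order; the audit covers every input row."""
    audit: List[FilterDecision] = []
    kept: List[VariantCall] = []
    for v in variants:
        try:
            d = filter_variant(v, genes)
        except FilterInputError:
            raise
        audit.append(d)
        if d.kept:
            kept.append(v)
    return kept, audit


def clinical_subset(variants: Sequence[VariantCall]) -> List[VariantCall]:
    """Oncogenic / likely-oncogenic variants only (clinical decision space)."""
    return [v for v in variants if v.oncogenicity in OLO]
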