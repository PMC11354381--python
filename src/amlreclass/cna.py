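"""CN-LOH / gain / loss annotation and VAF-based zygosity interpretation.

A copy-neutral LOH segment (major 2, minor 0) duplicates one parental
haplotype.  A somatic mutation whose gene lies inside such a segment is
interpreted from its allele fraction:

* VAF > 0.70  — compatible with a homozygous (duplicated) mutation;
* VAF < 0.50  — the mutation most likely arose *after* the CN-LOH event,
  on one of the two identical haplotypes;
* in between  — ambiguous (the published account uses "generally", so the
  band is not forced either way).  Events without a VAF (e.g. KMT2A-PTD)
  are also ambiguous.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence

from .types import CnaEvent, CNASegment, GeneLocus, VariantCall

log = logging.getLogger(__name__)


class Interpretation(str, Enum):
    HOMOZYGOUS_COMPATIBLE = "homozygous_compatible"
    MUTATION_AFTER_CNLOH = "mutation_after_cnloh"
    AMBIGUOUS = "ambiguous"
    NO_ASSOCIATED_MUTATION = "no_associated_mutation"
    COPY_NUMBER_EFFECT = "copy_number_effect"


@dataclass(frozen=True)
class CnaAnnotation:
    segment: CNASegment
    gene: Optional[str] = None
    variant: Optional[VariantCall] = None
    interpretation: Optional[Interpretation] = None

    def __post_init__(self):
        if self.interpretation is Interpretation.NO_ASSOCIATED_MUTATION and self.variant is not None:
            raise ValueError("no_associated_mutation implies no variant")


def classify_segment(s: CNASegment) -> CnaEvent:
    """Event class from allele-specific copy numbers (CN-LOH iff (2,0))."""
    return s.event


def overlap_variants(
    segments: Sequence[CNASegment],
    variants: Sequence[VariantCall],
    loci: Mapping[str, GeneLocus],
) -> List[CnaAnnotation]:
    """Pair segments with same-patient O/LO variants whose gene locus lies
    fully inside the segment.

    CN-LOH segments with no contained mutation are emitted as
    ``no_associated_mutation``; gains/losses containing mutations are
    emitted as ``copy_number_effect``.  Variants whose gene has no locus
    are logged and skipped.
    """
    olo = [v for v in variants if v.is_olo]
    missing = sorted({v.gene for v in olo if v.gene not in loci})
    for g in missing:
        log.warning("gene %s has no packaged locus; its variants are skipped", g)

    out: List[CnaAnnotation] = []
    for s in segments:
        ev = s.event
        if ev is CnaEvent.NEUTRAL:
            continue
        hits = [
            v for v in olo
            if v.patient_id == s.patient_id
            and v.gene in loci
            and loci[v.gene].chrom == s.chrom
            and s.contains(loci[v.gene].start_bp, loci[v.gene].end_bp)
        ]
        if ev is CnaEvent.CN_LOH:
            if hits:
                for v in hits:
                    out.append(CnaAnnotation(segment=s, gene=v.gene, variant=v))
            else:
                out.append(CnaAnnotation(
                    segment=s, interpretation=Interpretation.NO_ASSOCIATED_MUTATION,
                ))
        else:  # GAIN / LOSS
            for v in hits:
                out.append(CnaAnnotation(
                    segment=s, gene=v.gene, variant=v,
                    interpretation=Interpretation.COPY_NUMBER_EFFECT,
                ))
    return out


def interpret_zygosity(a: CnaAnnotation) -> CnaAnnotation:
    """Attach the VAF-based interpretation to a CN-LOH/variant pairing."""
    if a.variant is None or a.segment.event is not CnaEvent.CN_LOH:
        return a
    vaf = a.variant.vaf
    if vaf is None:
        interp = Interpretation.AMBIGUOUS
    elif vaf > 0.70:
        interp = Interpretation.HOMOZYGOUS_COMPATIBLE
    elif vaf < 0.50:
        interp = Interpretation.MUTATION_AFTER_CNLOH
    else:
        interp = Interpretation.AMBIGUOUS
    return replace(a, interpretation=interp)


def annotate(
    segments: Sequence[CNASegment],
    variants: Sequence[VariantCall],
    loci: Mapping[str, GeneLocus],
) -> List[CnaAnnotation]:
    """Full overlap + interpretation pass."""
    return [interpret_zygosity(a) for a in overlap_variants(segments, variants, loci)]


@dataclass(frozen=True)
class CnlohSummary:
    patients_by_event: Mapping[str, int]          # unique patients per event class
    segments_by_chrom: Mapping[str, int]          # CN-LOH segment counts per chromosome
    n_chromosomes_cnloh: int
    interpretations: Mapping[str, int]            # tally over annotated pairings


def cnloh_summary(
    segments: Sequence[CNASegment], annotations: Sequence[CnaAnnotation]
) -> CnlohSummary:
    pat: Dict[str, set] = {}
    chrom_counts: Counter = Counter()
    for s in segments:
        ev = s.event
        pat.setdefault(ev.value, set()).add(s.patient_id)
        if ev is CnaEvent.CN_LOH:
            chrom_counts[s.chrom] += 1
    interp = Counter(
        a.interpretation.value for a in annotations if a.interpretation is not None
    )
    return CnlohSummary(
        patients_by_event={k: len(v) for k, v in sorted(pat.items())},
        segments_by_chrom=dict(sorted(chrom_counts.items())),
        n_chromosomes_cnloh=len(chrom_counts),
        interpretations=dict(sorted(interp.items())),
    )
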