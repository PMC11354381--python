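"""Core domain types for the AML reclassification pipeline.

All records are validated stdlib dataclasses.  Coordinates are 1-based,
fully closed intervals on GRCh38.  Variant allele fractions are stored as
fractions in [0, 1]; the TSV layer accepts percent columns (``vaf_pct``)
and converts on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, List, Optional, Tuple


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


def _enum_parse(enum_cls, value, field_name):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"{field_name}={value!r} is not valid; allowed values: {allowed}"
        ) from None


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "indel"
    FLT3_ITD = "FLT3_ITD"
    FLT3_TKD = "FLT3_TKD"
    KMT2A_PTD = "KMT2A_PTD"
    FUSION = "fusion"


#: variant classes detected orthogonally to exome SNV/indel calling
#: (fragment analysis / PCR) and therefore exempt from impact and CADD rules
SPECIAL_EVENT_CLASSES = frozenset(
    {VariantClass.FLT3_ITD, VariantClass.FLT3_TKD, VariantClass.KMT2A_PTD, VariantClass.FUSION}
)


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class Oncogenicity(str, Enum):
    ONCOGENIC = "ONCOGENIC"
    LIKELY_ONCOGENIC = "LIKELY_ONCOGENIC"
    VUS = "VUS"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"


OLO = frozenset({Oncogenicity.ONCOGENIC, Oncogenicity.LIKELY_ONCOGENIC})


class Sex(str, Enum):
    F = "F"
    M = "M"


class Karyotype(str, Enum):
    NORMAL = "normal"
    ABNORMAL_INTERMEDIATE = "abnormal_intermediate"
    UNKNOWN = "unknown"


class Lineage(str, Enum):
    ERYTHROID = "erythroid"
    GRANULOCYTIC = "granulocytic"
    MEGAKARYOCYTIC = "megakaryocytic"


class CnaEvent(str, Enum):
    CN_LOH = "CN_LOH"
    GAIN = "GAIN"
    LOSS = "LOSS"
    NEUTRAL = "NEUTRAL"


AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant or special event (FLT3-ITD, KMT2A-PTD, fusion)."""

    patient_id: str
    gene: str
    variant_class: VariantClass
    impact: Impact
    alt_reads: int
    vaf: Optional[float]
    oncogenicity: Oncogenicity
    paired_normal: bool
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    fusion_partner: Optional[str] = None
    pop_af: Optional[float] = None
    cadd: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "variant_class",
                           _enum_parse(VariantClass, self.variant_class, "variant_class"))
        object.__setattr__(self, "impact", _enum_parse(Impact, self.impact, "impact"))
        object.__setattr__(self, "oncogenicity",
                           _enum_parse(Oncogenicity, self.oncogenicity, "oncogenicity"))
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf={self.vaf} outside [0, 1] for {self.patient_id}/{self.gene}")
        if self.alt_reads < 0:
            raise ValidationError(f"alt_reads={self.alt_reads} must be >= 0")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValidationError(f"pop_af={self.pop_af} outside [0, 1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"cadd={self.cadd} must be >= 0")
        if (self.fusion_partner is not None) != (self.variant_class is VariantClass.FUSION):
            raise ValidationError(
                "fusion_partner must be set if and only if variant_class is fusion"
            )
        if self.variant_class in (VariantClass.FLT3_ITD, VariantClass.FLT3_TKD) and self.gene != "FLT3":
            raise ValidationError(f"{self.variant_class.value} requires gene=FLT3, got {self.gene}")
        if self.variant_class is VariantClass.KMT2A_PTD and self.gene != "KMT2A":
            raise ValidationError(f"KMT2A_PTD requires gene=KMT2A, got {self.gene}")

    @property
    def is_olo(self) -> bool:
        return self.oncogenicity in OLO


@dataclass(frozen=True)
class CytogeneticFinding:
    """One karyotypic lesion with precomputed classification flags."""

    label: str
    mds_defining: bool = False
    eln_adverse: bool = False


@dataclass(frozen=True)
class PatientRecord:
    """Clinical, cytogenetic and ontogeny attributes of one patient."""

    patient_id: str
    age_years: float
    sex: Sex
    wbc_e9_per_l: float
    bm_blast_pct: float
    pb_blast_pct: float
    karyotype: Karyotype
    cytogenetic_findings: Tuple[CytogeneticFinding, ...] = ()
    mds_history: bool = False
    mds_mpn_history: bool = False
    mld_lineages: FrozenSet[Lineage] = frozenset()
    prior_cytotoxic_therapy: bool = False
    os_months: Optional[float] = None
    os_event: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", _enum_parse(Sex, self.sex, "sex"))
        object.__setattr__(self, "karyotype", _enum_parse(Karyotype, self.karyotype, "karyotype"))
        object.__setattr__(self, "cytogenetic_findings", tuple(self.cytogenetic_findings))
        object.__setattr__(
            self,
            "mld_lineages",
            frozenset(_enum_parse(Lineage, l, "mld_lineages") for l in self.mld_lineages),
        )
        for name in ("bm_blast_pct", "pb_blast_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100] for {self.patient_id}")
        if self.os_months is not None and self.os_months < 0:
            raise ValidationError(f"os_months={self.os_months} must be >= 0")

    @property
    def has_mld(self) -> bool:
        """Multilineage dysplasia: >=50% dysplastic precursors in >=2 lineages."""
        return len(self.mld_lineages) >= 2

    @property
    def has_mds_defining_cytogenetics(self) -> bool:
        return any(f.mds_defining for f in self.cytogenetic_findings)

    @property
    def has_eln_adverse_cytogenetics(self) -> bool:
        return any(f.eln_adverse for f in self.cytogenetic_findings)


@dataclass(frozen=True)
class CNASegment:
    """Allele-specific copy-number interval (autosomes only, GRCh38)."""

    patient_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_major: int
    n_minor: int

    def __post_init__(self):
        if self.chrom not in AUTOSOMES:
            raise ValidationError(
                f"chrom={self.chrom!r} rejected: sex chromosomes are discarded; "
                f"allowed chr1..chr22"
            )
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"segment {self.patient_id} {self.chrom}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )
        if self.n_major < 0 or self.n_minor < 0:
            raise ValidationError("copy numbers must be >= 0")
        if self.n_major < self.n_minor:
            raise ValidationError(
                f"n_major {self.n_major} < n_minor {self.n_minor} for {self.patient_id}"
            )

    @property
    def event(self) -> CnaEvent:
        if self.n_major == 2 and self.n_minor == 0:
            return CnaEvent.CN_LOH
        total = self.n_major + self.n_minor
        if total > 2:
            return CnaEvent.GAIN
        if total < 2:
            return CnaEvent.LOSS
        return CnaEvent.NEUTRAL

    def contains(self, start_bp: int, end_bp: int) -> bool:
        return self.start_bp <= start_bp and end_bp <= self.end_bp


@dataclass(frozen=True)
class GeneLocus:
    """GRCh38 gene interval used to overlap segments with mutated genes."""

    gene: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValidationError(f"locus {self.gene}: start_bp > end_bp")


class System(str, Enum):
    WHO17 = "WHO17"
    WHO22 = "WHO22"
    ICC22 = "ICC22"


class Category(str, Enum):
    AML_MRC = "AML_MRC"
    AML_NOS = "AML_NOS"
    AML_RUNX1M = "AML_RUNX1m"
    AML_MR = "AML_MR"
    AML_DD = "AML_DD"
    AML_NUP98 = "AML_NUP98"
    AML_TP53M = "AML_TP53m"


class Criterion(str, Enum):
    MR_MUTATION = "MR_mutation"
    MR_CYTOGENETICS = "MR_cytogenetics"
    MDS_HISTORY = "MDS_history"
    MDS_MPN_HISTORY = "MDS_MPN_history"
    MLD = "MLD"
    RUNX1_MUTATION = "RUNX1_mutation"
    NUP98_REARRANGEMENT = "NUP98_rearrangement"
    TP53_MUTATION = "TP53_mutation"


_SYSTEM_CATEGORIES = {
    System.WHO17: {Category.AML_MRC, Category.AML_NOS, Category.AML_RUNX1M},
    System.WHO22: {Category.AML_MR, Category.AML_DD, Category.AML_NUP98},
    System.ICC22: {Category.AML_MR, Category.AML_NOS, Category.AML_NUP98, Category.AML_TP53M},
}


@dataclass(frozen=True)
class Diagnosis:
    """Category assigned to one patient by one classification system."""

    patient_id: str
    system: System
    category: Category
    criteria: Tuple[Criterion, ...] = ()
    mr_genes_hit: FrozenSet[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "system", _enum_parse(System, self.system, "system"))
        object.__setattr__(self, "category", _enum_parse(Category, self.category, "category"))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "mr_genes_hit", frozenset(self.mr_genes_hit))
        if self.category not in _SYSTEM_CATEGORIES[self.system]:
            raise ValidationError(
                f"category {self.category.value} not permitted under {self.system.value}"
            )
        if not self.criteria and self.category not in (Category.AML_NOS, Category.AML_DD):
            raise ValidationError(
                f"{self.category.value} requires a non-empty criteria list"
            )


class RiskSystem(str, Enum):
    ELN2017 = "ELN2017"
    ELN2022 = "ELN2022"


class RiskGroup(str, Enum):
    INTERMEDIATE = "intermediate"
    ADVERSE = "adverse"


@dataclass(frozen=True)
class RiskCall:
    """ELN risk assignment restricted to this cohort's genetic space."""

    patient_id: str
    system: RiskSystem
    risk: RiskGroup
    adverse_lesions: Tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "system", _enum_parse(RiskSystem, self.system, "system"))
        object.__setattr__(self, "risk", _enum_parse(RiskGroup, self.risk, "risk"))
        object.__setattr__(self, "adverse_lesions", tuple(self.adverse_lesions))
        if (self.risk is RiskGroup.ADVERSE) != bool(self.adverse_lesions):
            raise ValidationError("risk is adverse iff adverse_lesions is non-empty")
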