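"""Deterministic fixture cohort and seeded stochastic cohort generator.

``fixture_cohort`` rebuilds, patient by patient, a 69-patient cytogenetic
intermediate-risk AML cohort whose printed aggregates are known: WHO17
strata of 27 AML-MRC / 26 AML-NOS / 16 AML-RUNX1m, the myelodysplasia
criteria mix (23 MLD, 11 MDS history — all with MLD, 12 MLD-sole, 4
cytogenetics-only), 26 RUNX1 O/LO carriers, 40 patients with MR-gene
mutations (46 counting RUNX1), 37 with an actionable FLT3/IDH lesion,
three NUP98 rearrangements, one TP53-mutated case, and exactly one patient
without any oncogenic/likely-oncogenic mutation.  Construction is fully
deterministic (no RNG except a fixed-seed generator for survival times)
and self-checks every constraint before returning.

``fixture_table3`` loads the packaged machine-readable CN-LOH table
(20 segments, 19 patients, plus one footnoted homozygous RUNX1 loss).

``random_cohort`` draws an arbitrary-size cohort from per-lesion
prevalences with a mandatory seed, for property-style testing at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as _io
from .genesets import MR_ICC22, MR_WHO22, load_gene_loci
from .types import (
    CNASegment,
    CytogeneticFinding,
    GeneLocus,
    Karyotype,
    Lineage,
    PatientRecord,
    VariantCall,
    VariantClass,
)


class FixtureError(AssertionError):
    """An internal consistency constraint of the fixture was violated."""


# --------------------------------------------------------------------------
# Per-patient recipe.  Gene tokens:
#   "GENE"         O/LO SNV            "GENE?vus"   VUS SNV
#   "GENE?lo"      likely-oncogenic    "GENE@NN"    O/LO with VAF NN percent
#   "FLT3i"/"FLT3t"  FLT3-ITD / FLT3-TKD   "NUP98r"  NUP98 rearrangement
# Strata: A = WHO17 AML-RUNX1m, H = MDS-history MRC (always with MLD),
#         M = MLD-sole MRC, C = cytogenetics-only MRC, N = AML-NOS.
# --------------------------------------------------------------------------

_GM = (Lineage.GRANULOCYTIC, Lineage.MEGAKARYOCYTIC)
_GME = (Lineage.GRANULOCYTIC, Lineage.MEGAKARYOCYTIC, Lineage.ERYTHROID)

_RECIPE: List[Tuple[str, str, Tuple[str, ...]]] = [
    # --- WHO17 AML-RUNX1m (16): 11 with extra MR genes (5 of them with two),
    #     5 RUNX1-only (non-MR passengers allowed)
    ("P01", "A", ("RUNX1", "ASXL1", "EZH2", "FLT3i", "IDH2")),
    ("P02", "A", ("RUNX1", "BCOR", "SRSF2", "FLT3t")),
    ("P03", "A", ("RUNX1", "STAG2", "U2AF1", "IDH2")),
    ("P04", "A", ("RUNX1", "SF3B1", "ZRSR2")),
    ("P05", "A", ("RUNX1", "BCOR", "ASXL1")),
    ("P06", "A", ("RUNX1", "BCOR", "FLT3i")),
    ("P07", "A", ("RUNX1", "SRSF2", "FLT3t")),
    ("P08", "A", ("RUNX1", "SF3B1", "IDH1")),
    ("P09", "A", ("RUNX1", "STAG2")),
    ("P10", "A", ("RUNX1", "ASXL1")),
    ("P11", "A", ("RUNX1", "EZH2")),
    ("P12", "A", ("RUNX1", "DNMT3A", "FLT3i")),
    ("P13", "A", ("RUNX1", "BCORL1", "FLT3t")),
    ("P14", "A", ("RUNX1", "PHF6", "IDH2")),
    ("P15", "A", ("RUNX1",)),
    ("P16", "A", ("RUNX1", "NRAS")),
    # --- MDS-history MRC (11), all with concurrent MLD:
    #     5 RUNX1 + MR (2 with two MR), 4 non-RUNX1 with two MR,
    #     the FLT3-ITD/WT1/RUNX1 case, the TET2/KRAS case
    ("P17", "H", ("RUNX1", "ASXL1", "EZH2", "FLT3i", "IDH1")),
    ("P18", "H", ("RUNX1", "SRSF2", "STAG2", "FLT3t")),
    ("P19", "H", ("RUNX1", "BCOR", "IDH1")),
    ("P20", "H", ("RUNX1", "U2AF1")),
    ("P21", "H", ("RUNX1", "SRSF2")),
    ("P22", "H", ("ASXL1", "SRSF2", "FLT3i")),
    ("P23", "H", ("STAG2", "ZRSR2", "IDH2")),
    ("P24", "H", ("SF3B1", "SRSF2")),
    ("P25", "H", ("ASXL1", "STAG2")),
    ("P26", "H", ("FLT3i", "WT1", "RUNX1")),
    ("P27", "H", ("TET2", "KRAS")),
    # --- MLD-sole MRC (12): 9 MR-mutated (2 also RUNX1, 1 of those with two
    #     MR; 3 of the 7 non-RUNX1 with two MR), 2 FLT3-ITD+WT1,
    #     1 FLT3-ITD+KIT with the NUP98 rearrangement
    ("P28", "M", ("RUNX1", "STAG2", "SRSF2", "FLT3i", "IDH2")),
    ("P29", "M", ("RUNX1", "BCOR")),
    ("P30", "M", ("ASXL1", "EZH2", "FLT3t")),
    ("P31", "M", ("SRSF2", "STAG2", "IDH1")),
    ("P32", "M", ("U2AF1", "ZRSR2")),
    ("P33", "M", ("STAG2", "FLT3i")),
    ("P34", "M", ("SRSF2", "IDH2")),
    ("P35", "M", ("SF3B1",)),
    ("P36", "M", ("ASXL1",)),
    ("P37", "M", ("FLT3i", "WT1")),
    ("P38", "M", ("FLT3i", "WT1")),
    ("P39", "M", ("FLT3i", "KIT", "NUP98r")),
    # --- cytogenetics-only MRC (4): 2 MR-mutated (both with RUNX1, one with
    #     two MR genes), 2 without MR mutations
    ("P40", "C", ("RUNX1", "ASXL1", "SRSF2", "IDH1")),
    ("P41", "C", ("RUNX1", "STAG2")),
    ("P42", "C", ("DNMT3A", "NRAS", "IDH2")),
    ("P43", "C", ("TET2", "PTPN11")),
    # --- AML-NOS (26): 9 MR-mutated non-RUNX1 (2 with two MR genes; 8 of the
    #     9 with a chromatin-modifier hit: ASXL1 x4, ASXL2 x2, BCOR x3,
    #     EZH2 x1, CREBBP x1, KDM6A x1), 2 NUP98, 1 TP53, 14 plain
    ("P44", "N", ("ASXL1", "SRSF2", "FLT3i", "IDH1")),
    ("P45", "N", ("ASXL1", "STAG2", "FLT3t")),
    ("P46", "N", ("ASXL1", "ASXL2", "IDH1")),
    ("P47", "N", ("ASXL1", "CREBBP")),
    ("P48", "N", ("BCOR", "FLT3i")),
    ("P49", "N", ("BCOR", "ASXL2", "IDH2")),
    ("P50", "N", ("BCOR", "KDM6A")),
    ("P51", "N", ("EZH2", "IDH1")),
    ("P52", "N", ("U2AF1",)),
    ("P53", "N", ("NUP98r", "WT1")),
    ("P54", "N", ("NUP98r", "NRAS")),
    ("P55", "N", ("TP53@40",)),
    ("P56", "N", ("RUNX1?vus", "FLT3i", "IDH2")),
    ("P57", "N", ("DNMT3A", "FLT3i")),
    ("P58", "N", ("TET2", "FLT3t")),
    ("P59", "N", ("DNMT3A", "IDH2")),
    ("P60", "N", ("NRAS", "IDH1")),
    ("P61", "N", ("WT1", "IDH1")),
    ("P62", "N", ("DNMT3A", "NRAS")),
    ("P63", "N", ("TET2", "CBL")),
    ("P64", "N", ("WT1", "KRAS")),
    ("P65", "N", ("PTPN11",)),
    ("P66", "N", ("DNMT3A", "WT1")),
    ("P67", "N", ("CELSFR2?vus@3",)),
    ("P68", "N", ("EGFR?lo@35", "KDM6A")),
    ("P69", "N", ("BCORL1?lo@21.6",)),
]

_AGE_BASE = {"A": 58, "H": 62, "M": 60, "C": 59, "N": 56}
_BM_BASE = {"A": 78, "H": 40, "M": 38, "C": 42, "N": 64}
_AGE_CYCLE = (-14, -6, -2, 0, 3, 7, 11, 16)


def _parse_token(pid: str, token: str, idx: int) -> VariantCall:
    onc = "ONCOGENIC" if idx % 2 == 0 else "LIKELY_ONCOGENIC"
    vaf_pct: Optional[float] = None
    if "@" in token:
        token, raw = token.split("@")
        vaf_pct = float(raw)
    if token.endswith("?vus"):
        token, onc = token[:-4], "VUS"
    elif token.endswith("?lo"):
        token, onc = token[:-3], "LIKELY_ONCOGENIC"

    if token == "FLT3i":
        gene, vclass, impact = "FLT3", VariantClass.FLT3_ITD, "HIGH"
    elif token == "FLT3t":
        gene, vclass, impact = "FLT3", VariantClass.FLT3_TKD, "MODERATE"
    elif token == "NUP98r":
        gene, vclass, impact = "NUP98", VariantClass.FUSION, "HIGH"
    else:
        gene = token
        vclass = VariantClass.SNV if idx % 3 else VariantClass.INDEL
        impact = "HIGH" if vclass is VariantClass.INDEL else "MODERATE"

    n = int(pid[1:])
    if vaf_pct is None:
        vaf = round(0.15 + ((n * 7 + idx * 11) % 40) / 100.0, 2)
    else:
        vaf = round(vaf_pct / 100.0, 6)
    return VariantCall(
        patient_id=pid,
        gene=gene,
        hgvs_c=None if vclass is not VariantClass.SNV else f"c.{100 + n * 13 + idx}A>G",
        hgvs_p=None if vclass is not VariantClass.SNV else f"p.Ala{30 + n * 5 + idx}Thr",
        variant_class=vclass,
        fusion_partner="NSD1" if vclass is VariantClass.FUSION else None,
        impact=impact,
        alt_reads=20 + (n * 3 + idx * 5) % 60,
        vaf=vaf,
        pop_af=0.0,
        cadd=float(20 + (n + idx) % 14),
        oncogenicity=onc,
        paired_normal=True,
    )


def _make_patient(pid: str, stratum: str, n_olo: int, rng: np.random.Generator) -> PatientRecord:
    n = int(pid[1:])
    age = float(np.clip(_AGE_BASE[stratum] + _AGE_CYCLE[n % 8], 24, 81))
    sex = "F" if n % 7 in (0, 2, 5) else "M"
    bm = float(np.clip(_BM_BASE[stratum] + _AGE_CYCLE[(n + 3) % 8] * 2, 10, 98))
    pb = float(np.clip(bm - 22 + (n % 9), 0, 100))
    wbc = round(1.0 + (n * 5 % 40) + (n % 3) * 0.4, 1)

    mld: Tuple[Lineage, ...] = ()
    history = False
    findings: Tuple[CytogeneticFinding, ...] = ()
    karyotype = Karyotype.NORMAL
    if stratum == "H":
        history = True
        mld = _GME if n % 2 else _GM
    elif stratum == "M":
        mld = _GME if pid == "P38" else _GM
    elif stratum == "C":
        findings = (CytogeneticFinding("del(11q)", mds_defining=True, eln_adverse=False),)
        karyotype = Karyotype.ABNORMAL_INTERMEDIATE
    if pid == "P16":
        findings = (CytogeneticFinding("+13", mds_defining=False, eln_adverse=False),)
        karyotype = Karyotype.ABNORMAL_INTERMEDIATE
    if pid == "P26":
        age, sex = 41.0, "F"

    # survival: exponential with hazard increasing in O/LO burden, fixed seed
    rate = 0.010 * (1.0 + 0.45 * n_olo)
    t = float(rng.exponential(1.0 / rate))
    os_months = round(min(t, 72.0), 1)
    os_event = t <= 72.0

    return PatientRecord(
        patient_id=pid,
        age_years=age,
        sex=sex,
        wbc_e9_per_l=wbc,
        bm_blast_pct=bm,
        pb_blast_pct=pb,
        karyotype=karyotype,
        cytogenetic_findings=findings,
        mds_history=history,
        mds_mpn_history=False,
        mld_lineages=frozenset(mld),
        prior_cytotoxic_therapy=False,
        os_months=os_months,
        os_event=os_event,
    )


def fixture_cohort() -> Tuple[List[PatientRecord], List[VariantCall]]:
    """The deterministic 69-patient cohort; self-checked before returning."""
    rng = np.random.default_rng(20240808)
    patients: List[PatientRecord] = []
    variants: List[VariantCall] = []
    for pid, stratum, tokens in _RECIPE:
        vs = [_parse_token(pid, tok, i) for i, tok in enumerate(tokens)]
        patients.append(_make_patient(pid, stratum, sum(v.is_olo for v in vs), rng))
        variants.extend(vs)
    _validate_fixture(patients, variants)
    return patients, variants


def _validate_fixture(patients: Sequence[PatientRecord], variants: Sequence[VariantCall]) -> None:
    from .classify import System, classify_cohort  # deferred: avoid import cycle
    from .types import Category

    def fail(constraint: str, detail: str) -> None:
        raise FixtureError(f"fixture constraint {constraint} violated: {detail}")

    by_pid: Dict[str, List[VariantCall]] = {}
    for v in variants:
        by_pid.setdefault(v.patient_id, []).append(v)
    olo = {p.patient_id: [v for v in by_pid.get(p.patient_id, []) if v.is_olo] for p in patients}

    # (a) WHO17 strata and criteria mix
    who17 = classify_cohort(patients, variants, System.WHO17)
    tot = {c: sum(1 for d in who17.values() if d.category is c) for c in Category}
    if (tot[Category.AML_MRC], tot[Category.AML_NOS], tot[Category.AML_RUNX1M]) != (27, 26, 16):
        fail("(a)", f"WHO17 strata {tot}")
    hist = [p for p in patients if p.mds_history]
    if len(hist) != 11 or not all(p.has_mld for p in hist):
        fail("(a)", "11 MDS-history patients, all with MLD, expected")
    mld_sole = [
        p for p in patients
        if p.has_mld and not p.mds_history and not p.has_mds_defining_cytogenetics
    ]
    if len(mld_sole) != 12:
        fail("(a)", f"{len(mld_sole)} MLD-sole patients, expected 12")
    cyt = [p for p in patients if p.has_mds_defining_cytogenetics]
    if len(cyt) != 4 or any(p.has_mld or p.mds_history for p in cyt):
        fail("(a)", "4 cytogenetics patients without any other criterion expected")
    if sum(1 for p in patients if p.has_mld) != 23:
        fail("(a)", "23 MLD patients expected")

    # (b) RUNX1 carriers
    runx1 = {pid for pid, vs in olo.items() if any(v.gene == "RUNX1" for v in vs)}
    if len(runx1) != 26:
        fail("(b)", f"{len(runx1)} RUNX1 O/LO carriers, expected 26")
    in_runx1m = {pid for pid in runx1 if who17[pid].category is Category.AML_RUNX1M}
    in_mrc = {pid for pid in runx1 if who17[pid].category is Category.AML_MRC}
    if len(in_runx1m) != 16 or len(in_mrc) != 10:
        fail("(b)", f"RUNX1 carriers split {len(in_runx1m)}/{len(in_mrc)}, expected 16/10")
    pmap = {p.patient_id: p for p in patients}
    mrc_mld = sum(1 for pid in in_mrc if pmap[pid].has_mld)
    mrc_hist = sum(1 for pid in in_mrc if pmap[pid].mds_history)
    mrc_cyt = sum(1 for pid in in_mrc if pmap[pid].has_mds_defining_cytogenetics)
    if (mrc_mld, mrc_hist, mrc_cyt) != (8, 6, 2):
        fail("(b)", f"MRC RUNX1 criteria split {(mrc_mld, mrc_hist, mrc_cyt)}, expected (8, 6, 2)")
    vus_runx1 = [
        pid for pid, vs in by_pid.items()
        if sum(1 for v in vs if v.gene == "RUNX1") == 1
        and all(not v.is_olo for v in vs if v.gene == "RUNX1")
        and any(v.gene == "RUNX1" for v in vs)
    ]
    if len(vus_runx1) != 1:
        fail("(b)", f"expected exactly one single-RUNX1-VUS patient, got {vus_runx1}")

    # (c) MR mutation aggregates
    mr = {pid for pid, vs in olo.items() if any(v.gene in MR_WHO22 for v in vs)}
    mr_multi = {pid for pid, vs in olo.items()
                if sum(1 for v in vs if v.gene in MR_WHO22) >= 2}
    mrr = {pid for pid, vs in olo.items() if any(v.gene in MR_ICC22 for v in vs)}
    mrr_multi = {pid for pid, vs in olo.items()
                 if sum(1 for v in vs if v.gene in MR_ICC22) >= 2}
    if (len(mr), len(mr_multi), len(mrr), len(mrr_multi)) != (40, 18, 46, 29):
        fail("(c)", f"MR aggregates {(len(mr), len(mr_multi), len(mrr), len(mrr_multi))}, "
                    "expected (40, 18, 46, 29)")

    # (d) actionable lesions
    itd = {pid for pid, vs in olo.items()
           if any(v.variant_class is VariantClass.FLT3_ITD for v in vs)}
    tkd = {pid for pid, vs in olo.items()
           if any(v.variant_class is VariantClass.FLT3_TKD for v in vs)}
    idh = {pid for pid, vs in olo.items() if any(v.gene in ("IDH1", "IDH2") for v in vs)}
    both = (itd | tkd) & idh
    union = itd | tkd | idh
    if (len(itd), len(tkd), len(idh), len(both), len(union)) != (15, 7, 20, 5, 37):
        fail("(d)", f"actionable {(len(itd), len(tkd), len(idh), len(both), len(union))}, "
                    "expected (15, 7, 20, 5, 37)")

    # (e) variant floor
    if any(not by_pid.get(p.patient_id) for p in patients):
        fail("(e)", "every patient must have at least one variant")
    zero_olo = [p.patient_id for p in patients if not olo[p.patient_id]]
    if len(zero_olo) != 1:
        fail("(e)", f"exactly one patient without O/LO variants expected, got {zero_olo}")

    # (f) karyotype structure
    runx1m_normal = sum(
        1 for p in patients
        if who17[p.patient_id].category is Category.AML_RUNX1M
        and p.karyotype is Karyotype.NORMAL
    )
    if runx1m_normal != 15:
        fail("(f)", f"{runx1m_normal}/16 AML-RUNX1m with normal karyotype, expected 15")
    if any(p.has_eln_adverse_cytogenetics for p in patients):
        fail("(f)", "no ELN-adverse cytogenetics allowed in the cohort")


def fixture_table3() -> Tuple[List[CNASegment], List[VariantCall], Dict[str, GeneLocus]]:
    """Packaged machine-readable CN-LOH table with its associated mutations."""
    data = resources.files("amlreclass.data")
    with resources.as_file(data.joinpath("table3_segments.tsv")) as p:
        segments = _io.read_segments(p)
    with resources.as_file(data.joinpath("table3_variants.tsv")) as p:
        variants = _io.read_variants(p)
    return segments, variants, load_gene_loci()


# ------------------------------------------------------------- simulation

@dataclass(frozen=True)
class SimulationParams:
    """Prevalences for the stochastic cohort generator (all in [0, 1])."""

    n_patients: int = 69
    seed: int = 0
    mr_gene_prev: Dict[str, float] = field(default_factory=lambda: {
        "ASXL1": 0.15, "BCOR": 0.10, "EZH2": 0.06, "SF3B1": 0.07,
        "SRSF2": 0.15, "STAG2": 0.12, "U2AF1": 0.06, "ZRSR2": 0.04,
    })
    p_runx1: float = 0.38
    p_tp53: float = 0.015
    p_nup98: float = 0.045
    p_flt3_itd: float = 0.22
    p_flt3_tkd: float = 0.10
    p_idh: float = 0.29
    p_mld: float = 0.33
    p_mds_history: float = 0.16
    p_mds_cytogenetics: float = 0.06
    passenger_mean: float = 1.5

    def __post_init__(self):
        probs = [*self.mr_gene_prev.values(), self.p_runx1, self.p_tp53, self.p_nup98,
                 self.p_flt3_itd, self.p_flt3_tkd, self.p_idh, self.p_mld,
                 self.p_mds_history, self.p_mds_cytogenetics]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all prevalences must lie in [0, 1]")
        if self.passenger_mean < 0:
            raise ValueError("passenger_mean must be >= 0")


_PASSENGERS = ("DNMT3A", "TET2", "NRAS", "KRAS", "WT1", "PTPN11", "CBL", "PHF6", "SETBP1")


def random_cohort(params: SimulationParams) -> Tuple[List[PatientRecord], List[VariantCall]]:
    """Seeded stochastic cohort with the configured marginal prevalences."""
    rng = np.random.default_rng(params.seed)
    patients: List[PatientRecord] = []
    variants: List[VariantCall] = []
    for i in range(params.n_patients):
        pid = f"S{i + 1:04d}"
        tokens: List[str] = []
        for gene, prev in params.mr_gene_prev.items():
            if rng.random() < prev:
                tokens.append(gene)
        if rng.random() < params.p_runx1:
            tokens.append("RUNX1")
        if rng.random() < params.p_tp53:
            tokens.append("TP53@40")
        if rng.random() < params.p_nup98:
            tokens.append("NUP98r")
        if rng.random() < params.p_flt3_itd:
            tokens.append("FLT3i")
        if rng.random() < params.p_flt3_tkd:
            tokens.append("FLT3t")
        if rng.random() < params.p_idh:
            tokens.append("IDH1" if rng.random() < 0.5 else "IDH2")
        for _ in range(rng.poisson(params.passenger_mean)):
            tokens.append(_PASSENGERS[int(rng.integers(len(_PASSENGERS)))])
        vs = [_parse_token(pid, tok, j) for j, tok in enumerate(dict.fromkeys(tokens))]
        variants.extend(vs)

        mld = _GM if rng.random() < params.p_mld else ()
        history = rng.random() < params.p_mds_history
        if history:
            mld = _GM  # mirror the cohort: MDS history always with MLD
        cyt: Tuple[CytogeneticFinding, ...] = ()
        karyotype = Karyotype.NORMAL
        if rng.random() < params.p_mds_cytogenetics:
            cyt = (CytogeneticFinding("del(11q)", mds_defining=True),)
            karyotype = Karyotype.ABNORMAL_INTERMEDIATE
        n_olo = sum(v.is_olo for v in vs)
        rate = 0.010 * (1.0 + 0.45 * n_olo)
        t = float(rng.exponential(1.0 / rate))
        patients.append(PatientRecord(
            patient_id=pid,
            age_years=float(np.clip(rng.normal(58, 12), 18, 90)),
            sex="F" if rng.random() < 0.43 else "M",
            wbc_e9_per_l=float(np.round(rng.lognormal(1.8, 1.0), 1)),
            bm_blast_pct=float(np.clip(rng.normal(55, 22), 10, 98)),
            pb_blast_pct=float(np.clip(rng.normal(30, 25), 0, 100)),
            karyotype=karyotype,
            cytogenetic_findings=cyt,
            mds_history=history,
            mld_lineages=frozenset(mld),
            os_months=round(min(t, 72.0), 1),
            os_event=t <= 72.0,
        ))
    return patients, variants
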