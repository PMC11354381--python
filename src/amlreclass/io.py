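"""Readers and writers for the three canonical TSV tables.

Canonical dialect: UTF-8, tab-separated, header row, ``#`` comment lines,
``true``/``false`` booleans, empty string for missing optionals.  VAF may
arrive either as a fraction (column ``vaf``) or as percent (column
``vaf_pct``); the writer always emits fractions.  Writing then re-reading a
table reproduces it byte-identically.

A small VCF ingestion path (cyvcf2) is provided for variant tables whose
annotations travel in INFO fields.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .types import (
    CNASegment,
    CytogeneticFinding,
    Lineage,
    PatientRecord,
    ValidationError,
    VariantCall,
)


class TableFormatError(ValueError):
    """Malformed row or header; the message names the offending line."""


VARIANT_COLUMNS = [
    "patient_id", "gene", "hgvs_c", "hgvs_p", "variant_class", "fusion_partner",
    "impact", "alt_reads", "vaf", "pop_af", "cadd", "oncogenicity", "paired_normal",
]
#: columns that must be present on read; the rest default to missing
VARIANT_REQUIRED = [
    "patient_id", "gene", "variant_class", "impact", "alt_reads", "vaf",
    "oncogenicity", "paired_normal",
]
COHORT_COLUMNS = [
    "patient_id", "age_years", "sex", "wbc_e9_per_l", "bm_blast_pct", "pb_blast_pct",
    "karyotype", "cytogenetic_findings", "mds_history", "mds_mpn_history",
    "mld_lineages", "prior_cytotoxic_therapy", "os_months", "os_event",
]
SEGMENT_COLUMNS = ["patient_id", "chrom", "start_bp", "end_bp", "n_major", "n_minor"]


def _opt_str(s: str) -> Optional[str]:
    return s if s != "" else None


def _opt_float(s: str, name: str, line: int) -> Optional[float]:
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise TableFormatError(f"line {line}: {name}={s!r} is not a number") from None


def _req_float(s: str, name: str, line: int) -> float:
    v = _opt_float(s, name, line)
    if v is None:
        raise TableFormatError(f"line {line}: {name} is required")
    return v


def _req_int(s: str, name: str, line: int) -> int:
    try:
        return int(s)
    except ValueError:
        raise TableFormatError(f"line {line}: {name}={s!r} is not an integer") from None


def _bool(s: str, name: str, line: int) -> bool:
    if s.lower() in ("true", "1"):
        return True
    if s.lower() in ("false", "0"):
        return False
    raise TableFormatError(f"line {line}: {name}={s!r} must be true/false")


def _opt_bool(s: str, name: str, line: int) -> Optional[bool]:
    return None if s == "" else _bool(s, name, line)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return format(v, "g")
    return str(v)


def _iter_rows(path, expected: Sequence[str], vaf_pct_ok: bool = False):
    """Yield (line_number, dict) for each data row; validates the header."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        header: Optional[List[str]] = None
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = row
                cols = set(header)
                need = set(expected)
                if vaf_pct_ok and "vaf" in need and "vaf_pct" in cols:
                    need = (need - {"vaf"}) | {"vaf_pct"}
                missing = need - cols
                if missing:
                    raise TableFormatError(
                        f"{path.name}: header missing columns: {sorted(missing)}"
                    )
                continue
            if len(row) != len(header):
                raise TableFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, dict(zip(header, row))
    if header is None:
        raise TableFormatError(f"{path}: empty file (no header)")


def read_variants(path, dialect: str = "tsv") -> List[VariantCall]:
    """Read a variant table; ``dialect`` is 'tsv' (canonical) or 'vcf'."""
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}; allowed: tsv, vcf")
    out: List[VariantCall] = []
    for lineno, r in _iter_rows(path, VARIANT_REQUIRED, vaf_pct_ok=True):
        if "vaf_pct" in r:
            raw = _opt_float(r["vaf_pct"], "vaf_pct", lineno)
            vaf = None if raw is None else raw / 100.0
        else:
            vaf = _opt_float(r["vaf"], "vaf", lineno)
        try:
            out.append(VariantCall(
                patient_id=r["patient_id"],
                gene=r["gene"],
                hgvs_c=_opt_str(r.get("hgvs_c", "")),
                hgvs_p=_opt_str(r.get("hgvs_p", "")),
                variant_class=r["variant_class"],
                fusion_partner=_opt_str(r["fusion_partner"]) if "fusion_partner" in r else None,
                impact=r["impact"],
                alt_reads=_req_int(r["alt_reads"], "alt_reads", lineno),
                vaf=vaf,
                pop_af=_opt_float(r.get("pop_af", ""), "pop_af", lineno),
                cadd=_opt_float(r.get("cadd", ""), "cadd", lineno),
                oncogenicity=r["oncogenicity"],
                paired_normal=_bool(r["paired_normal"], "paired_normal", lineno),
            ))
        except ValidationError as e:
            raise TableFormatError(f"line {lineno}: {e}") from e
    return out


def _read_variants_vcf(path) -> List[VariantCall]:
    from cyvcf2 import VCF  # optional dependency

    out: List[VariantCall] = []
    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else None
    for rec in vcf:
        info = dict(rec.INFO)
        pid = info.get("PATIENT", sample)
        if pid is None:
            raise TableFormatError(f"{path}: record {rec.CHROM}:{rec.POS} has no PATIENT/sample")
        out.append(VariantCall(
            patient_id=str(pid),
            gene=str(info["GENE"]),
            hgvs_c=info.get("HGVSC"),
            hgvs_p=info.get("HGVSP"),
            variant_class=str(info.get("CLASS", "SNV")),
            fusion_partner=info.get("FUSION_PARTNER"),
            impact=str(info["IMPACT"]),
            alt_reads=int(info.get("ALT_READS", 0)),
            vaf=float(info["VAF"]) if "VAF" in info else None,
            pop_af=float(info["POP_AF"]) if "POP_AF" in info else None,
            cadd=float(info["CADD"]) if "CADD" in info else None,
            oncogenicity=str(info["ONCOGENICITY"]),
            paired_normal=str(info.get("PAIRED", "true")).lower() in ("true", "1"),
        ))
    return out


def write_variants(variants: Sequence[VariantCall], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in variants:
            w.writerow([
                v.patient_id, v.gene, _fmt(v.hgvs_c), _fmt(v.hgvs_p),
                v.variant_class.value, _fmt(v.fusion_partner), v.impact.value,
                v.alt_reads, _fmt(v.vaf), _fmt(v.pop_af), _fmt(v.cadd),
                v.oncogenicity.value, _fmt(v.paired_normal),
            ])


def _parse_findings(s: str, lineno: int):
    if not s:
        return ()
    out = []
    for item in s.split(";"):
        parts = item.split("|")
        if len(parts) != 3:
            raise TableFormatError(
                f"line {lineno}: cytogenetic finding {item!r} must be label|mds_defining|eln_adverse"
            )
        out.append(CytogeneticFinding(
            label=parts[0],
            mds_defining=_bool(parts[1], "mds_defining", lineno),
            eln_adverse=_bool(parts[2], "eln_adverse", lineno),
        ))
    return tuple(out)


def read_cohort(path) -> List[PatientRecord]:
    out: List[PatientRecord] = []
    for lineno, r in _iter_rows(path, COHORT_COLUMNS):
        try:
            out.append(PatientRecord(
                patient_id=r["patient_id"],
                age_years=_req_float(r["age_years"], "age_years", lineno),
                sex=r["sex"],
                wbc_e9_per_l=_req_float(r["wbc_e9_per_l"], "wbc_e9_per_l", lineno),
                bm_blast_pct=_req_float(r["bm_blast_pct"], "bm_blast_pct", lineno),
                pb_blast_pct=_req_float(r["pb_blast_pct"], "pb_blast_pct", lineno),
                karyotype=r["karyotype"],
                cytogenetic_findings=_parse_findings(r["cytogenetic_findings"], lineno),
                mds_history=_bool(r["mds_history"], "mds_history", lineno),
                mds_mpn_history=_bool(r["mds_mpn_history"], "mds_mpn_history", lineno),
                mld_lineages=frozenset(
                    Lineage(x) for x in r["mld_lineages"].split(";") if x
                ),
                prior_cytotoxic_therapy=_bool(
                    r["prior_cytotoxic_therapy"], "prior_cytotoxic_therapy", lineno
                ),
                os_months=_opt_float(r["os_months"], "os_months", lineno),
                os_event=_opt_bool(r["os_event"], "os_event", lineno),
            ))
        except (ValidationError, ValueError) as e:
            if isinstance(e, TableFormatError):
                raise
            raise TableFormatError(f"line {lineno}: {e}") from e
    return out


def write_cohort(patients: Sequence[PatientRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COHORT_COLUMNS)
        for p in patients:
            findings = ";".join(
                f"{f.label}|{_fmt(f.mds_defining)}|{_fmt(f.eln_adverse)}"
                for f in p.cytogenetic_findings
            )
            lineages = ";".join(sorted(l.value for l in p.mld_lineages))
            w.writerow([
                p.patient_id, _fmt(p.age_years), p.sex.value, _fmt(p.wbc_e9_per_l),
                _fmt(p.bm_blast_pct), _fmt(p.pb_blast_pct), p.karyotype.value,
                findings, _fmt(p.mds_history), _fmt(p.mds_mpn_history), lineages,
                _fmt(p.prior_cytotoxic_therapy), _fmt(p.os_months), _fmt(p.os_event),
            ])


def read_segments(path) -> List[CNASegment]:
    out: List[CNASegment] = []
    for lineno, r in _iter_rows(path, SEGMENT_COLUMNS):
        try:
            out.append(CNASegment(
                patient_id=r["patient_id"],
                chrom=r["chrom"],
                start_bp=_req_int(r["start_bp"], "start_bp", lineno),
                end_bp=_req_int(r["end_bp"], "end_bp", lineno),
                n_major=_req_int(r["n_major"], "n_major", lineno),
                n_minor=_req_int(r["n_minor"], "n_minor", lineno),
            ))
        except ValidationError as e:
            raise TableFormatError(f"line {lineno}: {e}") from e
    return out


def write_segments(segments: Sequence[CNASegment], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SEGMENT_COLUMNS)
        for s in segments:
            w.writerow([s.patient_id, s.chrom, s.start_bp, s.end_bp, s.n_major, s.n_minor])
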