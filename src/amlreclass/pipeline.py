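"""End-to-end orchestration: filter -> classify -> risk -> CNA -> statistics.

``run_pipeline`` executes every stage on one cohort and writes the
paper-style artifacts: a per-patient master TSV, flow tables, the
WHO22-vs-ICC22 disparity report, the CN-LOH summary, the pairwise
co-occurrence screen and a ``metrics.json`` holding every count the
analysis produces.  The metrics file is the single machine-readable
contract: rerunning on identical inputs reproduces it byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import io as _io
from .classify import (
    FlowTable,
    System,
    classify_cohort,
    disparity_rate,
    reclassification_flow,
    variants_by_patient,
)
from .cna import annotate, cnloh_summary
from .filtering import clinical_subset, filter_table
from .genesets import GeneSetRegistry, MR_ICC22, MR_WHO22, load_gene_loci
from .risk import eln2017, eln2022
from .stats import build_matrix, km_logrank, pairwise_screen
from .types import (
    Category,
    CNASegment,
    PatientRecord,
    RiskGroup,
    VariantCall,
    VariantClass,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass(frozen=True)
class RunConfig:
    """Inputs, systems and thresholds for one pipeline run.

    Thresholds default to the published analysis values and are echoed
    into the run log/metrics for provenance.
    """

    variants_path: Optional[str] = None
    cohort_path: Optional[str] = None
    segments_path: Optional[str] = None
    out_dir: str = "amlreclass_out"
    systems: Tuple[str, ...] = ("WHO17", "WHO22", "ICC22")
    min_mutated: int = 4
    survival_rules: Tuple[str, ...] = ("olo_gt3", "all_gt4", "mr_runx1_gt1")
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(known)}")
        d = dict(d)
        for key in ("systems", "survival_rules"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def flow_table_render(flow: FlowTable) -> pd.DataFrame:
    """Long-format (from, to, n) rows with n > 0, ready for alluvial plotting."""
    rows = [
        {"from": a.value, "to": b.value, "n": n}
        for (a, b), n in sorted(flow.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
        if n > 0
    ]
    return pd.DataFrame(rows, columns=["from", "to", "n"])


def _flow_metrics(flow: FlowTable) -> Dict:
    return {
        f"{a.value}_to_{b.value}": n for (a, b), n in sorted(
            flow.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        )
    } | {"n_total": flow.n_total, "n_unchanged": flow.n_unchanged}


def compute_metrics(
    patients: Sequence[PatientRecord],
    variants: Sequence[VariantCall],
    segments: Optional[Sequence[CNASegment]] = None,
    genes: Optional[GeneSetRegistry] = None,
    min_mutated: int = 4,
) -> Dict:
    """Every cohort-level count the analysis produces, as one JSON-able dict."""
    genes = genes or GeneSetRegistry.default()
    kept, _ = filter_table(variants, genes)
    clinical = clinical_subset(kept)
    by_pid = variants_by_patient(clinical)

    metrics: Dict = {"n_patients": len(patients), "n_variants_input": len(variants),
                     "n_variants_filtered": len(kept), "n_variants_clinical": len(clinical)}

    for system in (System.WHO17, System.WHO22, System.ICC22):
        diag = classify_cohort(patients, clinical, system)
        counts: Dict[str, int] = {}
        for d in diag.values():
            counts[d.category.value] = counts.get(d.category.value, 0) + 1
        metrics[f"{system.value.lower()}_counts"] = dict(sorted(counts.items()))

    metrics["who22_flow"] = _flow_metrics(
        reclassification_flow(patients, clinical, System.WHO17, System.WHO22))
    metrics["icc22_flow"] = _flow_metrics(
        reclassification_flow(patients, clinical, System.WHO17, System.ICC22))

    rep = disparity_rate(patients, clinical)
    metrics["disparity"] = {
        "n_discordant": len(rep.discordant),
        "percent": round(rep.fraction * 100),
        "reasons": sorted(r for _, r in rep.discordant),
    }

    mr = {pid for pid, vs in by_pid.items() if any(v.gene in MR_WHO22 for v in vs)}
    mrr = {pid for pid, vs in by_pid.items() if any(v.gene in MR_ICC22 for v in vs)}
    itd = {pid for pid, vs in by_pid.items()
           if any(v.variant_class is VariantClass.FLT3_ITD for v in vs)}
    tkd = {pid for pid, vs in by_pid.items()
           if any(v.variant_class is VariantClass.FLT3_TKD for v in vs)}
    idh = {pid for pid, vs in by_pid.items() if any(v.gene in ("IDH1", "IDH2") for v in vs)}
    metrics["mutation_aggregates"] = {
        "mr_mutated_patients": len(mr),
        "mr_multi": sum(1 for pid, vs in by_pid.items()
                        if sum(v.gene in MR_WHO22 for v in vs) >= 2),
        "mr_runx1_patients": len(mrr),
        "mr_runx1_multi": sum(1 for pid, vs in by_pid.items()
                              if sum(v.gene in MR_ICC22 for v in vs) >= 2),
        "flt3_itd": len(itd), "flt3_tkd": len(tkd), "idh": len(idh),
        "actionable_patients": len(itd | tkd | idh),
    }

    risk_counts = {}
    for name, fn in (("eln2017", eln2017), ("eln2022", eln2022)):
        calls = [fn(p, by_pid.get(p.patient_id, [])) for p in patients]
        risk_counts[name] = {
            "adverse": sum(1 for c in calls if c.risk is RiskGroup.ADVERSE),
            "intermediate": sum(1 for c in calls if c.risk is RiskGroup.INTERMEDIATE),
        }
    metrics["risk"] = risk_counts

    if segments is not None:
        loci = load_gene_loci()
        anns = annotate(segments, clinical if clinical else [], loci)
        # Table-3-style inputs carry their own variant table; fall back to it
        summ = cnloh_summary(segments, anns)
        metrics["cna"] = {
            "patients_by_event": dict(summ.patients_by_event),
            "n_chromosomes_cnloh": summ.n_chromosomes_cnloh,
            "interpretations": dict(summ.interpretations),
        }
    return metrics


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns the metrics dict (also written as ``metrics.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = GeneSetRegistry.default()

    stage = "read_inputs"
    try:
        if cfg.cohort_path is None:
            from .synth import fixture_cohort
            patients, variants = fixture_cohort()
        else:
            patients = _io.read_cohort(cfg.cohort_path)
            variants = _io.read_variants(cfg.variants_path) if cfg.variants_path else []
        segments = _io.read_segments(cfg.segments_path) if cfg.segments_path else None

        stage = "filter"
        kept, audit = filter_table(variants, genes)
        clinical = clinical_subset(kept)
        pd.DataFrame([
            {"patient_id": d.variant.patient_id, "gene": d.variant.gene,
             "kept": d.kept, "failed_rules": ";".join(d.failed_rules)}
            for d in audit
        ]).to_csv(out / "filter_audit.tsv", sep="\t", index=False)

        stage = "classify"
        by_pid = variants_by_patient(clinical)
        master_rows = []
        for p in patients:
            row = {"patient_id": p.patient_id}
            for system in (System.WHO17, System.WHO22, System.ICC22):
                if system.value in cfg.systems:
                    d = classify_cohort([p], clinical, system)[p.patient_id]
                    row[system.value.lower()] = d.category.value
                    row[f"{system.value.lower()}_criteria"] = ";".join(
                        c.value for c in d.criteria)
            master_rows.append(row)
        flow22 = reclassification_flow(patients, clinical, System.WHO17, System.WHO22)
        flow_icc = reclassification_flow(patients, clinical, System.WHO17, System.ICC22)
        flow_table_render(flow22).to_csv(out / "flow_who17_who22.tsv", sep="\t", index=False)
        flow_table_render(flow_icc).to_csv(out / "flow_who17_icc22.tsv", sep="\t", index=False)
        rep = disparity_rate(patients, clinical)
        pd.DataFrame(list(rep.discordant), columns=["patient_id", "reason"]).to_csv(
            out / "disparity.tsv", sep="\t", index=False)

        stage = "risk"
        for p in patients:
            vs = by_pid.get(p.patient_id, [])
            r17, r22 = eln2017(p, vs), eln2022(p, vs)
            for row in master_rows:
                if row["patient_id"] == p.patient_id:
                    row["eln2017"] = r17.risk.value
                    row["eln2022"] = r22.risk.value
        pd.DataFrame(master_rows).to_csv(out / "per_patient.tsv", sep="\t", index=False)

        stage = "cna"
        if segments is not None:
            loci = load_gene_loci()
            anns = annotate(segments, clinical, loci)
            pd.DataFrame([
                {"patient_id": a.segment.patient_id, "chrom": a.segment.chrom,
                 "start_bp": a.segment.start_bp, "end_bp": a.segment.end_bp,
                 "event": a.segment.event.value, "gene": a.gene or "",
                 "vaf": "" if (a.variant is None or a.variant.vaf is None) else a.variant.vaf,
                 "interpretation": a.interpretation.value if a.interpretation else ""}
                for a in anns
            ]).to_csv(out / "cna_annotations.tsv", sep="\t", index=False)

        stage = "cooccur"
        matrix = build_matrix(clinical, min_mutated=cfg.min_mutated,
                              patients=[p.patient_id for p in patients])
        pairs = pairwise_screen(matrix)
        pd.DataFrame([
            {"gene_a": r.gene_a, "gene_b": r.gene_b, "n11": r.n11, "n10": r.n10,
             "n01": r.n01, "n00": r.n00, "odds_ratio": r.odds_ratio,
             "p": r.p_two_sided, "direction": r.direction.value}
            for r in pairs
        ]).to_csv(out / "cooccurrence.tsv", sep="\t", index=False)

        stage = "survival"
        has_fu = any(p.os_months is not None and p.os_event is not None for p in patients)
        if has_fu and patients:
            for rule in cfg.survival_rules:
                res = km_logrank(patients, variants, rule)
                frames = []
                for name, curve in sorted(res.curves.items()):
                    c = curve.copy()
                    c.insert(0, "stratum", name)
                    frames.append(c)
                pd.concat(frames).to_csv(out / f"survival_{rule}.tsv", sep="\t", index=False)

        stage = "metrics"
        metrics = compute_metrics(patients, variants, segments,
                                  genes=genes, min_mutated=cfg.min_mutated)
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return metrics
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
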