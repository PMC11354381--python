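"""Controlled gene vocabularies: MR gene sets, panel/extended lists, pathways.

The eight-gene myelodysplasia-related (MR) set is the WHO 2022 criterion;
the ICC 2022 set adds RUNX1.  The 40-gene recurrent panel and the 148-gene
extended low-frequency list ship as editable packaged text files; variants
in extended-list genes additionally require CADD > 15 at the filter stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List

from .types import GeneLocus

MR_WHO22: FrozenSet[str] = frozenset(
    {"ASXL1", "BCOR", "EZH2", "SF3B1", "SRSF2", "STAG2", "U2AF1", "ZRSR2"}
)
MR_ICC22: FrozenSet[str] = MR_WHO22 | {"RUNX1"}

CHROMATIN_MODIFIERS = frozenset(
    {"ASXL1", "ASXL2", "BCOR", "BCORL1", "EZH2", "KMT2A", "CREBBP", "KDM6A", "EP300", "SETD2"}
)
SPLICING = frozenset({"SF3B1", "SRSF2", "U2AF1", "ZRSR2", "U2AF2", "PRPF8", "DDX41"})
COHESIN = frozenset({"STAG2", "STAG1", "RAD21", "SMC1A", "SMC3"})
DNA_METHYLATION = frozenset({"DNMT3A", "TET2", "IDH1", "IDH2"})
SIGNALING = frozenset(
    {"FLT3", "KIT", "KRAS", "NRAS", "PTPN11", "CBL", "JAK2", "NF1", "CSF3R", "BRAF", "EGFR", "MPL"}
)
TRANSCRIPTION_FACTORS = frozenset({"RUNX1", "CEBPA", "GATA2", "ETV6", "IKZF1", "SETBP1"})
TUMOR_SUPPRESSORS = frozenset({"TP53", "WT1", "PHF6", "RB1", "CUX1"})


def _read_gene_list(name: str) -> FrozenSet[str]:
    text = resources.files("amlreclass.data").joinpath(name).read_text(encoding="utf-8")
    genes = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return frozenset(genes)


@dataclass(frozen=True)
class GeneSetRegistry:
    """All gene sets the rule engines and the filter consult."""

    mr_who22: FrozenSet[str] = MR_WHO22
    mr_icc22: FrozenSet[str] = MR_ICC22
    recurrent_panel: FrozenSet[str] = field(default_factory=frozenset)
    extended_lowfreq: FrozenSet[str] = field(default_factory=frozenset)
    chromatin_modifiers: FrozenSet[str] = CHROMATIN_MODIFIERS
    splicing: FrozenSet[str] = SPLICING
    cohesin: FrozenSet[str] = COHESIN
    dna_methylation: FrozenSet[str] = DNA_METHYLATION
    signaling: FrozenSet[str] = SIGNALING
    transcription_factors: FrozenSet[str] = TRANSCRIPTION_FACTORS
    tumor_suppressors: FrozenSet[str] = TUMOR_SUPPRESSORS

    def __post_init__(self):
        if not self.mr_who22 < self.mr_icc22:
            raise ValueError("mr_who22 must be a proper subset of mr_icc22")
        if len(self.mr_icc22 - self.mr_who22) != 1:
            raise ValueError("mr_icc22 must extend mr_who22 by exactly one gene")
        if self.recurrent_panel & self.extended_lowfreq:
            overlap = sorted(self.recurrent_panel & self.extended_lowfreq)
            raise ValueError(f"panel and extended lists must be disjoint; overlap: {overlap}")

    @classmethod
    def default(cls) -> "GeneSetRegistry":
        """Registry with the packaged 40-gene panel and 148-gene extended list."""
        return cls(
            recurrent_panel=_read_gene_list("panel_genes.txt"),
            extended_lowfreq=_read_gene_list("extended_genes.txt"),
        )


def load_gene_loci() -> Dict[str, GeneLocus]:
    """Packaged GRCh38 gene intervals keyed by symbol."""
    text = resources.files("amlreclass.data").joinpath("gene_loci.tsv").read_text(encoding="utf-8")
    loci: Dict[str, GeneLocus] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("gene\t"):
            continue
        gene, chrom, start, end = ln.split("\t")
        loci[gene] = GeneLocus(gene=gene, chrom=chrom, start_bp=int(start), end_bp=int(end))
    return loci
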