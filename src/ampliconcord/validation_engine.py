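"""Rule-based validation of reported alterations into pathogenic calls.

Reported variants are triaged into five classes (Pathogenic, Likely
pathogenic, Uncertain significance, Likely benign, Benign) by a
deterministic cascade driven by a pre-materialised knowledge base, then
combined with gene roles:

* any variant seen at population frequency > 0.1% is a polymorphism
  (Benign), regardless of anything else;
* oncogenes are activated by hotspot missense / in-frame indels; truncating
  or silent changes are not activating;
* tumour suppressors require *bi-allelic* inactivation — a homozygous
  inactivating variant, two distinct heterozygous inactivating variants
  (composite het), one heterozygous inactivating variant plus loss of
  heterozygosity (a co-located deletion call), or a homozygous deletion.

Only Pathogenic / Likely pathogenic variants at allele frequency >= 5%
enter the validated set; every validated alteration carries the ordered
list of rule ids that fired (its evidence trace) and an actionability flag
looked up in the knowledge base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import (
    KnowledgeBase,
    ONCOGENE,
    TUMOUR_SUPPRESSOR,
    VariantRecord,
)
from .cnv_caller import (
    AMPLIFICATION,
    CnvCall,
    HETEROZYGOUS_DELETION,
    HOMOZYGOUS_DELETION,
)

PATHOGENIC = "Pathogenic"
LIKELY_PATHOGENIC = "Likely_pathogenic"
UNCERTAIN = "Uncertain_significance"
LIKELY_BENIGN = "Likely_benign"
BENIGN = "Benign"

PATHOGENICITY_CLASSES = (PATHOGENIC, LIKELY_PATHOGENIC, UNCERTAIN,
                         LIKELY_BENIGN, BENIGN)

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"

PATHOGENIC_VARIANT = "pathogenic_variant"

#: Population frequency above which a variant is a polymorphism.
POLYMORPHISM_FREQ = 0.001
#: Minimum allele frequency for a variant to be considered for validation.
MIN_VALIDATION_AF = 0.05
#: Silent changes within this many bases of an exon edge may alter splicing.
EXON_EDGE_BP = 2

#: Consequences that inactivate a tumour suppressor outright.
TSG_INACTIVATING = frozenset(
    {"nonsense", "frameshift_indel", "splice", "intragenic_large_del_dup"}
)


@dataclass
class ValidatedAlteration:
    """A clinically relevant, gene-level pathogenic alteration."""

    patient_id: str
    sample_id: str
    gene: str
    alteration_class: str  # pathogenic_variant | amplification | homozygous_deletion
    zygosity: str = "NA"
    allele_freq: float | None = None
    pathogenicity_class: str = PATHOGENIC
    actionable: bool = False
    evidence_trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.evidence_trace:
            raise ValueError("validated alteration must carry an evidence trace")


def classify_variant(record: VariantRecord, kb: KnowledgeBase) -> tuple[str, list[str]]:
    """Five-class pathogenicity call with the ordered rule trace."""
    trace: list[str] = []
    role = kb.role(record.gene)
    if kb.population_freq(record) > POLYMORPHISM_FREQ:
        trace.append("POLYMORPHISM_FREQ_GT_0.1PCT")
        return BENIGN, trace
    cons = record.consequence
    if role == ONCOGENE:
        if cons in ("missense", "inframe_indel"):
            source = kb.hotspots.get((record.gene, record.protein_change))
            if source is not None:
                if "in_silico" in source:
                    trace.append("ONCOGENE_HOTSPOT_IN_SILICO")
                    return LIKELY_PATHOGENIC, trace
                trace.append("ONCOGENE_HOTSPOT")
                return PATHOGENIC, trace
            trace.append("ONCOGENE_NON_HOTSPOT")
            return UNCERTAIN, trace
        if cons == "synonymous":
            trace.append("ONCOGENE_SILENT_NOT_ACTIVATING")
            return BENIGN, trace
        if cons in ("nonsense", "frameshift_indel"):
            trace.append("ONCOGENE_TRUNCATING_NOT_ACTIVATING")
            return LIKELY_BENIGN, trace
        # splice / large intragenic events in an oncogene: unclear activation
        trace.append("ONCOGENE_OTHER")
        return UNCERTAIN, trace
    # tumour suppressor
    if cons in TSG_INACTIVATING:
        trace.append(f"TSG_INACTIVATING_{cons.upper()}")
        return PATHOGENIC, trace
    if cons == "missense":
        if (record.gene, record.protein_change) in kb.known_inactivating_missense:
            trace.append("TSG_KNOWN_INACTIVATING_MISSENSE")
            return PATHOGENIC, trace
        trace.append("TSG_UNKNOWN_MISSENSE")
        return UNCERTAIN, trace
    if cons == "synonymous":
        if record.exon_edge_distance <= EXON_EDGE_BP:
            trace.append("TSG_SILENT_NEAR_EXON_EDGE")
            return UNCERTAIN, trace
        trace.append("TSG_SILENT")
        return LIKELY_BENIGN, trace
    trace.append("TSG_OTHER")
    return UNCERTAIN, trace


def apply_af_gate(record: VariantRecord, min_af: float = MIN_VALIDATION_AF) -> bool:
    """Validation allele-frequency gate (inclusive at 5%)."""
    return record.allele_freq >= min_af


def call_zygosity(
    record: VariantRecord,
    tumour_cell_fraction: float,
    cnv_call: CnvCall | None = None,
) -> str:
    """Nearest-expectation zygosity call without a matched normal.

    At tumour-cell fraction *c* a clonal heterozygous variant is expected at
    AF = 0.5c and a homozygous one at AF = c; the observed AF is assigned to
    the nearer expectation.  A co-located heterozygous-deletion call
    upgrades a het-AF variant to homozygous (mutation plus loss of the
    other allele).
    """
    if not 0.0 < tumour_cell_fraction <= 1.0:
        raise ValueError("tumour_cell_fraction must be in (0, 1]")
    het_exp = 0.5 * tumour_cell_fraction
    hom_exp = tumour_cell_fraction
    zyg = (
        HETEROZYGOUS
        if abs(record.allele_freq - het_exp) < abs(record.allele_freq - hom_exp)
        else HOMOZYGOUS
    )
    if (
        zyg == HETEROZYGOUS
        and cnv_call is not None
        and cnv_call.gene == record.gene
        and cnv_call.status == HETEROZYGOUS_DELETION
    ):
        return HOMOZYGOUS
    return zyg


def tsg_inactivation(
    gene: str,
    variants: list[tuple[VariantRecord, str]],
    cnv_calls: list[CnvCall],
) -> tuple[bool, list[str]]:
    """Bi-allelic inactivation check for one tumour suppressor.

    ``variants`` are (record, zygosity) pairs for the gene's *inactivating*
    Pathogenic/Likely-pathogenic variants; ``cnv_calls`` the gene's CNV
    calls.  Returns (validated, trace) where the trace records which
    branch fired: homozygous variant, composite heterozygous, mutation +
    LOH, or homozygous deletion.
    """
    trace: list[str] = []
    gene_cnv = [c for c in cnv_calls if c.gene == gene]
    hom = [v for v, z in variants if z == HOMOZYGOUS]
    het = [(v, z) for v, z in variants if z == HETEROZYGOUS]
    if hom:
        trace.append("TSG_BIALLELIC_HOMOZYGOUS_VARIANT")
        return True, trace
    if len({v.key() for v, _ in het}) >= 2:
        trace.append("TSG_BIALLELIC_COMPOSITE_HET")
        return True, trace
    loh = any(c.status in (HETEROZYGOUS_DELETION, HOMOZYGOUS_DELETION)
              for c in gene_cnv)
    if het and loh:
        trace.append("TSG_BIALLELIC_MUTATION_PLUS_LOH")
        return True, trace
    if any(c.status == HOMOZYGOUS_DELETION for c in gene_cnv):
        trace.append("TSG_BIALLELIC_HOMOZYGOUS_DELETION")
        return True, trace
    return False, trace


def validate_sample(
    variants: list[VariantRecord],
    cnv_calls: list[CnvCall],
    kb: KnowledgeBase,
    tumour_cell_fraction: float,
    patient_id: str = "",
    sample_id: str = "",
    include_likely_pathogenic: bool = True,
) -> list[ValidatedAlteration]:
    """Full validation of one sample's reported variants and CNV calls."""
    accepted = {PATHOGENIC, LIKELY_PATHOGENIC} if include_likely_pathogenic \
        else {PATHOGENIC}
    out: list[ValidatedAlteration] = []
    calls_by_gene: dict[str, list[CnvCall]] = {}
    for c in cnv_calls:
        calls_by_gene.setdefault(c.gene, []).append(c)

    # per-gene grouping of pathogenic variants passing the AF gate
    patho_by_gene: dict[str, list[tuple[VariantRecord, str, str, list[str]]]] = {}
    for rec in variants:
        cls, trace = classify_variant(rec, kb)
        if cls not in accepted:
            continue
        trace = list(trace)
        if not apply_af_gate(rec):
            continue
        trace.append("AF_GATE_GE_5PCT")
        gene_cnv = calls_by_gene.get(rec.gene, [])
        hetdel = next((c for c in gene_cnv
                       if c.status == HETEROZYGOUS_DELETION), None)
        raw_zyg = call_zygosity(rec, tumour_cell_fraction, None)
        zyg = call_zygosity(rec, tumour_cell_fraction, hetdel)
        patho_by_gene.setdefault(rec.gene, []).append((rec, raw_zyg, zyg, trace))
        _ = cls

    for gene, entries in patho_by_gene.items():
        role = kb.role(gene)
        if role == ONCOGENE:
            for rec, _raw, zyg, trace in entries:
                out.append(ValidatedAlteration(
                    patient_id=patient_id, sample_id=sample_id, gene=gene,
                    alteration_class=PATHOGENIC_VARIANT, zygosity=zyg,
                    allele_freq=rec.allele_freq,
                    pathogenicity_class=classify_variant(rec, kb)[0],
                    actionable=kb.is_actionable(gene, PATHOGENIC_VARIANT),
                    evidence_trace=trace + ["ONCOGENE_ACTIVATING_VALIDATED"],
                ))
        else:
            pairs = [(rec, raw) for rec, raw, _zyg, _tr in entries]
            ok, branch = tsg_inactivation(gene, pairs,
                                          calls_by_gene.get(gene, []))
            if ok:
                # report the gene once, carried by its strongest variant
                rec, _raw, zyg, trace = max(
                    entries, key=lambda e: (e[2] == HOMOZYGOUS, e[0].allele_freq))
                out.append(ValidatedAlteration(
                    patient_id=patient_id, sample_id=sample_id, gene=gene,
                    alteration_class=PATHOGENIC_VARIANT, zygosity=zyg,
                    allele_freq=rec.allele_freq,
                    pathogenicity_class=classify_variant(rec, kb)[0],
                    actionable=kb.is_actionable(gene, PATHOGENIC_VARIANT),
                    evidence_trace=trace + branch,
                ))

    for gene, calls in calls_by_gene.items():
        role = kb.role(gene)
        for c in calls:
            if role == ONCOGENE and c.status == AMPLIFICATION:
                out.append(ValidatedAlteration(
                    patient_id=patient_id, sample_id=sample_id, gene=gene,
                    alteration_class=AMPLIFICATION, zygosity="NA",
                    pathogenicity_class=PATHOGENIC,
                    actionable=kb.is_actionable(gene, AMPLIFICATION),
                    evidence_trace=["CNV_AMPLIFICATION_GT_2"],
                ))
            elif role == TUMOUR_SUPPRESSOR and c.status == HOMOZYGOUS_DELETION:
                out.append(ValidatedAlteration(
                    patient_id=patient_id, sample_id=sample_id, gene=gene,
                    alteration_class=HOMOZYGOUS_DELETION, zygosity="NA",
                    pathogenicity_class=PATHOGENIC,
                    actionable=kb.is_actionable(gene, HOMOZYGOUS_DELETION),
                    evidence_trace=["CNV_HOMOZYGOUS_DELETION_LT_MINUS1"],
                ))
    return out
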