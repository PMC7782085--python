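"""End-to-end orchestration: counts -> CNV calls -> variants -> validation
-> paired concordance, for a whole cohort in memory.

This is the glue the CLI and the test-bench run; every step delegates to
the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cnv_caller import (
    CnvCall,
    CnvThresholds,
    GAIN,
    HETEROZYGOUS_DELETION,
    SegmentedProfile,
    gene_level_calls,
    normalize,
    segment_profile,
)
from .concordance import (
    AlterationObservation,
    CohortReport,
    PairedAlteration,
    af_correlation,
    cnv_pair_correlation,
    cohort_summary,
    observation_from_validated,
    pair_and_classify,
)
from .core_io import KnowledgeBase, SampleMeta, TUMOUR_SUPPRESSOR
from .synthetic_cohort import CohortData
from .validation_engine import (
    LIKELY_PATHOGENIC,
    PATHOGENIC,
    PATHOGENIC_VARIANT,
    ValidatedAlteration,
    apply_af_gate,
    classify_variant,
    validate_sample,
)
from .variant_filter import filter_records, panel_consensus

AMPLIFICATION = "amplification"
HOMOZYGOUS_DELETION = "homozygous_deletion"


@dataclass
class SampleResult:
    meta: SampleMeta
    profile_a: SegmentedProfile
    profile_b: SegmentedProfile
    cnv_calls: list[CnvCall]
    variants: list  # consensus VariantRecords
    validated: list[ValidatedAlteration]
    observations: list[AlterationObservation]


@dataclass
class PipelineResult:
    samples: dict[str, SampleResult]
    paired: list[PairedAlteration]
    report: CohortReport
    af_r: float
    cnv_correlations: pd.DataFrame
    qc_cnb: pd.DataFrame = field(default_factory=pd.DataFrame)
    qc_fna: pd.DataFrame = field(default_factory=pd.DataFrame)


def _context_observations(
    sample: "SampleResult",
    kb: KnowledgeBase,
    tcf: float,
) -> list[AlterationObservation]:
    """Non-validated findings that still inform the discordance ledger:
    lone heterozygous TSG pathogenic variants, heterozygous deletions,
    gains."""
    out = []
    validated_keys = {(v.gene, v.alteration_class) for v in sample.validated}
    for rec in sample.variants:
        cls, _ = classify_variant(rec, kb)
        if cls not in (PATHOGENIC, LIKELY_PATHOGENIC) or not apply_af_gate(rec):
            continue
        if kb.role(rec.gene) != TUMOUR_SUPPRESSOR:
            continue
        if (rec.gene, PATHOGENIC_VARIANT) in validated_keys:
            continue
        out.append(AlterationObservation(
            gene=rec.gene, alteration_class=PATHOGENIC_VARIANT,
            status="Heterozygous mutation", validated=False,
            actionable=kb.is_actionable(rec.gene, PATHOGENIC_VARIANT),
            allele_freq=rec.allele_freq,
        ))
    for call in sample.cnv_calls:
        if call.status == HETEROZYGOUS_DELETION and \
                (call.gene, HOMOZYGOUS_DELETION) not in validated_keys:
            out.append(AlterationObservation(
                gene=call.gene, alteration_class=HOMOZYGOUS_DELETION,
                status="Heterozygous deletion", validated=False,
                actionable=kb.is_actionable(call.gene, HOMOZYGOUS_DELETION)))
        elif call.status == GAIN and \
                (call.gene, AMPLIFICATION) not in validated_keys:
            out.append(AlterationObservation(
                gene=call.gene, alteration_class=AMPLIFICATION,
                status="Gain", validated=False,
                actionable=kb.is_actionable(call.gene, AMPLIFICATION)))
    # de-duplicate
    seen = set()
    uniq = []
    for o in out:
        if (o.gene, o.alteration_class) not in seen:
            seen.add((o.gene, o.alteration_class))
            uniq.append(o)
    return uniq


def analyse_sample(
    cohort: CohortData,
    meta: SampleMeta,
    log2: pd.DataFrame,
    thresholds: CnvThresholds,
    penalty: float | None,
    patient_id: str,
) -> SampleResult:
    bc_a, bc_b = meta.barcodes
    prof_a = segment_profile(log2[bc_a], cohort.manifest,
                             penalty=penalty, thresholds=thresholds)
    prof_b = segment_profile(log2[bc_b], cohort.manifest,
                             penalty=penalty, thresholds=thresholds)
    calls = gene_level_calls(prof_a, prof_b, cohort.manifest,
                             panel_consensus=True)
    recs_a = filter_records(cohort.variant_tables[meta.sample_id]["A"])
    recs_b = filter_records(cohort.variant_tables[meta.sample_id]["B"])
    consensus = panel_consensus(recs_a, recs_b)
    validated = validate_sample(
        consensus, calls, cohort.kb, meta.tumour_cell_fraction,
        patient_id=patient_id, sample_id=meta.sample_id)
    result = SampleResult(meta=meta, profile_a=prof_a, profile_b=prof_b,
                          cnv_calls=calls, variants=consensus,
                          validated=validated, observations=[])
    obs = [observation_from_validated(v) for v in validated]
    obs.extend(_context_observations(result, cohort.kb,
                                     meta.tumour_cell_fraction))
    result.observations = obs
    return result


def run_pipeline(
    cohort: CohortData,
    thresholds: CnvThresholds = CnvThresholds(),
    penalty: float | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated (or loaded) cohort."""
    norm = normalize(cohort.counts, cohort.manifest)
    samples: dict[str, SampleResult] = {}
    paired: list[PairedAlteration] = []
    profile_pairs = {}
    qc_rows = {"CNB": [], "FNA": []}
    for pair in cohort.pairs:
        if not pair.eligible:
            continue
        res_cnb = analyse_sample(cohort, pair.cnb, norm.log2, thresholds,
                                 penalty, pair.patient_id)
        res_fna = analyse_sample(cohort, pair.fna, norm.log2, thresholds,
                                 penalty, pair.patient_id)
        samples[pair.cnb.sample_id] = res_cnb
        samples[pair.fna.sample_id] = res_fna
        paired.extend(pair_and_classify(res_cnb.observations,
                                        res_fna.observations,
                                        patient_id=pair.patient_id))
        profile_pairs[pair.patient_id] = (res_cnb.profile_a, res_fna.profile_a)
        qc_rows["CNB"].append(pair.cnb.qc_metrics)
        qc_rows["FNA"].append(pair.fna.qc_metrics)
    patient_ids = [p.patient_id for p in cohort.pairs if p.eligible]
    report = cohort_summary(paired, patient_ids=patient_ids)
    af_pairs = [(p.cnb_af, p.fna_af) for p in paired
                if p.concordant and p.alteration_class == PATHOGENIC_VARIANT
                and p.cnb_af is not None and p.fna_af is not None]
    if len(af_pairs) >= 3:
        af_r = af_correlation([a for a, _ in af_pairs],
                              [b for _, b in af_pairs])
    else:
        af_r = float("nan")
    corr = cnv_pair_correlation(profile_pairs)
    return PipelineResult(
        samples=samples, paired=paired, report=report, af_r=af_r,
        cnv_correlations=corr,
        qc_cnb=pd.DataFrame(qc_rows["CNB"]),
        qc_fna=pd.DataFrame(qc_rows["FNA"]),
    )


def recovery_stats(cohort: CohortData, result: PipelineResult,
                   min_cellularity: float = 0.5) -> dict[str, dict[str, int]]:
    """Planted-driver recovery per event class, over samples at or above
    ``min_cellularity`` (recall denominators) and all samples (false
    positives), matched by (gene, alteration class)."""
    stats = {k: {"tp": 0, "fn": 0, "fp": 0}
             for k in (PATHOGENIC_VARIANT, AMPLIFICATION, HOMOZYGOUS_DELETION)}
    for pair in cohort.pairs:
        truth = cohort.truth.driver_events(pair.patient_id)
        for meta in (pair.cnb, pair.fna):
            res = result.samples.get(meta.sample_id)
            if res is None:
                continue
            found = {(v.gene, v.alteration_class) for v in res.validated}
            if meta.tumour_cell_fraction >= min_cellularity:
                for gene, klass in truth:
                    if (gene, klass) in found:
                        stats[klass]["tp"] += 1
                    else:
                        stats[klass]["fn"] += 1
            for gene, klass in found:
                if (gene, klass) not in truth:
                    stats[klass]["fp"] += 1
    return stats
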