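"""Reporting filters for candidate variants, with dual-panel consensus.

The assay reports a variant when three inclusive conditions hold at a
pileup site over the primer-trimmed target:

    alt reads >= 1,  depth >= 30,  alt/depth >= 1%.

Indels longer than 10 bp are routed to a dedicated intermediate-size indel
strategy (an external detection path; only the routing threshold is modelled
here).  Because each sample is sequenced as two barcodes (panels "A" and
"B") targeting both strands, only variants found by both are considered,
with allele frequency and depth reported from panel "A".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


from .core_io import VariantRecord

logger = logging.getLogger("ampliconcord")

SMALL_INDEL_PATH = "small_indel_path"
INTERMEDIATE_INDEL_PATH = "intermediate_indel_path"

#: Indels strictly longer than this route to the dedicated strategy.
INTERMEDIATE_INDEL_MIN_LEN = 10

MIN_DEPTH = 30
MIN_ALT_READS = 1
MIN_AF = 0.01


@dataclass
class PileupSite:
    """Allele counts at one position of the primer-trimmed target."""

    chrom: str
    pos: int  # 0-based
    ref: str
    depth: int
    allele_counts: dict[str, int] = field(default_factory=dict)
    gene: str = ""
    annotations: dict[str, dict] = field(default_factory=dict)  # alt -> extra fields

    def __post_init__(self) -> None:
        if sum(self.allele_counts.values()) > self.depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: allele counts exceed depth"
            )


def passes_report_filter(depth: int, alt_reads: int,
                         min_depth: int = MIN_DEPTH,
                         min_alt_reads: int = MIN_ALT_READS,
                         min_af: float = MIN_AF) -> bool:
    """The three inclusive reporting conditions."""
    if depth < min_depth or alt_reads < min_alt_reads:
        return False
    return alt_reads / depth >= min_af


def report_variants(
    pileups,
    min_depth: int = MIN_DEPTH,
    min_alt_reads: int = MIN_ALT_READS,
    min_af: float = MIN_AF,
) -> list[VariantRecord]:
    """Emit a :class:`VariantRecord` per non-reference allele passing the
    reporting filter.  Site annotations (consequence, indel length, protein
    change...) are carried through when present; otherwise alleles default
    to SNV missense records, which is sufficient for filter testing.
    """
    out = []
    for site in pileups:
        for alt, n_alt in sorted(site.allele_counts.items()):
            if alt == site.ref:
                continue
            if not passes_report_filter(site.depth, n_alt, min_depth,
                                        min_alt_reads, min_af):
                continue
            extra = site.annotations.get(alt, {})
            out.append(VariantRecord(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=alt,
                gene=extra.get("gene", site.gene),
                depth=site.depth,
                alt_reads=n_alt,
                allele_freq=n_alt / site.depth,
                consequence=extra.get("consequence", "missense"),
                indel_len=extra.get("indel_len", 0),
                exon_edge_distance=extra.get("exon_edge_distance", 100),
                protein_change=extra.get("protein_change", ""),
            ))
    return out


def filter_records(
    records,
    min_depth: int = MIN_DEPTH,
    min_alt_reads: int = MIN_ALT_READS,
    min_af: float = MIN_AF,
) -> list[VariantRecord]:
    """Apply the same reporting filter to pre-built candidate records."""
    return [r for r in records
            if passes_report_filter(r.depth, r.alt_reads, min_depth,
                                    min_alt_reads, min_af)]


def route_indel(record: VariantRecord) -> str:
    """Route an indel to the small or intermediate-size (>10 bp) path."""
    if not record.is_indel:
        raise ValueError(f"{record.key()} is not an indel")
    if record.indel_len > INTERMEDIATE_INDEL_MIN_LEN:
        return INTERMEDIATE_INDEL_PATH
    return SMALL_INDEL_PATH


def panel_consensus(
    records_a: list[VariantRecord],
    records_b: list[VariantRecord],
) -> list[VariantRecord]:
    """Keep variants found by both barcodes, with panel-A values.

    Records are keyed by (chrom, pos, ref, alt); allele frequency and depth
    of the surviving record come from panel A.  A-only records are dropped
    and logged.
    """
    keys_b = {r.key() for r in records_b}
    kept = []
    for r in records_a:
        if r.key() in keys_b:
            kept.append(r)
        else:
            logger.debug("variant %s found in panel A only; dropped", r.key())
    return kept
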