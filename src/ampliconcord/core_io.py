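"""Domain types and readers/writers for the formats the pipeline touches.

All genomic intervals are 0-based half-open internally.  The only places the
convention changes are the converters to/from 1-based text formats (SAM via
pysam, VCF-like variant export).  The panel manifest on disk is a BED-like TSV
(0-based half-open, so no conversion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

logger = logging.getLogger("ampliconcord")

#: Recognised functional consequence labels for variants.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "synonymous",
        "frameshift_indel",
        "inframe_indel",
        "splice",
        "intragenic_large_del_dup",
    }
)

#: Consequence labels that denote an insertion/deletion.
INDEL_CONSEQUENCES = frozenset({"frameshift_indel", "inframe_indel"})

ONCOGENE = "oncogene"
TUMOUR_SUPPRESSOR = "tumour_suppressor"


class ManifestError(ValueError):
    """Raised for malformed or inconsistent panel manifests."""


@dataclass(frozen=True)
class Amplicon:
    """One PCR amplicon of the targeted panel.

    ``start``/``end`` are the genomic endpoints of the amplified fragment
    including primers; the primer lengths delimit the informative insert.
    """

    id: str
    chrom: str
    start: int
    end: int
    fwd_primer_len: int
    rev_primer_len: int
    gene: str
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ManifestError(
                f"amplicon {self.id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.end - self.start <= self.fwd_primer_len + self.rev_primer_len:
            raise ManifestError(
                f"amplicon {self.id}: primers ({self.fwd_primer_len}+"
                f"{self.rev_primer_len}) leave no insert in "
                f"[{self.start},{self.end})"
            )

    @property
    def insert_start(self) -> int:
        return self.start + self.fwd_primer_len

    @property
    def insert_end(self) -> int:
        return self.end - self.rev_primer_len


@dataclass
class PanelManifest:
    """Ordered amplicon intervals: the coordinate backbone of the pipeline.

    Amplicons are kept sorted by (chrom, start); identifiers are unique.
    Blacklisted amplicons stay in the manifest but are excluded from the
    copy-number analysis.
    """

    amplicons: list[Amplicon]
    panel_id: str = "A"
    genome_build: str = "hg19"

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate amplicon id(s): {dupes}")
        key = [(a.chrom, a.start) for a in self.amplicons]
        if key != sorted(key):
            logger.info("panel %s: amplicons were unsorted; sorting", self.panel_id)
            self.amplicons = sorted(self.amplicons, key=lambda a: (a.chrom, a.start))

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.amplicons]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.amplicons:
            seen.setdefault(a.gene, None)
        return list(seen)

    def by_id(self, amplicon_id: str) -> Amplicon:
        index = self.__dict__.get("_id_index")
        if index is None or len(index) != len(self.amplicons):
            index = {a.id: a for a in self.amplicons}
            self.__dict__["_id_index"] = index
        return index[amplicon_id]

    def gene_amplicons(self, gene: str) -> list[Amplicon]:
        out = [a for a in self.amplicons if a.gene == gene]
        if not out:
            raise KeyError(f"gene {gene} not in manifest")
        return out

    def analysable(self) -> "PanelManifest":
        """Manifest restricted to non-blacklisted amplicons (CNV analysis)."""
        keep = [a for a in self.amplicons if not a.blacklisted]
        return PanelManifest(keep, panel_id=self.panel_id, genome_build=self.genome_build)

    def with_panel_id(self, panel_id: str) -> "PanelManifest":
        return PanelManifest(list(self.amplicons), panel_id=panel_id,
                             genome_build=self.genome_build)


@dataclass(frozen=True)
class ReadPairAlignment:
    """A mapped read pair reduced to its outer aligned span.

    ``r1_start`` is the 0-based leftmost mapped position of the first (5')
    read; ``r2_end`` the half-open rightmost mapped position of the second
    (3') read.
    """

    read_id: str
    chrom: str
    r1_start: int
    r2_end: int
    mapped: bool = True
    proper_pair: bool = True

    @property
    def valid(self) -> bool:
        return self.mapped and self.proper_pair and self.r1_start < self.r2_end


@dataclass
class VariantRecord:
    """One candidate small variant (SNV or indel) in one barcode/sample."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    gene: str
    depth: int
    alt_reads: int
    allele_freq: float
    consequence: str
    indel_len: int = 0
    exon_edge_distance: int = 100
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence label: {self.consequence!r}")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"{self.key()}: alt_reads ({self.alt_reads}) > depth ({self.depth})"
            )

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return (
            self.indel_len > 0
            or len(self.ref) != len(self.alt)
            or self.consequence in INDEL_CONSEQUENCES
        )


def variant_key_str(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


@dataclass
class KnowledgeBase:
    """Pre-materialised annotation tables driving pathogenicity triage.

    Literature / in-silico judgements (hotspot status, known inactivating
    missense changes) are inputs, not live queries, so runs are reproducible
    offline.  ``hotspots`` maps (gene, protein_change) to a source tag;
    tags containing ``in_silico`` yield Likely_pathogenic rather than
    Pathogenic classifications.
    """

    gene_roles: dict[str, str]
    hotspots: dict[tuple[str, str], str] = field(default_factory=dict)
    known_inactivating_missense: set[tuple[str, str]] = field(default_factory=set)
    population_freqs: dict[str, float] = field(default_factory=dict)
    actionable_rules: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {g: r for g, r in self.gene_roles.items()
               if r not in (ONCOGENE, TUMOUR_SUPPRESSOR)}
        if bad:
            raise ValueError(f"unknown gene role(s): {bad}")
        for k, f in self.population_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"population frequency out of [0,1] for {k}: {f}")

    def role(self, gene: str) -> str:
        try:
            return self.gene_roles[gene]
        except KeyError:
            raise KeyError(f"gene {gene} has no role in the knowledge base") from None

    def population_freq(self, record: VariantRecord) -> float:
        return self.population_freqs.get(variant_key_str(*record.key()), 0.0)

    def is_actionable(self, gene: str, alteration_class: str) -> bool:
        return (gene, alteration_class) in self.actionable_rules


@dataclass
class SampleMeta:
    """One physical specimen (CNB or FNA) with its two library barcodes."""

    sample_id: str
    sample_type: str  # "CNB" | "FNA"
    tumour_cell_fraction: float
    barcodes: list[str] = field(default_factory=list)
    qc_metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_type not in ("CNB", "FNA"):
            raise ValueError(f"sample_type must be CNB or FNA, got {self.sample_type}")


@dataclass
class SamplePair:
    """The CNB + FNA specimens of one patient.

    Pairs only enter analysis when both members reach the 10% tumour-cell
    eligibility floor used for DNA extraction.
    """

    patient_id: str
    cnb: SampleMeta
    fna: SampleMeta
    tumour_type: str = ""
    biopsy_site: str = ""

    MIN_TUMOUR_FRACTION = 0.10

    @property
    def eligible(self) -> bool:
        return (
            self.cnb.tumour_cell_fraction >= self.MIN_TUMOUR_FRACTION
            and self.fna.tumour_cell_fraction >= self.MIN_TUMOUR_FRACTION
        )


# ---------------------------------------------------------------------------
# Panel manifest I/O (BED-like TSV)
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "chrom", "start", "end", "id", "gene",
    "fwd_primer_len", "rev_primer_len", "blacklisted",
]


def read_panel_manifest(path: str | Path, panel_id: str = "A",
                        genome_build: str = "hg19") -> PanelManifest:
    """Read a tab-separated amplicon manifest.

    Raises :class:`ManifestError` with the offending line number for
    malformed rows; unsorted input is sorted silently with a logged notice.
    """
    path = Path(path)
    amplicons: list[Amplicon] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MANIFEST_COLUMNS:
            raise ManifestError(
                f"{path}: bad header {header!r}; expected {_MANIFEST_COLUMNS}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_MANIFEST_COLUMNS):
                raise ManifestError(f"{path}:{lineno}: expected "
                                    f"{len(_MANIFEST_COLUMNS)} fields, got {len(fields)}")
            try:
                amplicons.append(
                    Amplicon(
                        id=fields[3],
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        fwd_primer_len=int(fields[5]),
                        rev_primer_len=int(fields[6]),
                        gene=fields[4],
                        blacklisted=fields[7] in ("1", "true", "True"),
                    )
                )
            except (ValueError, ManifestError) as exc:
                raise ManifestError(f"{path}:{lineno}: {exc}") from exc
    return PanelManifest(amplicons, panel_id=panel_id, genome_build=genome_build)


def write_panel_manifest(manifest: PanelManifest, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for a in manifest:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.id}\t{a.gene}\t"
                f"{a.fwd_primer_len}\t{a.rev_primer_len}\t{int(a.blacklisted)}\n"
            )


# ---------------------------------------------------------------------------
# Alignment I/O (SAM via pysam)
# ---------------------------------------------------------------------------

@dataclass
class AlignmentStats:
    n_records: int = 0
    n_pairs: int = 0
    n_singletons: int = 0
    n_unmapped: int = 0
    n_skipped: int = 0


def read_alignments(path: str | Path) -> tuple[list[ReadPairAlignment], AlignmentStats]:
    """Read a SAM/BAM file into outer-span read pairs.

    Singleton alignments (mate missing or unmapped) are discarded and
    tallied; unparseable records are skipped with a counter.
    """
    stats = AlignmentStats()
    first: dict[str, pysam.AlignedSegment] = {}
    second: dict[str, pysam.AlignedSegment] = {}
    pairs: list[ReadPairAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            stats.n_records += 1
            if rec.is_secondary or rec.is_supplementary:
                stats.n_skipped += 1
                continue
            if rec.is_unmapped:
                stats.n_unmapped += 1
                continue
            if rec.mate_is_unmapped or not rec.is_paired:
                stats.n_singletons += 1
                continue
            try:
                store = second if rec.is_read2 else first
                store[rec.query_name] = rec
            except Exception:  # defensive: malformed record
                stats.n_skipped += 1
    for name, r1 in first.items():
        r2 = second.pop(name, None)
        if r2 is None:
            stats.n_singletons += 1
            continue
        # orient so r1 is the 5' (leftmost) read of the pair
        left, right = (r1, r2) if r1.reference_start <= r2.reference_start else (r2, r1)
        pair = ReadPairAlignment(
            read_id=name,
            chrom=r1.reference_name,
            r1_start=left.reference_start,
            r2_end=right.reference_end,
            mapped=True,
            proper_pair=bool(r1.is_proper_pair),
        )
        stats.n_pairs += 1
        pairs.append(pair)
    stats.n_singletons += len(second)  # read2 without read1
    return pairs, stats


def write_alignments_sam(
    pairs: Iterable[ReadPairAlignment],
    chrom_lengths: dict[str, int],
    path: str | Path,
    read_len: int = 75,
    singletons: Iterable[ReadPairAlignment] = (),
) -> None:
    """Write read pairs as minimal SAM records (two 75 bp mates per pair)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(chrom_lengths)}
        for pair in pairs:
            span = pair.r2_end - pair.r1_start
            l1 = min(read_len, span)
            l2 = min(read_len, span)
            a = pysam.AlignedSegment(out.header)
            a.query_name = pair.read_id
            a.reference_id = tid[pair.chrom]
            a.reference_start = pair.r1_start
            a.cigarstring = f"{l1}M"
            a.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate-rev, read1
            a.next_reference_id = a.reference_id
            a.next_reference_start = pair.r2_end - l2
            a.template_length = span
            a.query_sequence = "N" * l1
            a.query_qualities = pysam.qualitystring_to_array("I" * l1)
            b = pysam.AlignedSegment(out.header)
            b.query_name = pair.read_id
            b.reference_id = tid[pair.chrom]
            b.reference_start = pair.r2_end - l2
            b.cigarstring = f"{l2}M"
            b.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, read2
            b.next_reference_id = a.reference_id
            b.next_reference_start = pair.r1_start
            b.template_length = -span
            b.query_sequence = "N" * l2
            b.query_qualities = pysam.qualitystring_to_array("I" * l2)
            out.write(a)
            out.write(b)
        for s in singletons:
            a = pysam.AlignedSegment(out.header)
            a.query_name = s.read_id
            a.reference_id = tid[s.chrom]
            a.reference_start = s.r1_start
            a.cigarstring = f"{min(read_len, s.r2_end - s.r1_start)}M"
            a.flag = 0x1 | 0x8 | 0x40  # paired, mate unmapped, read1
            a.query_sequence = "N" * min(read_len, s.r2_end - s.r1_start)
            out.write(a)


# ---------------------------------------------------------------------------
# Count matrix, variant table and knowledge-base I/O (TSV via pandas)
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix: rows = amplicon ids, columns = barcode ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="amplicon_id")


_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "depth", "alt_reads", "allele_freq",
    "consequence", "indel_len", "exon_edge_distance", "protein_change",
]


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """VCF-like TSV export; positions are written 1-based."""
    rows = []
    for r in records:
        rows.append({
            "chrom": r.chrom, "pos": r.pos + 1, "ref": r.ref, "alt": r.alt,
            "gene": r.gene, "depth": r.depth, "alt_reads": r.alt_reads,
            "allele_freq": round(r.allele_freq, 6), "consequence": r.consequence,
            "indel_len": r.indel_len, "exon_edge_distance": r.exon_edge_distance,
            "protein_change": r.protein_change,
        })
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos) - 1, ref=str(row.ref),
            alt=str(row.alt), gene=str(row.gene), depth=int(row.depth),
            alt_reads=int(row.alt_reads), allele_freq=float(row.allele_freq),
            consequence=str(row.consequence), indel_len=int(row.indel_len),
            exon_edge_distance=int(row.exon_edge_distance),
            protein_change=str(row.protein_change),
        ))
    return records


def write_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(kb.gene_roles.items()), columns=["gene", "role"]
    ).to_csv(directory / "gene_roles.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((g, p, s) for (g, p), s in kb.hotspots.items()),
        columns=["gene", "protein_change", "source"],
    ).to_csv(directory / "hotspots.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(kb.known_inactivating_missense),
        columns=["gene", "protein_change"],
    ).to_csv(directory / "inactivating_missense.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(kb.population_freqs.items()), columns=["variant", "freq"]
    ).to_csv(directory / "popfreq.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(kb.actionable_rules), columns=["gene", "alteration_class"]
    ).to_csv(directory / "actionable.tsv", sep="\t", index=False)


def read_knowledge_base(directory: str | Path) -> KnowledgeBase:
    directory = Path(directory)
    roles = pd.read_csv(directory / "gene_roles.tsv", sep="\t")
    hotspots = pd.read_csv(directory / "hotspots.tsv", sep="\t")
    inact = pd.read_csv(directory / "inactivating_missense.tsv", sep="\t")
    popfreq = pd.read_csv(directory / "popfreq.tsv", sep="\t")
    actionable = pd.read_csv(directory / "actionable.tsv", sep="\t")
    return KnowledgeBase(
        gene_roles=dict(zip(roles.gene, roles.role)),
        hotspots={(g, p): s for g, p, s in
                  zip(hotspots.gene, hotspots.protein_change, hotspots.source)},
        known_inactivating_missense=set(
            zip(inact.gene, inact.protein_change)),
        population_freqs=dict(zip(popfreq.variant, popfreq.freq)),
        actionable_rules=set(zip(actionable.gene, actionable.alteration_class)),
    )
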