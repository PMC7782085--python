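"""Assign aligned read pairs to panel amplicons and count them.

In amplicon sequencing every informative read pair starts and ends at the
primer-defined ends of exactly one amplicon.  A pair is assigned when both
the first (5') read start and the second (3') read end fall within a small
coordinate tolerance (default ±3 bp) of one amplicon's ends.  Pairs whose
two ends match *different* amplicons arise from the fusion of adjacent
amplicons during library preparation and are excluded; everything else is
unassigned.  Raw per-amplicon counts (number of assigned pairs) feed the
copy-number analysis; trimmed insert spans feed the pileup used for variant
calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core_io import Amplicon, PanelManifest, ReadPairAlignment


class _Sentinel:
    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:
        return self.name


#: Pair matched no amplicon within tolerance.
UNASSIGNED = _Sentinel("UNASSIGNED")
#: Pair's ends matched the start of one amplicon and the end of another.
FUSED = _Sentinel("FUSED")


class ManifestIndex:
    """Per-chromosome arrays of amplicon starts/ends for fast window lookup."""

    def __init__(self, manifest: PanelManifest) -> None:
        self.manifest = manifest
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        per_chrom: dict[str, list[int]] = {}
        for i, a in enumerate(manifest):
            per_chrom.setdefault(a.chrom, []).append(i)
        for chrom, idx in per_chrom.items():
            starts = np.array([manifest.amplicons[i].start for i in idx])
            ends = np.array([manifest.amplicons[i].end for i in idx])
            self._by_chrom[chrom] = (starts, ends, idx)

    def candidates(self, chrom: str, r1_start: int, r2_end: int,
                   tolerance: int) -> tuple[list[int], list[int]]:
        """Manifest indices whose start (resp. end) matches within tolerance."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return [], []
        starts, ends, idx = entry
        smatch = [idx[j] for j in np.flatnonzero(np.abs(starts - r1_start) <= tolerance)]
        ematch = [idx[j] for j in np.flatnonzero(np.abs(ends - r2_end) <= tolerance)]
        return smatch, ematch


@dataclass
class SampleCounts:
    """Raw per-amplicon counts for one barcode, with assignment tallies."""

    barcode_id: str
    panel_id: str
    raw: dict[str, int]
    n_total_reads: int = 0
    n_aligned: int = 0
    n_assigned: int = 0
    tallies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.raw.values()):
            raise ValueError("negative raw counts")
        if not (self.n_assigned <= self.n_aligned <= self.n_total_reads):
            raise ValueError(
                f"count hierarchy violated: assigned={self.n_assigned} "
                f"aligned={self.n_aligned} total={self.n_total_reads}"
            )


@dataclass
class QCReport:
    """Run-level sequencing / enrichment quality metrics for one barcode."""

    n_total_reads: int
    low_read_warning: bool
    pct_aligned: float
    pct_aligned_processed: float
    coverage_pct_at: dict[int, float]

    LOW_READ_THRESHOLD = 1_000_000


def assign_pair(
    pair: ReadPairAlignment,
    manifest: PanelManifest | ManifestIndex,
    tolerance: int = 3,
    _tie_counter: dict[str, int] | None = None,
):
    """Assign one read pair to an amplicon id, ``UNASSIGNED`` or ``FUSED``.

    When two overlapping amplicons both satisfy the match, the tie is broken
    by smallest combined |offset|, then manifest order, and counted.
    """
    index = manifest if isinstance(manifest, ManifestIndex) else ManifestIndex(manifest)
    if not pair.valid:
        return UNASSIGNED
    smatch, ematch = index.candidates(pair.chrom, pair.r1_start, pair.r2_end, tolerance)
    both = sorted(set(smatch) & set(ematch))
    amplicons = index.manifest.amplicons
    if both:
        if len(both) > 1 and _tie_counter is not None:
            _tie_counter["tie_break"] = _tie_counter.get("tie_break", 0) + 1
        best = min(
            both,
            key=lambda i: (
                abs(amplicons[i].start - pair.r1_start)
                + abs(amplicons[i].end - pair.r2_end),
                i,
            ),
        )
        return amplicons[best].id
    if smatch and ematch:
        # ends belong to two different amplicons: cross-amplicon fusion
        return FUSED
    return UNASSIGNED


def trim_primers(pair: ReadPairAlignment, amplicon: Amplicon) -> tuple[int, int] | None:
    """Insert span of an assigned pair after removing sequenced primers.

    Returns ``None`` (pair dropped) when the trimmed span is empty.
    """
    start = amplicon.insert_start
    end = amplicon.insert_end
    if start >= end:
        return None
    return (start, end)


def count_amplicons(
    alignments: Iterable[ReadPairAlignment],
    manifest: PanelManifest,
    tolerance: int = 3,
    barcode_id: str = "",
    n_total_reads: int | None = None,
) -> SampleCounts:
    """Raw counts per amplicon (number of assigned pairs) for one barcode.

    Fused and unassigned pairs are excluded from counts but tallied;
    the result is independent of input order.
    """
    index = ManifestIndex(manifest)
    raw = {a.id: 0 for a in manifest}
    tallies = {"assigned": 0, "unassigned": 0, "fused": 0,
               "singleton": 0, "unmapped": 0, "tie_break": 0}
    n_pairs = 0
    for pair in alignments:
        n_pairs += 1
        if not pair.mapped:
            tallies["unmapped"] += 1
            continue
        if not pair.proper_pair:
            tallies["singleton"] += 1
            continue
        result = assign_pair(pair, index, tolerance, _tie_counter=tallies)
        if result is UNASSIGNED:
            tallies["unassigned"] += 1
        elif result is FUSED:
            tallies["fused"] += 1
        else:
            raw[result] += 1
            tallies["assigned"] += 1
    n_aligned = n_pairs - tallies["unmapped"]
    total = n_pairs if n_total_reads is None else n_total_reads
    return SampleCounts(
        barcode_id=barcode_id,
        panel_id=manifest.panel_id,
        raw=raw,
        n_total_reads=max(total, n_aligned),
        n_aligned=n_aligned,
        n_assigned=tallies["assigned"],
        tallies=tallies,
    )


def target_depth(
    assigned: Iterable[tuple[ReadPairAlignment, Amplicon]],
    manifest: PanelManifest,
) -> np.ndarray:
    """Per-base depth over the primer-trimmed target (concatenated inserts).

    Pairs whose trimmed span is empty are dropped.  The returned vector has
    one entry per targeted coding base, in manifest order.
    """
    offsets: dict[str, int] = {}
    total = 0
    for a in manifest:
        offsets[a.id] = total
        total += max(a.insert_end - a.insert_start, 0)
    depth = np.zeros(total, dtype=np.int64)
    for pair, amplicon in assigned:
        span = trim_primers(pair, amplicon)
        if span is None:
            continue
        off = offsets[amplicon.id]
        n = amplicon.insert_end - amplicon.insert_start
        depth[off:off + n] += 1
    return depth


def qc_report(
    counts: SampleCounts,
    depth: np.ndarray,
    thresholds: tuple[int, ...] = (100, 300, 1000),
) -> QCReport:
    """Sequencing QC: read-count warning, alignment rates, coverage tiers."""
    total = counts.n_total_reads
    coverage = {}
    for t in thresholds:
        coverage[t] = float(np.mean(depth >= t)) if depth.size else 0.0
    return QCReport(
        n_total_reads=total,
        low_read_warning=total < QCReport.LOW_READ_THRESHOLD,
        pct_aligned=100.0 * counts.n_aligned / total if total else 0.0,
        pct_aligned_processed=100.0 * counts.n_assigned / total if total else 0.0,
        coverage_pct_at=coverage,
    )
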