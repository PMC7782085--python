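"""Count-based copy-number calling: normalization, segmentation, statuses.

Per-amplicon read counts proxy local copy number.  Counts are normalized in
two median steps — by the median over all amplicons within each barcode
(library size), then by the median over all barcodes within each amplicon
(amplicon efficiency) — leaving a ratio whose log2 is ~0 for copy-neutral
loci.  The log2 ratios, ordered by genome coordinate, are segmented with an
exact dynamic-programming least-squares fit, and each segment's *median*
log2 value is thresholded into a status:

    median log2 < -1     homozygous deletion    (strict)
    median log2 > 2      amplification          (strict)
    median log2 <= -0.41 heterozygous deletion  (configurable)
    median log2 >= 0.58  gain                   (configurable)

The two strict thresholds are the assay's published decision points; the
intermediate ones are the ideal single-copy values at 50% tumour content
and are exposed in :class:`CnvThresholds` as an explicit extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import PanelManifest

logger = logging.getLogger("ampliconcord")

HOMOZYGOUS_DELETION = "homozygous_deletion"
HETEROZYGOUS_DELETION = "heterozygous_deletion"
NORMAL = "normal"
GAIN = "gain"
AMPLIFICATION = "amplification"


@dataclass(frozen=True)
class CnvThresholds:
    """Segment-median log2 cutoffs for status calls.

    ``homdel`` and ``amp`` are strict inequalities; ``hetdel`` and ``gain``
    inclusive.
    """

    homdel: float = -1.0
    amp: float = 2.0
    hetdel: float = -0.41
    gain: float = 0.58


@dataclass
class NormalizedMatrix:
    """Double-median normalized count ratios and their log2."""

    values: pd.DataFrame  # rows = amplicons, cols = barcodes
    log2: pd.DataFrame


@dataclass
class Segment:
    chrom: str
    start_index: int  # ordered-amplicon index, inclusive
    end_index: int    # exclusive
    median_log2: float
    n_amplicons: int
    status: str = NORMAL


@dataclass
class SegmentedProfile:
    """Piecewise-constant partition of the ordered amplicon axis."""

    segments: list[Segment]
    amplicon_ids: list[str] = field(default_factory=list)

    def segment_of(self, index: int) -> Segment:
        for seg in self.segments:
            if seg.start_index <= index < seg.end_index:
                return seg
        raise IndexError(index)


@dataclass
class CnvCall:
    gene: str
    status: str
    median_log2: float
    segment: Segment
    panel_id: str = "A"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(
    counts: pd.DataFrame,
    manifest: PanelManifest | None = None,
    pseudocount: float = 0.5,
) -> NormalizedMatrix:
    """Two-step median normalization of a raw count matrix.

    Rows are amplicon ids, columns barcode ids.  Blacklisted amplicons are
    removed first when a manifest is given.  Zero counts are replaced by
    ``pseudocount`` before the ratios are formed so log2 stays finite (a
    homozygous-deletion segment then shows a strongly negative ratio rather
    than -inf).  A barcode whose counts are all zero is rejected.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization needs >= 2 barcodes")
    if manifest is not None:
        keep = [a.id for a in manifest if not a.blacklisted]
        counts = counts.loc[[i for i in counts.index if i in set(keep)]]
    dead = [c for c in counts.columns if (counts[c] == 0).all()]
    if dead:
        raise ValueError(f"barcode(s) with all-zero counts: {dead}")
    x = counts.astype(float).where(counts > 0, pseudocount)
    # step 1: median over all amplicons, per barcode
    x = x / x.median(axis=0)
    # step 2: median over all barcodes, per amplicon
    x = x.div(x.median(axis=1), axis=0)
    return NormalizedMatrix(values=x, log2=np.log2(x))


# ---------------------------------------------------------------------------
# Segmentation: exact least-squares DP with per-segment penalty
# ---------------------------------------------------------------------------

def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise scale from median absolute successive differences.

    For i.i.d. Gaussian noise, successive differences have sd sigma*sqrt(2)
    and MAD->0.6745*sigma*sqrt(2), hence the 0.9539 divisor.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(x))) / 0.9539)


def default_penalty(x: np.ndarray) -> float:
    """Modified-BIC-style penalty: 2 * sigma^2 * log(n)."""
    n = len(x)
    if n < 2:
        return 0.0
    return 2.0 * estimate_noise_sd(x) ** 2 * np.log(n)


def _segment_indices(x: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Exact minimizer of sum of within-segment squared deviations from the
    segment mean, plus ``penalty`` per segment.  Ties prefer fewer segments.
    """
    n = len(x)
    if n == 0:
        return []
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    best = np.empty(n + 1)
    nseg = np.zeros(n + 1, dtype=int)
    back = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    for j in range(1, n + 1):
        i = np.arange(j)
        lens = j - i
        cost = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / lens
        tot = best[:j] + cost + penalty
        lo = tot.min()
        tol = 1e-9 * (1.0 + abs(lo))
        cand = np.flatnonzero(tot <= lo + tol)
        pick = cand[np.argmin(nseg[cand])]
        best[j] = tot[pick]
        nseg[j] = nseg[pick] + 1
        back[j] = pick
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((int(i), int(j)))
        j = i
    return bounds[::-1]


def segment(
    log2_values: Sequence[float],
    penalty: float | None = None,
    chrom: str = "chr1",
    index_offset: int = 0,
    thresholds: CnvThresholds = CnvThresholds(),
) -> SegmentedProfile:
    """Segment one chromosome's coordinate-ordered log2 ratios.

    The fit is the exact DP minimization of within-segment sum of squared
    deviations + penalty x (number of segments); each segment is summarised
    by the *median* log2 of its amplicons and given a status.
    """
    x = np.asarray(log2_values, dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("non-finite log2 values")
    if penalty is None:
        penalty = default_penalty(x)
    if penalty < 0:
        raise ValueError("penalty must be > 0")
    segs = []
    for i, j in _segment_indices(x, penalty):
        med = float(np.median(x[i:j]))
        segs.append(Segment(
            chrom=chrom,
            start_index=index_offset + i,
            end_index=index_offset + j,
            median_log2=med,
            n_amplicons=j - i,
            status=call_status(med, thresholds),
        ))
    return SegmentedProfile(segments=segs)


def segment_profile(
    log2_series: pd.Series,
    manifest: PanelManifest,
    penalty: float | None = None,
    thresholds: CnvThresholds = CnvThresholds(),
) -> SegmentedProfile:
    """Per-chromosome segmentation of a whole-panel log2 vector.

    ``log2_series`` is indexed by amplicon id; amplicons are processed in
    manifest (genome) order, each chromosome segmented independently, and
    the segments concatenated on the shared ordered-amplicon axis.
    """
    order = [a for a in manifest if not a.blacklisted and a.id in log2_series.index]
    ids = [a.id for a in order]
    values = log2_series.loc[ids].to_numpy(dtype=float)
    segs: list[Segment] = []
    offset = 0
    pos = 0
    while pos < len(order):
        chrom = order[pos].chrom
        end = pos
        while end < len(order) and order[end].chrom == chrom:
            end += 1
        sub = values[pos:end]
        prof = segment(sub, penalty=penalty, chrom=chrom,
                       index_offset=offset, thresholds=thresholds)
        segs.extend(prof.segments)
        offset += end - pos
        pos = end
    return SegmentedProfile(segments=segs, amplicon_ids=ids)


# ---------------------------------------------------------------------------
# Status calls
# ---------------------------------------------------------------------------

def call_status(median_log2: float, thresholds: CnvThresholds = CnvThresholds()) -> str:
    """Status from a segment's median log2 ratio (strict at homdel/amp)."""
    if median_log2 < thresholds.homdel:
        return HOMOZYGOUS_DELETION
    if median_log2 > thresholds.amp:
        return AMPLIFICATION
    if median_log2 <= thresholds.hetdel:
        return HETEROZYGOUS_DELETION
    if median_log2 >= thresholds.gain:
        return GAIN
    return NORMAL


def _gene_positions(profile: SegmentedProfile,
                    manifest: PanelManifest) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i, aid in enumerate(profile.amplicon_ids):
        pos.setdefault(manifest.by_id(aid).gene, []).append(i)
    return pos


def _gene_call(profile: SegmentedProfile, manifest: PanelManifest,
               gene: str, panel_id: str,
               positions: dict[str, list[int]] | None = None) -> CnvCall:
    if positions is None:
        positions = _gene_positions(profile, manifest)
    pos = positions.get(gene, [])
    if not pos:
        raise KeyError(f"gene {gene} has no analysable amplicons in profile")
    segs = [profile.segment_of(i) for i in pos]
    # supporting segment = the one covering most of the gene's amplicons;
    # ties resolved toward the segment of the gene's central amplicon
    counts: dict[int, int] = {}
    for s in segs:
        counts[id(s)] = counts.get(id(s), 0) + 1
    central = profile.segment_of(pos[len(pos) // 2])
    support = max(segs, key=lambda s: (counts[id(s)], s is central))
    return CnvCall(gene=gene, status=support.status,
                   median_log2=support.median_log2, segment=support,
                   panel_id=panel_id)


def gene_level_calls(
    profile_a: SegmentedProfile,
    profile_b: SegmentedProfile | None,
    manifest: PanelManifest,
    panel_consensus: bool = True,
) -> list[CnvCall]:
    """Per-gene CNV calls, optionally requiring A/B barcode consensus.

    With consensus on, a gene call is emitted only when both barcodes agree
    on the status; the reported median log2 is always taken from barcode A.
    Discrepant genes are logged and dropped.  Genes whose supporting status
    is ``normal`` are not emitted.
    """
    if panel_consensus and profile_b is None:
        raise ValueError("consensus requested but no second profile given")
    pos_a = _gene_positions(profile_a, manifest)
    pos_b = _gene_positions(profile_b, manifest) if profile_b is not None else None
    calls = []
    for gene in manifest.genes:
        call_a = _gene_call(profile_a, manifest, gene, panel_id="A",
                            positions=pos_a)
        if panel_consensus:
            call_b = _gene_call(profile_b, manifest, gene, panel_id="B",
                                positions=pos_b)
            if call_a.status != call_b.status:
                logger.info("gene %s: panel discrepancy A=%s B=%s; no call",
                            gene, call_a.status, call_b.status)
                continue
        if call_a.status != NORMAL:
            calls.append(call_a)
    return calls
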