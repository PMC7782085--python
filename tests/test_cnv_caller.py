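"""Normalization invariants, exact segmentation, and status thresholds."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ampliconcord import (
    CnvThresholds,
    call_status,
    gene_level_calls,
    normalize,
    segment,
    segment_profile,
)
from ampliconcord.cnv_caller import (
    AMPLIFICATION,
    GAIN,
    HETEROZYGOUS_DELETION,
    HOMOZYGOUS_DELETION,
    NORMAL,
    _segment_indices,
)
from ampliconcord.core_io import Amplicon, PanelManifest


def brute_force_segmentation(x, penalty):
    """Exhaustive minimum of SSE + penalty * K over all 2^(n-1) partitions."""
    n = len(x)
    best = (np.inf, np.inf)
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        sse = sum(np.sum((np.array(x[i:j]) - np.mean(x[i:j])) ** 2)
                  for i, j in zip(bounds[:-1], bounds[1:]))
        k = len(bounds) - 1
        cand = (sse + penalty * k, k)
        if cand < best:
            best = cand
    return best


class TestNormalize:
    def test_constant_matrix_normalizes_to_one(self):
        counts = pd.DataFrame(np.full((4, 3), 7.0),
                              index=list("abcd"), columns=list("xyz"))
        norm = normalize(counts)
        assert np.allclose(norm.values, 1.0)
        assert np.allclose(norm.log2, 0.0)

    def test_hand_computed_two_barcode_example(self):
        # two identical barcodes with counts 10, 20, 40: both median steps
        # reduce every entry to exactly 1
        counts = pd.DataFrame({"b1": [10, 20, 40], "b2": [10, 20, 40]},
                              index=["a1", "a2", "a3"], dtype=float)
        norm = normalize(counts)
        assert np.allclose(norm.values, 1.0)

    def test_library_size_factor_removed_by_first_step(self):
        rng = np.random.default_rng(11)
        base = rng.lognormal(5, 0.4, size=50)
        counts = pd.DataFrame({
            "b1": base, "b2": base, "b3": 2.0 * base,  # doubled library
        }, index=[f"a{i}" for i in range(50)])
        norm = normalize(counts)
        assert np.allclose(norm.log2["b3"], 0.0, atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_median_invariants_hold_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(1, 5000, size=(11, 5)).astype(float),
            index=[f"a{i}" for i in range(11)],
            columns=[f"b{j}" for j in range(5)])
        x = counts.where(counts > 0, 0.5)
        step1 = x / x.median(axis=0)
        assert np.allclose(step1.median(axis=0), 1.0)
        norm = normalize(counts)
        # step 2 fixes the per-amplicon cross-barcode median at 1
        assert np.allclose(norm.values.median(axis=1), 1.0)

    def test_idempotence_on_fully_normalized_matrix(self):
        # the double-median map has a fixed point (both median invariants
        # holding at once); once reached, normalize leaves it unchanged
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.integers(10, 3000, size=(21, 7)).astype(float),
            index=[f"a{i}" for i in range(21)],
            columns=[f"b{j}" for j in range(7)])
        fixed = normalize(normalize(counts).values).values
        again = normalize(fixed).values
        assert np.allclose(fixed, again, atol=1e-12)

    def test_amplified_span_log2_is_exactly_two(self):
        # a 10-amplicon span at 4x the flat background (total copy number 8
        # at full cellularity) must land at log2 ratio 2 after both steps
        n = 60
        counts = pd.DataFrame(
            np.full((n, 5), 100.0), index=[f"a{i}" for i in range(n)],
            columns=[f"b{j}" for j in range(5)])
        counts.iloc[20:30, 0] = 400.0
        norm = normalize(counts)
        assert np.allclose(norm.log2.iloc[20:30, 0], 2.0)
        assert np.allclose(norm.log2.iloc[:20, 0], 0.0)

    def test_all_zero_barcode_rejected(self):
        counts = pd.DataFrame({"b1": [1, 2], "b2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            normalize(counts)

    def test_single_barcode_rejected(self):
        counts = pd.DataFrame({"b1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match=">= 2"):
            normalize(counts)

    def test_blacklisted_amplicons_removed(self):
        manifest = PanelManifest([
            Amplicon("a1", "chr1", 100, 240, 20, 20, "G"),
            Amplicon("a2", "chr1", 300, 440, 20, 20, "G", blacklisted=True),
        ])
        counts = pd.DataFrame({"b1": [10, 99], "b2": [10, 99]},
                              index=["a1", "a2"])
        norm = normalize(counts, manifest)
        assert list(norm.values.index) == ["a1"]


class TestSegment:
    def test_flat_vector_is_one_segment(self):
        prof = segment([0.1] * 30)
        assert len(prof.segments) == 1
        assert prof.segments[0].n_amplicons == 30

    def test_noiseless_step_found_exactly(self):
        x = [0.0] * 20 + [-2.0] * 20
        prof = segment(x)
        assert [(s.start_index, s.end_index) for s in prof.segments] == \
            [(0, 20), (20, 40)]
        assert prof.segments[1].median_log2 == -2.0

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            segment([0.0, np.nan, 1.0])

    @given(st.integers(0, 2**32 - 1), st.integers(2, 12),
           st.sampled_from([0.05, 0.3, 1.0]))
    def test_dp_equals_exhaustive_search(self, seed, n, penalty):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=n)
        bounds = _segment_indices(x, penalty)
        sse = sum(float(np.sum((x[i:j] - np.mean(x[i:j])) ** 2))
                  for i, j in bounds)
        dp_obj = sse + penalty * len(bounds)
        brute_obj, brute_k = brute_force_segmentation(list(x), penalty)
        assert dp_obj == pytest.approx(brute_obj, abs=1e-9)
        assert len(bounds) == brute_k

    def test_profile_segments_do_not_cross_chromosomes(self):
        manifest = PanelManifest(
            [Amplicon(f"a{i}", "chr1" if i < 5 else "chr2",
                      100 + 200 * (i % 5), 240 + 200 * (i % 5), 20, 20, "G")
             for i in range(10)])
        log2 = pd.Series(0.0, index=manifest.ids)
        prof = segment_profile(log2, manifest)
        assert [(s.chrom, s.start_index, s.end_index) for s in prof.segments] \
            == [("chr1", 0, 5), ("chr2", 5, 10)]


class TestCallStatus:
    @pytest.mark.parametrize("value,expected", [
        (-1.5, HOMOZYGOUS_DELETION),
        (-1.0, HETEROZYGOUS_DELETION),   # strict at -1
        (-0.41, HETEROZYGOUS_DELETION),
        (-0.40, NORMAL),
        (0.57, NORMAL),
        (0.58, GAIN),
        (2.0, GAIN),                     # strict at 2
        (2.5, AMPLIFICATION),
    ])
    def test_threshold_boundaries(self, value, expected):
        assert call_status(value) == expected

    def test_thresholds_configurable(self):
        t = CnvThresholds(hetdel=-0.2, gain=0.3)
        assert call_status(-0.25, t) == HETEROZYGOUS_DELETION
        assert call_status(0.35, t) == GAIN


def _two_gene_manifest():
    amps = []
    for gi, gene in enumerate(["G1", "G2"]):
        for ai in range(5):
            start = 1000 * gi + 200 * ai
            amps.append(Amplicon(f"{gene}_a{ai}", "chr1", start + 100,
                                 start + 240, 20, 20, gene))
    return PanelManifest(amps)


def _profile(manifest, values):
    return segment_profile(pd.Series(values, index=manifest.ids), manifest,
                           penalty=0.05)


class TestGeneLevelCalls:
    def test_consensus_emits_panel_a_value(self):
        manifest = _two_gene_manifest()
        a = _profile(manifest, [2.5] * 5 + [0.0] * 5)
        b = _profile(manifest, [2.3] * 5 + [0.0] * 5)
        calls = gene_level_calls(a, b, manifest)
        assert len(calls) == 1
        assert calls[0].gene == "G1"
        assert calls[0].status == AMPLIFICATION
        assert calls[0].median_log2 == pytest.approx(2.5)
        assert calls[0].panel_id == "A"

    def test_panel_discrepancy_suppresses_call(self):
        manifest = _two_gene_manifest()
        a = _profile(manifest, [2.5] * 5 + [0.0] * 5)
        b = _profile(manifest, [0.0] * 10)
        assert gene_level_calls(a, b, manifest) == []

    def test_consensus_off_passes_single_panel_calls(self):
        manifest = _two_gene_manifest()
        a = _profile(manifest, [0.0] * 5 + [-1.4] * 5)
        calls = gene_level_calls(a, None, manifest, panel_consensus=False)
        assert [(c.gene, c.status) for c in calls] == \
            [("G2", HOMOZYGOUS_DELETION)]
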