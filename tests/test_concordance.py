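"""Pairing logic, cohort tallies, correlation and group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ampliconcord import (
    AlterationObservation,
    af_correlation,
    bh_adjust,
    cnv_pair_correlation,
    cohort_summary,
    kruskal_dunn,
    pair_and_classify,
    qc_group_tests,
)
from ampliconcord.cnv_caller import Segment, SegmentedProfile
from ampliconcord.concordance import CNB_ONLY, CONCORDANT, FNA_ONLY


def obs(gene, klass, status, validated=True, actionable=False, af=None):
    return AlterationObservation(gene, klass, status, validated,
                                 actionable, af)


HOMDEL = "homozygous_deletion"
AMP = "amplification"
VAR = "pathogenic_variant"


class TestPairAndClassify:
    def test_shared_homozygous_deletion_is_concordant(self):
        pairs = pair_and_classify(
            [obs("CDKN2A", HOMDEL, "Homozygous deletion")],
            [obs("CDKN2A", HOMDEL, "Homozygous deletion")], "p1")
        assert len(pairs) == 1
        assert pairs[0].concordant and pairs[0].direction == CONCORDANT

    def test_fna_only_homdel_is_discordant(self):
        pairs = pair_and_classify(
            [], [obs("PTEN", HOMDEL, "Homozygous deletion")], "p27")
        assert len(pairs) == 1
        assert not pairs[0].concordant
        assert pairs[0].direction == FNA_ONLY
        assert pairs[0].cnb_result == "Normal"

    def test_homdel_versus_hetdel_is_discordant(self):
        pairs = pair_and_classify(
            [obs("MAP2K4", HOMDEL, "Homozygous deletion")],
            [obs("MAP2K4", HOMDEL, "Heterozygous deletion",
                 validated=False)], "p49")
        assert len(pairs) == 1
        assert not pairs[0].concordant
        assert pairs[0].direction == CNB_ONLY
        assert pairs[0].fna_result == "Heterozygous deletion"

    def test_het_only_finding_visible_under_special_rule(self):
        het = [obs("TP53", VAR, "Heterozygous mutation", validated=False)]
        with_rule = pair_and_classify(het, [], "p1", special_het_rule=True)
        without = pair_and_classify(het, [], "p1", special_het_rule=False)
        assert len(with_rule) == 1 and not with_rule[0].concordant
        assert with_rule[0].fna_result == "WT"
        assert without == []

    def test_het_context_against_validated_hom_prints_both_statuses(self):
        pairs = pair_and_classify(
            [obs("NF1", VAR, "Heterozygous mutation", validated=False)],
            [obs("NF1", VAR, "Homozygous mutation")], "p19")
        assert len(pairs) == 1
        assert pairs[0].direction == FNA_ONLY
        assert (pairs[0].cnb_result, pairs[0].fna_result) == \
            ("Heterozygous mutation", "Homozygous mutation")

    obs_strategy = st.lists(
        st.tuples(st.sampled_from(["G1", "G2", "G3", "G4"]),
                  st.sampled_from([VAR, AMP, HOMDEL]),
                  st.booleans()),
        max_size=6, unique_by=lambda t: (t[0], t[1]))

    @staticmethod
    def _make(entries):
        status = {VAR: "Homozygous mutation", AMP: "Amplification",
                  HOMDEL: "Homozygous deletion"}
        return [obs(g, k, status[k], validated=v) for g, k, v in entries]

    @given(obs_strategy, obs_strategy)
    def test_outer_join_conservation(self, e_cnb, e_fna):
        pairs = pair_and_classify(self._make(e_cnb), self._make(e_fna), "p")
        keys_validated = ({(g, k) for g, k, v in e_cnb if v}
                          | {(g, k) for g, k, v in e_fna if v})
        assert len(pairs) == len(keys_validated)
        n = {CONCORDANT: 0, CNB_ONLY: 0, FNA_ONLY: 0}
        for p in pairs:
            n[p.direction] += 1
        assert sum(n.values()) == len(pairs)

    @given(obs_strategy, obs_strategy)
    def test_label_swap_symmetry(self, e_cnb, e_fna):
        fwd = pair_and_classify(self._make(e_cnb), self._make(e_fna), "p")
        rev = pair_and_classify(self._make(e_fna), self._make(e_cnb), "p")
        count = lambda ps, d: sum(1 for p in ps if p.direction == d)
        assert count(fwd, CONCORDANT) == count(rev, CONCORDANT)
        assert count(fwd, CNB_ONLY) == count(rev, FNA_ONLY)
        assert count(fwd, FNA_ONLY) == count(rev, CNB_ONLY)


class TestCohortSummary:
    def test_all_concordant_cohort(self):
        pairs = pair_and_classify(
            [obs("CDKN2A", HOMDEL, "Homozygous deletion")],
            [obs("CDKN2A", HOMDEL, "Homozygous deletion")], "p1")
        report = cohort_summary(pairs)
        assert report.pooled_pct == 100.0
        assert report.n_discordant_patients == 0
        assert report.n_fully_concordant_patients == 1

    def test_empty_cohort_reports_na(self):
        report = cohort_summary([])
        assert report.n_total == 0
        assert report.pooled_pct is None
        assert report.pct_actionable is None

    def test_patients_without_alterations_count_as_concordant(self):
        report = cohort_summary([], patient_ids=["p1", "p2"])
        assert report.n_fully_concordant_patients == 2


class TestAfCorrelation:
    def test_identical_vectors_give_unity(self):
        f = [0.1, 0.2, 0.4, 0.6]
        assert af_correlation(f, f) == pytest.approx(1.0)

    def test_transform_endpoints(self):
        assert math.asin(math.sqrt(0.0)) == 0.0
        assert math.asin(math.sqrt(1.0)) == pytest.approx(math.pi / 2)

    def test_matches_independent_recomputation(self, rng):
        a = rng.uniform(0, 1, size=40)
        b = np.clip(a + rng.normal(0, 0.1, size=40), 0, 1)
        ta, tb = np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))
        expected = (np.mean(ta * tb) - ta.mean() * tb.mean()) / (
            ta.std() * tb.std())
        assert af_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_gives_nan(self):
        r = af_correlation([0.2, 0.2, 0.2], [0.1, 0.5, 0.9])
        assert math.isnan(r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            af_correlation([0.1, 0.2], [0.1, 0.2])


def brute_force_bh(p, q=0.05):
    """Largest k with p_(k) <= k q / m; rejects the k smallest p-values."""
    p = np.asarray(p)
    order = np.argsort(p)
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


class TestBenjaminiHochberg:
    def test_hand_example_all_adjust_to_largest(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)
        assert all(adj < 0.05)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
           st.sampled_from([0.01, 0.05, 0.2]))
    def test_adjusted_pvalues_match_step_up_rejections(self, pvals, q):
        p = np.asarray(pvals)
        assert np.array_equal(bh_adjust(p) <= q, brute_force_bh(p, q))


def profile(medians, seg_len=5):
    segs = []
    for i, m in enumerate(medians):
        segs.append(Segment("chr1", i * seg_len, (i + 1) * seg_len,
                            float(m), seg_len))
    return SegmentedProfile(segs)


class TestCnvPairCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        p1 = profile([0.0, -1.2, 0.1, 2.1])
        pairs = {"p1": (p1, profile([0.0, -1.2, 0.1, 2.1])),
                 "p2": (profile([0.0, -0.5, 0.3, 1.0]),
                        profile([0.3, 0.1, -0.2, 0.4]))}
        df = cnv_pair_correlation(pairs)
        row = df.set_index("patient_id").loc["p1"]
        assert row.r == pytest.approx(1.0)
        assert row.p == df.p.min()

    def test_pairs_with_too_few_overlaps_excluded(self):
        pairs = {"p1": (profile([0.0, 1.0]), profile([0.0, 1.0]))}
        df = cnv_pair_correlation(pairs, min_overlap=3)
        assert len(df) == 0

    def test_misaligned_boundaries_use_atomic_overlaps(self):
        a = SegmentedProfile([Segment("chr1", 0, 6, 0.0, 6),
                              Segment("chr1", 6, 12, -1.0, 6)])
        b = SegmentedProfile([Segment("chr1", 0, 4, 0.1, 4),
                              Segment("chr1", 4, 12, -0.8, 8)])
        from ampliconcord.concordance import overlapping_segment_values
        va, vb = overlapping_segment_values(a, b)
        assert list(va) == [0.0, 0.0, -1.0]
        assert list(vb) == [0.1, -0.8, -0.8]

    def test_null_profiles_rarely_significant(self, rng):
        pairs = {}
        for i in range(100):
            pairs[f"p{i}"] = (profile(rng.normal(0, 0.3, size=6)),
                              profile(rng.normal(0, 0.3, size=6)))
        df = cnv_pair_correlation(pairs)
        assert df.significant.mean() <= 0.10


def exact_mannwhitney_p(a, b):
    """Two-sided exact permutation p-value for the Mann-Whitney U statistic."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    mu = len(a) * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = stats.mannwhitneyu(pooled[mask], pooled[~mask],
                               alternative="two-sided").statistic
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestGroupComparisons:
    def test_identical_groups_show_no_stars(self):
        df = pd.DataFrame({"metric": np.arange(10.0)})
        out = qc_group_tests(df, df.copy())
        assert out.loc[0, "stars"] == ""
        assert out.loc[0, "p"] > 0.5

    def test_mann_whitney_agrees_with_exact_permutation(self, rng):
        a = rng.normal(0, 1, size=6)
        b = rng.normal(1.2, 1, size=5)
        p_scipy = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
        p_perm = exact_mannwhitney_p(a, b)
        assert p_scipy == pytest.approx(p_perm, abs=1e-9)

    def test_cellularity_gap_detected_in_default_cohort(self, default_cohort):
        cnb = pd.DataFrame([p.cnb.qc_metrics for p in default_cohort.pairs])
        fna = pd.DataFrame([p.fna.qc_metrics for p in default_cohort.pairs])
        out = qc_group_tests(cnb, fna).set_index("metric")
        assert out.loc["tumour_pct", "p"] < 0.001
        # matched assay metrics show no group difference at this n
        assert out.loc["ratio_260_280", "p"] > 0.05

    def test_kruskal_dunn_flags_separated_strata(self, rng):
        values = np.concatenate([rng.normal(0, 1, 30),
                                 rng.normal(0, 1, 30),
                                 rng.normal(4, 1, 30)])
        groups = np.repeat(["<50", "50-100", ">100"], 30)
        kw_p, dunn = kruskal_dunn(values, groups)
        assert kw_p < 0.001

        def p_adj(ga, gb):
            m = dunn[((dunn.group_a == ga) & (dunn.group_b == gb))
                     | ((dunn.group_a == gb) & (dunn.group_b == ga))]
            return float(m.p_adj.iloc[0])

        assert p_adj("<50", "50-100") > 0.05
        assert p_adj("50-100", ">100") < 0.01

    def test_kruskal_dunn_small_groups_na(self):
        kw_p, dunn = kruskal_dunn([1.0, 2.0], ["a", "b"])
        assert math.isnan(kw_p)
        assert len(dunn) == 0
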