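"""Paired CNB/FNA concordance accounting and cohort statistics.

A patient's two specimens are compared at the level of *validated*
gene-level alterations, keyed by gene + alteration class (pathogenic
variant, amplification, homozygous deletion).  A pair is concordant when
both specimens carry the same validated alteration; an alteration validated
in only one specimen is a discordance attributed to the silent side.  For
tumour-suppressor mutations only homozygous (bi-allelically inactivating)
findings are validated, but a heterozygous-only finding facing an empty
partner sample is kept visible as a discordance.

Cohort statistics: pooled and per-category concordance fractions,
arcsine-square-root Pearson correlation of paired variant allele
frequencies, per-pair Pearson correlation of overlapping copy-number
segments with Benjamini-Hochberg control, and nonparametric group
comparisons of QC metrics (Mann-Whitney; Kruskal-Wallis with Dunn's
post-hoc across DNA-concentration strata).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnv_caller import (
    AMPLIFICATION,
    HOMOZYGOUS_DELETION,
    SegmentedProfile,
)
from .validation_engine import (
    HOMOZYGOUS,
    PATHOGENIC_VARIANT,
    ValidatedAlteration,
)

logger = logging.getLogger("ampliconcord")

CONCORDANT = "concordant"
CNB_ONLY = "cnb_only"
FNA_ONLY = "fna_only"

#: Printed status vocabulary used in the discordance ledger.
ABSENT_STATUS = {
    PATHOGENIC_VARIANT: "Absent",
    AMPLIFICATION: "Normal",
    HOMOZYGOUS_DELETION: "Normal",
}


@dataclass(frozen=True)
class AlterationObservation:
    """One gene-level finding in one sample, validated or context-only.

    Context-only observations (a lone heterozygous tumour-suppressor
    mutation, a heterozygous deletion, a gain) never count as validated
    alterations but supply the printed status for the partner column of the
    discordance ledger, and — for heterozygous mutations — trigger the
    het-versus-nothing visibility rule.
    """

    gene: str
    alteration_class: str
    status: str
    validated: bool
    actionable: bool = False
    allele_freq: float | None = None


def observation_from_validated(alt: ValidatedAlteration) -> AlterationObservation:
    if alt.alteration_class == PATHOGENIC_VARIANT:
        status = ("Homozygous mutation" if alt.zygosity == HOMOZYGOUS
                  else "Heterozygous mutation")
    elif alt.alteration_class == AMPLIFICATION:
        status = "Amplification"
    else:
        status = "Homozygous deletion"
    return AlterationObservation(
        gene=alt.gene, alteration_class=alt.alteration_class, status=status,
        validated=True, actionable=alt.actionable, allele_freq=alt.allele_freq,
    )


@dataclass
class PairedAlteration:
    """One row of the per-patient concordance ledger."""

    patient_id: str
    gene: str
    alteration_class: str
    cnb_result: str
    fna_result: str
    concordant: bool
    direction: str  # concordant | cnb_only | fna_only
    actionable: bool = False
    cnb_af: float | None = None
    fna_af: float | None = None


@dataclass
class CohortReport:
    """Cohort-level tallies over all paired alterations."""

    counts: dict[str, dict[str, int]]  # class -> {concordant, cnb_only, fna_only}
    n_concordant: int
    n_total: int
    pooled_pct: float | None
    n_fully_concordant_patients: int
    n_discordant_patients: int
    n_actionable: int
    n_actionable_concordant: int
    pct_actionable: float | None
    pct_actionable_concordant: float | None
    per_class_pct: dict[str, float | None] = field(default_factory=dict)


def _merge_duplicates(obs: list[AlterationObservation],
                      patient_id: str) -> dict[tuple[str, str], AlterationObservation]:
    merged: dict[tuple[str, str], AlterationObservation] = {}
    for o in obs:
        key = (o.gene, o.alteration_class)
        if key in merged:
            logger.warning("patient %s: duplicate %s/%s observation merged",
                           patient_id, *key)
            if o.validated and not merged[key].validated:
                merged[key] = o
        else:
            merged[key] = o
    return merged


def pair_and_classify(
    cnb: list[AlterationObservation],
    fna: list[AlterationObservation],
    patient_id: str = "",
    special_het_rule: bool = True,
) -> list[PairedAlteration]:
    """Outer-join the two specimens' observations and classify each event.

    Emitted events are those where at least one side is validated, plus —
    with ``special_het_rule`` — heterozygous-mutation observations whose
    partner sample shows nothing at all for that gene and class.
    """
    c = _merge_duplicates(cnb, patient_id)
    f = _merge_duplicates(fna, patient_id)
    out: list[PairedAlteration] = []
    for key in sorted(set(c) | set(f)):
        gene, klass = key
        oc, of = c.get(key), f.get(key)
        c_val = oc is not None and oc.validated
        f_val = of is not None and of.validated
        if not c_val and not f_val:
            het_only = (
                special_het_rule
                and klass == PATHOGENIC_VARIANT
                and ((oc is not None and of is None
                      and oc.status == "Heterozygous mutation")
                     or (of is not None and oc is None
                         and of.status == "Heterozygous mutation"))
            )
            if not het_only:
                continue
        cnb_status = oc.status if oc is not None else ABSENT_STATUS[klass]
        fna_status = of.status if of is not None else ABSENT_STATUS[klass]
        if klass == PATHOGENIC_VARIANT and oc is None:
            cnb_status = "WT"
        if klass == PATHOGENIC_VARIANT and of is None:
            fna_status = "WT"
        if c_val and f_val:
            concordant, direction = True, CONCORDANT
        elif c_val or (oc is not None and not f_val):
            concordant, direction = False, CNB_ONLY
        else:
            concordant, direction = False, FNA_ONLY
        out.append(PairedAlteration(
            patient_id=patient_id, gene=gene, alteration_class=klass,
            cnb_result=cnb_status, fna_result=fna_status,
            concordant=concordant, direction=direction,
            actionable=bool((oc is not None and oc.actionable)
                            or (of is not None and of.actionable)),
            cnb_af=oc.allele_freq if oc is not None else None,
            fna_af=of.allele_freq if of is not None else None,
        ))
    return out


def _round_pct(num: int, den: int) -> float | None:
    """Percentage rounded half-up to the nearest integer, as printed."""
    if den == 0:
        return None
    return float(math.floor(100.0 * num / den + 0.5))


def cohort_summary(
    pairs: list[PairedAlteration],
    patient_ids: list[str] | None = None,
) -> CohortReport:
    """Tally paired alterations into the cohort concordance report.

    ``patient_ids`` fixes the cohort denominator for the fully-concordant
    patient count (patients with no alterations at all are fully
    concordant); when omitted, the patients present in ``pairs`` are used.
    """
    classes = (PATHOGENIC_VARIANT, AMPLIFICATION, HOMOZYGOUS_DELETION)
    counts = {k: {CONCORDANT: 0, CNB_ONLY: 0, FNA_ONLY: 0} for k in classes}
    for p in pairs:
        counts[p.alteration_class][p.direction] += 1
    n_conc = sum(v[CONCORDANT] for v in counts.values())
    n_total = sum(sum(v.values()) for v in counts.values())
    discordant_patients = {p.patient_id for p in pairs if not p.concordant}
    if patient_ids is None:
        patient_ids = sorted({p.patient_id for p in pairs})
    n_fully = len([pid for pid in patient_ids if pid not in discordant_patients])
    n_act = sum(1 for p in pairs if p.actionable)
    n_act_conc = sum(1 for p in pairs if p.actionable and p.concordant)
    per_class = {
        k: _round_pct(v[CONCORDANT], sum(v.values())) for k, v in counts.items()
    }
    return CohortReport(
        counts=counts,
        n_concordant=n_conc,
        n_total=n_total,
        pooled_pct=_round_pct(n_conc, n_total),
        n_fully_concordant_patients=n_fully,
        n_discordant_patients=len(discordant_patients),
        n_actionable=n_act,
        n_actionable_concordant=n_act_conc,
        pct_actionable=_round_pct(n_act, n_total),
        pct_actionable_concordant=_round_pct(n_act_conc, n_act),
        per_class_pct=per_class,
    )


# ---------------------------------------------------------------------------
# Correlation statistics
# ---------------------------------------------------------------------------

def af_correlation(f_cnb, f_fna) -> float:
    """Pearson correlation of arcsine-square-root transformed paired AFs."""
    a = np.asarray(f_cnb, dtype=float)
    b = np.asarray(f_fna, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired allele frequencies")
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    ta, tb = np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))
    if np.std(ta) == 0 or np.std(tb) == 0:
        logger.warning("zero variance in transformed AFs; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(ta, tb).statistic)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def overlapping_segment_values(
    profile_a: SegmentedProfile, profile_b: SegmentedProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Median log2 of both profiles over their overlapping segments.

    Overlap is taken on the shared ordered-amplicon axis: the union of both
    profiles' change-points dissects the axis into atomic intervals on
    which each profile is constant.
    """
    bounds = sorted(
        {s.start_index for s in profile_a.segments}
        | {s.end_index for s in profile_a.segments}
        | {s.start_index for s in profile_b.segments}
        | {s.end_index for s in profile_b.segments}
    )
    va, vb = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        try:
            sa = profile_a.segment_of(lo)
            sb = profile_b.segment_of(lo)
        except IndexError:
            continue
        if sa.end_index >= hi and sb.end_index >= hi:
            va.append(sa.median_log2)
            vb.append(sb.median_log2)
    return np.asarray(va), np.asarray(vb)


def cnv_pair_correlation(
    profile_pairs: dict[str, tuple[SegmentedProfile, SegmentedProfile]],
    fdr: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Per-pair Pearson correlation of overlapping segment log2 ratios.

    Pairs with fewer than ``min_overlap`` overlapping segments, or with a
    constant profile, are excluded (logged).  Two-sided p-values are
    BH-adjusted across the included pairs; ``significant`` flags adjusted
    p < ``fdr``.
    """
    rows = []
    for pid, (pa, pb) in profile_pairs.items():
        va, vb = overlapping_segment_values(pa, pb)
        if va.size < min_overlap:
            logger.info("pair %s: only %d overlapping segments; excluded",
                        pid, va.size)
            continue
        if np.std(va) == 0 or np.std(vb) == 0:
            logger.info("pair %s: constant profile; excluded", pid)
            continue
        res = stats.pearsonr(va, vb)
        rows.append({"patient_id": pid, "n_overlap": int(va.size),
                     "r": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows, columns=["patient_id", "n_overlap", "r", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < fdr
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# Nonparametric QC group comparisons
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def qc_group_tests(
    cnb_metrics: pd.DataFrame,
    fna_metrics: pd.DataFrame,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per QC metric, CNB group vs FNA group."""
    if metrics is None:
        metrics = [m for m in cnb_metrics.columns if m in fna_metrics.columns]
    rows = []
    for m in metrics:
        a = cnb_metrics[m].dropna().to_numpy()
        b = fna_metrics[m].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"metric": m, "p": float("nan"), "stars": "NA"})
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"metric": m, "p": float(res.pvalue),
                     "stars": significance_stars(float(res.pvalue))})
    return pd.DataFrame(rows)


def kruskal_dunn(values, groups) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis across strata followed by Dunn's pairwise test.

    Dunn's z uses tie-corrected rank variance; pairwise two-sided p-values
    are Bonferroni-adjusted over the k(k-1)/2 comparisons.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        return float("nan"), pd.DataFrame(
            columns=["group_a", "group_b", "z", "p", "p_adj", "stars"])
    kw_p = float(stats.kruskal(*samples).pvalue)
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: float(np.mean(ranks[groups == g])) for g in labels}
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            se = math.sqrt(var_base * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
            z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m)
            rows.append({"group_a": ga, "group_b": gb, "z": z, "p": p,
                         "p_adj": p_adj, "stars": significance_stars(p_adj)})
    return kw_p, pd.DataFrame(rows)
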