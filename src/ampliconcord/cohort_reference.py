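"""Published summary counts of the clinical validation cohort.

The pipeline was modelled on a 61-patient paired CNB/FNA profiling cohort
whose per-patient data are not publicly deposited; what *is* printed are
the validated-alteration concordance tallies, the actionability counts and
the full ledger of discordant actionable alterations.  Those printed
numbers are inputs here: the arithmetic and the pair-classification logic
can be exercised against them without any sequence data.

``build_reference_observation_pairs`` reconstructs per-sample observation
lists from the ledger so that :func:`~ampliconcord.concordance.pair_and_classify`
can reproduce the ledger's row and patient counts.  Two ledger rows print
identical statuses in both specimens although the ledger lists only
discordant findings; for those two the underlying statuses are SYNTHETIC
reconstructions (the cohort's narrative explicitly corrects patient 19 to
a heterozygous deletion in the CNB; patient 16 is encoded with the
mirrored partial-deletion reading).  They are marked in the table below.
"""

from __future__ import annotations

from .cnv_caller import AMPLIFICATION, HOMOZYGOUS_DELETION
from .concordance import AlterationObservation, PairedAlteration
from .core_io import ONCOGENE, TUMOUR_SUPPRESSOR
from .validation_engine import PATHOGENIC_VARIANT

#: Validated-alteration concordance tallies: class -> (concordant, total).
VALIDATED_TALLIES: dict[str, tuple[int, int]] = {
    PATHOGENIC_VARIANT: (69, 85),
    AMPLIFICATION: (21, 23),
    HOMOZYGOUS_DELETION: (8, 15),
}

#: Actionability: (actionable, total validated) and (concordant, actionable).
ACTIONABLE_TOTAL: tuple[int, int] = (70, 123)
ACTIONABLE_CONCORDANT: tuple[int, int] = (53, 70)

#: Ledger of discordant actionable alterations, verbatim:
#: (gene, CNB result, FNA result, patient id, tumour location, biopsy site).
DISCORDANT_ACTIONABLE_ROWS: list[tuple[str, str, str, int, str, str]] = [
    ("CDKN2A", "Homozygous deletion", "Homozygous deletion", 19, "Anal canal", "Liver"),
    ("CDKN2A/B", "Homozygous deletion", "Normal", 10, "Stomach", "Liver"),
    ("CDKN2A/B", "Homozygous deletion", "Homozygous deletion", 16, "Breast", "Lung"),
    ("EGFR", "NA", "Amplification", 43, "Cervix", "Peritoneum"),
    ("FGFR1", "Gain", "Amplification", 3, "Breast", "Lymph node"),
    ("KRAS", "Heterozygous mutation", "WT", 9, "Pancreas", "Liver"),
    ("MAP2K4", "Homozygous deletion", "Heterozygous deletion", 49, "Breast", "Liver"),
    ("MAP2K4", "Homozygous mutation", "Heterozygous mutation", 55, "Breast", "Liver"),
    ("NF1", "Heterozygous mutation", "Homozygous mutation", 19, "Anal canal", "Liver"),
    ("PIK3CA", "Absent", "Heterozygous mutation", 5, "Pancreas", "Liver"),
    ("PIK3CA", "Heterozygous mutation", "Absent", 50, "Colon", "Liver"),
    ("PIK3R1", "Homozygous deletion", "Heterozygous deletion", 2, "Ovary", "Liver"),
    ("PIK3R1", "Homozygous mutation", "Heterozygous mutation", 46, "Breast", "Liver"),
    ("PTEN", "Heterozygous mutation", "Homozygous mutation", 6, "Breast", "Subcutaneous"),
    ("PTEN", "Normal", "Homozygous deletion", 27, "Muscle", "Peritoneum"),
    ("PTEN", "Homozygous deletion", "Normal", 46, "Breast", "Liver"),
]

#: Gene roles for the ledger's genes.
REFERENCE_GENE_ROLES: dict[str, str] = {
    "CDKN2A": TUMOUR_SUPPRESSOR,
    "CDKN2A/B": TUMOUR_SUPPRESSOR,
    "EGFR": ONCOGENE,
    "FGFR1": ONCOGENE,
    "KRAS": ONCOGENE,
    "MAP2K4": TUMOUR_SUPPRESSOR,
    "NF1": TUMOUR_SUPPRESSOR,
    "PIK3CA": ONCOGENE,
    "PIK3R1": TUMOUR_SUPPRESSOR,
    "PTEN": TUMOUR_SUPPRESSOR,
}

#: SYNTHETIC status reconstructions for the two identical-status rows
#: (row index -> (cnb status, fna status)); see module docstring.
_RECONSTRUCTED_STATUSES: dict[int, tuple[str, str]] = {
    0: ("Heterozygous deletion", "Homozygous deletion"),   # patient 19, narrative
    2: ("Homozygous deletion", "Heterozygous deletion"),   # patient 16, mirrored
}

def ledger_counts() -> tuple[int, int]:
    """(number of discordant actionable alterations, distinct patients)."""
    return (len(DISCORDANT_ACTIONABLE_ROWS),
            len({row[3] for row in DISCORDANT_ACTIONABLE_ROWS}))


def _status_to_observation(gene: str, status: str) -> AlterationObservation | None:
    """Map one printed status to a gene-level observation (or absence)."""
    role = REFERENCE_GENE_ROLES[gene]
    if status in ("NA", "Normal", "WT", "Absent"):
        return None
    if status == "Homozygous deletion":
        return AlterationObservation(gene, HOMOZYGOUS_DELETION, status,
                                     validated=True, actionable=True)
    if status == "Heterozygous deletion":
        return AlterationObservation(gene, HOMOZYGOUS_DELETION, status,
                                     validated=False, actionable=True)
    if status == "Amplification":
        return AlterationObservation(gene, AMPLIFICATION, status,
                                     validated=True, actionable=True)
    if status == "Gain":
        return AlterationObservation(gene, AMPLIFICATION, status,
                                     validated=False, actionable=True)
    if status == "Homozygous mutation":
        return AlterationObservation(gene, PATHOGENIC_VARIANT, status,
                                     validated=True, actionable=True)
    if status == "Heterozygous mutation":
        # an activating oncogene mutation is validated regardless of
        # zygosity; a lone heterozygous TSG mutation is not bi-allelic
        return AlterationObservation(gene, PATHOGENIC_VARIANT, status,
                                     validated=(role == ONCOGENE),
                                     actionable=True)
    raise ValueError(f"unknown printed status: {status!r}")


def build_reference_observation_pairs() -> dict[
        int, tuple[list[AlterationObservation], list[AlterationObservation]]]:
    """Per-patient (CNB, FNA) observation lists encoding the ledger."""
    pairs: dict[int, tuple[list, list]] = {}
    for idx, (gene, cnb_status, fna_status, pid, _, _) in \
            enumerate(DISCORDANT_ACTIONABLE_ROWS):
        if idx in _RECONSTRUCTED_STATUSES:
            cnb_status, fna_status = _RECONSTRUCTED_STATUSES[idx]
        cnb_list, fna_list = pairs.setdefault(pid, ([], []))
        oc = _status_to_observation(gene, cnb_status)
        of = _status_to_observation(gene, fna_status)
        if oc is not None:
            cnb_list.append(oc)
        if of is not None:
            fna_list.append(of)
    return pairs


def pairs_from_tallies(
    tallies: dict[str, tuple[int, int]] = VALIDATED_TALLIES,
    actionable: tuple[int, int] = ACTIONABLE_TOTAL,
    actionable_concordant: tuple[int, int] = ACTIONABLE_CONCORDANT,
) -> list[PairedAlteration]:
    """Expand printed per-class tallies into a paired-alteration list.

    Produces one :class:`PairedAlteration` per counted alteration with the
    right concordance flag and actionability composition, so the cohort
    summary arithmetic can be exercised on the published counts.
    """
    status_for = {
        PATHOGENIC_VARIANT: ("Homozygous mutation", "WT"),
        AMPLIFICATION: ("Amplification", "Normal"),
        HOMOZYGOUS_DELETION: ("Homozygous deletion", "Normal"),
    }
    n_act_conc, n_act = actionable_concordant
    assert actionable[0] == n_act
    out = []
    i = 0
    act_conc_left, act_disc_left = n_act_conc, n_act - n_act_conc
    for klass, (conc, total) in tallies.items():
        present, absent = status_for[klass]
        for j in range(total):
            i += 1
            is_conc = j < conc
            if is_conc:
                actionable_flag = act_conc_left > 0
                act_conc_left -= 1 if actionable_flag else 0
            else:
                actionable_flag = act_disc_left > 0
                act_disc_left -= 1 if actionable_flag else 0
            out.append(PairedAlteration(
                patient_id=f"T{i:03d}", gene=f"G{i:03d}",
                alteration_class=klass,
                cnb_result=present,
                fna_result=present if is_conc else absent,
                concordant=is_conc,
                direction="concordant" if is_conc else "cnb_only",
                actionable=actionable_flag,
            ))
    return out
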