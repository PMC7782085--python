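"""Synthetic paired-cohort generator with known per-patient truth.

Emulates the design of a paired-biopsy profiling cohort: each patient
contributes one core needle biopsy (CNB) and one fine-needle aspirate
(FNA), both carrying the *same* patient-level somatic truth (driver
variants, amplifications, homozygous deletions) but observed through
different tumour-cell fractions — CNB cellularity centred near 52%, FNA
near 31% — and independent count/sampling noise in two library barcodes
("A"/"B") per sample.

The observation model is deliberately simple and fully stated:

* variant allele frequency:  AF = ccf x cellularity x (0.5 het / 1 hom),
  observed through binomial sampling at the simulated site depth
  (germline polymorphisms sit at 0.5 / 1.0 independent of cellularity);
* amplicon counts:  mean depth x amplicon efficiency x copy factor, with
  negative-binomial overdispersion; the copy factor for total tumour copy
  number ``cn`` at cellularity ``c`` is  (1 - c) + c x cn / 2, so a
  homozygously deleted segment retains residual signal (1 - c) from
  stromal DNA — which is exactly why deletions drop out of low-cellularity
  samples while amplifications and variants survive.

The generated knowledge base marks the planted oncogene hotspot changes
and tumour-suppressor inactivating missense changes, so the downstream
validation stage has known expected outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    Amplicon,
    KnowledgeBase,
    ONCOGENE,
    PanelManifest,
    ReadPairAlignment,
    SampleMeta,
    SamplePair,
    TUMOUR_SUPPRESSOR,
    VariantRecord,
    variant_key_str,
)
from .cnv_caller import AMPLIFICATION, HOMOZYGOUS_DELETION
from .validation_engine import PATHOGENIC_VARIANT

# canonical solid-tumour panel genes used for default manifests
_DEFAULT_GENES: list[tuple[str, str]] = [
    ("TP53", TUMOUR_SUPPRESSOR), ("PIK3CA", ONCOGENE), ("KRAS", ONCOGENE),
    ("ESR1", ONCOGENE), ("CDKN2A", TUMOUR_SUPPRESSOR), ("PTEN", TUMOUR_SUPPRESSOR),
    ("EGFR", ONCOGENE), ("FGFR1", ONCOGENE), ("MAP2K4", TUMOUR_SUPPRESSOR),
    ("PIK3R1", TUMOUR_SUPPRESSOR), ("NF1", TUMOUR_SUPPRESSOR), ("BRAF", ONCOGENE),
    ("ERBB2", ONCOGENE), ("MYC", ONCOGENE), ("CCND1", ONCOGENE),
    ("RB1", TUMOUR_SUPPRESSOR), ("BRCA1", TUMOUR_SUPPRESSOR),
    ("BRCA2", TUMOUR_SUPPRESSOR), ("SMAD4", TUMOUR_SUPPRESSOR),
    ("APC", TUMOUR_SUPPRESSOR),
]

_TUMOUR_TYPES = ["Breast", "Colon", "Pancreas", "Cervix", "Stomach", "Other"]
_TUMOUR_TYPE_P = [0.38, 0.15, 0.11, 0.07, 0.07, 0.22]
_BIOPSY_SITES = ["Liver", "Lymph node", "Subcutaneous", "Other"]
_BIOPSY_SITE_P = [0.57, 0.12, 0.12, 0.19]


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (the study conditions).

    Defaults mirror the emulated cohort: 61 patients, CNB/FNA cellularity
    means 0.52/0.31, driver/amplification/homozygous-deletion rates matching
    the validated-alteration load per patient (85/23/15 events over 61
    patients), panel scaled down to 20 genes x 200 amplicons.
    """

    n_patients: int = 61
    n_genes: int = 20
    n_amplicons: int = 200
    n_chromosomes: int = 4
    cnb_cellularity_mean: float = 0.52
    fna_cellularity_mean: float = 0.31
    cellularity_sd: float = 0.15
    min_cellularity: float = 0.10
    max_cellularity: float = 0.95
    counts_dispersion: float = 0.005
    mean_depth_per_amplicon: int = 3700
    amplicon_efficiency_sd: float = 0.5
    driver_variant_rate: float = 1.4
    passenger_variant_rate: float = 1.7
    amp_rate: float = 0.38
    homdel_rate: float = 0.25
    amp_copies: float = 30.0
    gain_copies: float = 3.0
    oncogene_driver_fraction: float = 0.55
    tsg_hom_fraction: float = 0.60
    tsg_loh_fraction: float = 0.25
    private_event_rate: float = 0.0
    actionable_gene_fraction: float = 0.57
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cnb_cellularity_mean", "fna_cellularity_mean",
                     "cellularity_sd", "min_cellularity", "max_cellularity",
                     "oncogene_driver_fraction", "tsg_hom_fraction",
                     "tsg_loh_fraction", "actionable_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_amplicons < self.n_genes:
            raise ValueError("n_amplicons must be >= n_genes")


@dataclass
class VariantTruth:
    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    zygosity: str  # heterozygous | homozygous
    ccf: float
    germline: bool = False
    protein_change: str = ""
    indel_len: int = 0
    exon_edge_distance: int = 100
    driver: bool = False


@dataclass
class CnvTruth:
    patient_id: str
    gene: str
    state: str  # homdel | hetdel | gain | amp
    copy_number: float
    driver: bool = False


@dataclass
class TruthSet:
    """Patient-level planted events; identical for both specimens of a pair."""

    variants: dict[str, list[VariantTruth]] = field(default_factory=dict)
    cnvs: dict[str, list[CnvTruth]] = field(default_factory=dict)

    def driver_events(self, patient_id: str) -> set[tuple[str, str]]:
        """(gene, alteration_class) pairs expected in the validated set."""
        out: set[tuple[str, str]] = set()
        for v in self.variants.get(patient_id, []):
            if v.driver:
                out.add((v.gene, PATHOGENIC_VARIANT))
        for c in self.cnvs.get(patient_id, []):
            if c.driver and c.state == "amp":
                out.add((c.gene, AMPLIFICATION))
            elif c.driver and c.state == "homdel":
                out.add((c.gene, HOMOZYGOUS_DELETION))
        return out


@dataclass
class CohortData:
    """Everything one simulated run produces."""

    config: SimulationConfig
    manifest: PanelManifest
    truth: TruthSet
    counts: pd.DataFrame  # rows = amplicons, cols = barcodes
    variant_tables: dict[str, dict[str, list[VariantRecord]]]  # sample -> barcode tag
    kb: KnowledgeBase
    pairs: list[SamplePair]


def build_manifest(config: SimulationConfig, rng: np.random.Generator) -> PanelManifest:
    """Evenly spaced panel: n_genes genes, equal amplicon tiling, spread
    over n_chromosomes chromosomes."""
    per_gene = config.n_amplicons // config.n_genes
    if per_gene < 1:
        raise ValueError("need at least one amplicon per gene")
    if config.n_genes <= len(_DEFAULT_GENES):
        genes = _DEFAULT_GENES[: config.n_genes]
    else:
        genes = list(_DEFAULT_GENES)
        for i in range(len(_DEFAULT_GENES), config.n_genes):
            role = ONCOGENE if i % 2 else TUMOUR_SUPPRESSOR
            genes.append((f"GENE{i:03d}", role))
    amplicons = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    for gi, (gene, _role) in enumerate(genes):
        chrom = f"chr{gi // per_chrom + 1}"
        gpos = 10_000 + (gi % per_chrom) * 10_000
        for ai in range(per_gene):
            start = gpos + ai * 200
            fwd = int(rng.integers(18, 26))
            rev = int(rng.integers(18, 26))
            amplicons.append(Amplicon(
                id=f"{gene}_amp{ai:02d}", chrom=chrom, start=start,
                end=start + 140, fwd_primer_len=fwd, rev_primer_len=rev,
                gene=gene,
            ))
    return PanelManifest(amplicons, panel_id="A")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _build_kb(genes: list[tuple[str, str]], config: SimulationConfig,
              rng: np.random.Generator) -> KnowledgeBase:
    roles = dict(genes)
    hotspots: dict[tuple[str, str], str] = {}
    inactivating: set[tuple[str, str]] = set()
    actionable: set[tuple[str, str]] = set()
    for gene, role in genes:
        if role == ONCOGENE:
            for i in range(6):
                source = "in_silico" if i >= 5 else "literature;cosmic"
                hotspots[(gene, f"p.H{i + 1}")] = source
            classes = (PATHOGENIC_VARIANT, AMPLIFICATION)
        else:
            for i in range(3):
                inactivating.add((gene, f"p.M{i + 1}"))
            classes = (PATHOGENIC_VARIANT, HOMOZYGOUS_DELETION)
        for klass in classes:
            if rng.random() < config.actionable_gene_fraction:
                actionable.add((gene, klass))
    return KnowledgeBase(gene_roles=roles, hotspots=hotspots,
                         known_inactivating_missense=inactivating,
                         actionable_rules=actionable)


def _plant_variant(rng, patient_id, gene, manifest, counter,
                   consequence, zygosity, ccf, *, protein_change="",
                   indel_len=0, exon_edge_distance=100, germline=False,
                   driver=False) -> VariantTruth:
    anchor = manifest.gene_amplicons(gene)[counter % len(manifest.gene_amplicons(gene))]
    pos = anchor.insert_start + 5 + (counter % max(anchor.insert_end
                                                  - anchor.insert_start - 10, 1))
    if indel_len > 0:
        ref, alt = "A" * (indel_len + 1), "A"
    else:
        ref, alt = "A", "T"
    return VariantTruth(
        patient_id=patient_id, gene=gene, chrom=anchor.chrom, pos=pos,
        ref=ref, alt=alt, consequence=consequence, zygosity=zygosity,
        ccf=ccf, germline=germline, protein_change=protein_change,
        indel_len=indel_len, exon_edge_distance=exon_edge_distance,
        driver=driver,
    )


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate the full paired cohort; the seed determines everything."""
    rng = np.random.default_rng(config.seed)
    manifest = build_manifest(config, rng)
    # derive (gene, role) from the manifest ordering to stay consistent
    genes: list[tuple[str, str]] = []
    seen = set()
    role_lookup = dict(_DEFAULT_GENES)
    for a in manifest:
        if a.gene not in seen:
            seen.add(a.gene)
            role = role_lookup.get(a.gene,
                                   ONCOGENE if len(seen) % 2 else TUMOUR_SUPPRESSOR)
            genes.append((a.gene, role))
    kb = _build_kb(genes, config, rng)
    oncogenes = [g for g, r in genes if r == ONCOGENE]
    tsgs = [g for g, r in genes if r == TUMOUR_SUPPRESSOR]

    truth = TruthSet()
    pairs: list[SamplePair] = []
    counts_cols: dict[str, np.ndarray] = {}
    variant_tables: dict[str, dict[str, list[VariantRecord]]] = {}

    eff = np.exp(rng.normal(-config.amplicon_efficiency_sd ** 2 / 2,
                            config.amplicon_efficiency_sd, size=len(manifest)))
    gene_of = np.array([a.gene for a in manifest])
    counter = 0

    for pi in range(config.n_patients):
        pid = f"P{pi + 1:02d}"
        used: set[str] = set()
        variants: list[VariantTruth] = []
        cnvs: list[CnvTruth] = []

        def pick(pool: list[str]) -> str | None:
            avail = [g for g in pool if g not in used]
            if not avail:
                return None
            g = avail[int(rng.integers(len(avail)))]
            used.add(g)
            return g

        for _ in range(rng.poisson(config.driver_variant_rate)):
            counter += 1
            if rng.random() < config.oncogene_driver_fraction:
                gene = pick(oncogenes)
                if gene is None:
                    continue
                if rng.random() < 0.8:
                    cons, ilen = "missense", 0
                else:
                    cons, ilen = "inframe_indel", int(rng.integers(3, 10))
                hs = int(rng.integers(6))
                zyg = "homozygous" if rng.random() < 0.15 else "heterozygous"
                variants.append(_plant_variant(
                    rng, pid, gene, manifest, counter, cons, zyg, 1.0,
                    protein_change=f"p.H{hs + 1}", indel_len=ilen, driver=True))
            else:
                gene = pick(tsgs)
                if gene is None:
                    continue
                u = rng.random()
                form = ("hom" if u < config.tsg_hom_fraction else
                        "loh" if u < config.tsg_hom_fraction + config.tsg_loh_fraction
                        else "composite")
                def tsg_cons():
                    v = rng.random()
                    if v < 0.40:
                        return "nonsense", 0, ""
                    if v < 0.70:
                        return "frameshift_indel", int(rng.integers(1, 6)), ""
                    if v < 0.85:
                        return "splice", 0, ""
                    return "missense", 0, f"p.M{int(rng.integers(3)) + 1}"
                cons, ilen, pc = tsg_cons()
                if form == "hom":
                    variants.append(_plant_variant(
                        rng, pid, gene, manifest, counter, cons, "homozygous",
                        1.0, protein_change=pc, indel_len=ilen, driver=True))
                elif form == "loh":
                    variants.append(_plant_variant(
                        rng, pid, gene, manifest, counter, cons, "heterozygous",
                        1.0, protein_change=pc, indel_len=ilen, driver=True))
                    cnvs.append(CnvTruth(pid, gene, "hetdel", 1.0, driver=False))
                else:
                    cons2, ilen2, pc2 = tsg_cons()
                    variants.append(_plant_variant(
                        rng, pid, gene, manifest, counter, cons, "heterozygous",
                        1.0, protein_change=pc, indel_len=ilen, driver=True))
                    counter += 1
                    variants.append(_plant_variant(
                        rng, pid, gene, manifest, counter, cons2, "heterozygous",
                        1.0, protein_change=pc2, indel_len=ilen2, driver=True))

        for _ in range(rng.poisson(config.amp_rate)):
            gene = pick(oncogenes)
            if gene is not None:
                cnvs.append(CnvTruth(pid, gene, "amp", config.amp_copies,
                                     driver=True))
        for _ in range(rng.poisson(config.homdel_rate)):
            gene = pick(tsgs)
            if gene is not None:
                cnvs.append(CnvTruth(pid, gene, "homdel", 0.0, driver=True))

        for _ in range(rng.poisson(config.passenger_variant_rate)):
            counter += 1
            gene = pick(oncogenes + tsgs)
            if gene is None:
                continue
            u = rng.random()
            if u < 0.6:
                variants.append(_plant_variant(
                    rng, pid, gene, manifest, counter, "missense",
                    "heterozygous", float(rng.uniform(0.3, 1.0)),
                    protein_change=f"p.V{counter}", driver=False))
            elif u < 0.8:
                edge = int(rng.integers(1, 3)) if rng.random() < 0.1 \
                    else int(rng.integers(5, 50))
                variants.append(_plant_variant(
                    rng, pid, gene, manifest, counter, "synonymous",
                    "heterozygous", float(rng.uniform(0.3, 1.0)),
                    exon_edge_distance=edge, driver=False))
            else:
                zyg = "homozygous" if rng.random() < 0.1 else "heterozygous"
                vt = _plant_variant(rng, pid, gene, manifest, counter,
                                    "missense", zyg, 1.0,
                                    protein_change=f"p.P{counter}",
                                    germline=True, driver=False)
                variants.append(vt)
                kb.population_freqs[variant_key_str(vt.chrom, vt.pos, vt.ref,
                                                    vt.alt)] = \
                    float(rng.uniform(0.002, 0.05))

        truth.variants[pid] = variants
        truth.cnvs[pid] = cnvs

        # per-specimen realization -----------------------------------------
        metas = {}
        for stype, cmean in (("CNB", config.cnb_cellularity_mean),
                             ("FNA", config.fna_cellularity_mean)):
            c = _truncated_normal(rng, cmean, config.cellularity_sd,
                                  config.min_cellularity, config.max_cellularity)
            sample_id = f"{pid}-{stype}"
            cn_state = {ev.gene: ev.copy_number for ev in cnvs}
            multiplier = np.ones(len(manifest))
            for gi, g in enumerate(gene_of):
                cn = cn_state.get(g, 2.0)
                multiplier[gi] = (1.0 - c) + c * cn / 2.0
            phi = config.counts_dispersion
            r = 1.0 / phi
            for bc_tag in ("A", "B"):
                mu = config.mean_depth_per_amplicon * eff * multiplier
                mu = np.maximum(mu, 1e-9)
                col = rng.negative_binomial(r, r / (r + mu))
                counts_cols[f"{sample_id}-{bc_tag}"] = col

            # variant observations per barcode
            tables: dict[str, list[VariantRecord]] = {}
            for bc_tag in ("A", "B"):
                recs = []
                for v in variants:
                    if v.germline:
                        af = 1.0 if v.zygosity == "homozygous" else 0.5
                    else:
                        af = v.ccf * c * (1.0 if v.zygosity == "homozygous" else 0.5)
                    depth = max(int(rng.negative_binomial(
                        r, r / (r + config.mean_depth_per_amplicon))), 1)
                    alt = int(rng.binomial(depth, min(af, 1.0)))
                    recs.append(VariantRecord(
                        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                        gene=v.gene, depth=depth, alt_reads=alt,
                        allele_freq=alt / depth, consequence=v.consequence,
                        indel_len=v.indel_len,
                        exon_edge_distance=v.exon_edge_distance,
                        protein_change=v.protein_change,
                    ))
                tables[bc_tag] = recs
            variant_tables[sample_id] = tables

            qc = {
                "tumour_pct": 100.0 * c,
                "dna_concentration": float(rng.lognormal(
                    np.log(122.0 if stype == "CNB" else 148.0) - 0.9 ** 2 / 2,
                    0.9)),
                "ratio_260_280": float(rng.normal(1.9, 0.08)),
                "ratio_260_230": float(rng.normal(2.0, 0.12)),
                "reads_total": float(max(rng.normal(
                    11.4e6 if stype == "CNB" else 11.2e6, 4.0e6), 6.5e5)),
                "mapped_pct": float(np.clip(rng.normal(
                    81.8 if stype == "CNB" else 83.5, 8.0), 5.0, 99.0)),
                "depth100_pct": float(np.clip(rng.normal(
                    93.1 if stype == "CNB" else 95.4, 4.0), 60.0, 99.0)),
            }
            metas[stype] = SampleMeta(
                sample_id=sample_id, sample_type=stype,
                tumour_cell_fraction=c,
                barcodes=[f"{sample_id}-A", f"{sample_id}-B"],
                qc_metrics=qc,
            )
        pairs.append(SamplePair(
            patient_id=pid, cnb=metas["CNB"], fna=metas["FNA"],
            tumour_type=_TUMOUR_TYPES[int(rng.choice(len(_TUMOUR_TYPES),
                                                     p=_TUMOUR_TYPE_P))],
            biopsy_site=_BIOPSY_SITES[int(rng.choice(len(_BIOPSY_SITES),
                                                     p=_BIOPSY_SITE_P))],
        ))

    counts = pd.DataFrame(counts_cols, index=manifest.ids)
    return CohortData(config=config, manifest=manifest, truth=truth,
                      counts=counts, variant_tables=variant_tables,
                      kb=kb, pairs=pairs)


def simulate_read_pairs(
    manifest: PanelManifest,
    counts: dict[str, int],
    jitter: int = 0,
    fusion_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPairAlignment]:
    """Emit read pairs at amplicon ends, with optional end jitter and
    adjacent-amplicon fusion events.

    With ``fusion_rate`` > 0 a pair matches the start of amplicon *i* and
    the end of amplicon *i+1* (same chromosome); the last amplicon of a
    chromosome fuses backwards.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    amps = manifest.amplicons
    pairs = []
    n = 0
    for i, a in enumerate(amps):
        for _ in range(counts.get(a.id, 0)):
            n += 1
            fused = rng.random() < fusion_rate
            j1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            j2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            partner = None
            if fused:
                if i + 1 < len(amps) and amps[i + 1].chrom == a.chrom:
                    partner = amps[i + 1]
                elif i > 0 and amps[i - 1].chrom == a.chrom:
                    partner = amps[i - 1]
            if partner is not None:
                start = min(a.start, partner.start) + j1
                end = max(a.end, partner.end) + j2
            else:
                start, end = a.start + j1, a.end + j2
            pairs.append(ReadPairAlignment(
                read_id=f"sim{n:07d}", chrom=a.chrom,
                r1_start=start, r2_end=max(end, start + 1),
            ))
    return pairs
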