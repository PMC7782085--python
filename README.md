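# ampliconcord

Amplicon-panel NGS analysis for paired-specimen concordance studies in
precision oncology: does a fine-needle aspirate (FNA) recover the same
clinically relevant molecular alterations as the core needle biopsy (CNB)
taken from the same lesion?

The package implements the full analysis chain of a dual-barcode amplicon
assay as a tested, reusable library:

* **amplicon assignment** — positional assignment of aligned read pairs to
  panel amplicons (±3 bp on each extremity), exclusion of fused adjacent
  amplicons, primer trimming, raw counts and run QC;
* **copy-number calling** — double-median normalization (per-barcode, then
  per-amplicon), exact least-squares segmentation of coordinate-ordered
  log2 ratios (dynamic programming, penalty per segment), and status calls
  at segment-median log2 < −1 (homozygous deletion) and > 2
  (amplification);
* **variant reporting** — the assay's inclusive thresholds (≥1 alt read,
  ≥30× depth, ≥1% allele fraction), routing of >10 bp indels, and
  dual-barcode consensus with panel-A values;
* **validation** — a deterministic, knowledge-base-driven pathogenicity
  cascade (five classes), a ≥5% allele-fraction gate, and the bi-allelic
  inactivation rules for tumour suppressors (homozygous variant, composite
  heterozygous, mutation + LOH, homozygous deletion), with a full evidence
  trace per alteration;
* **concordance** — gene-level pairing of CNB vs FNA validated alterations,
  cohort tallies, arcsin-√ Pearson correlation of allele frequencies,
  per-pair segment correlations with Benjamini–Hochberg control, and
  nonparametric QC group tests (Mann–Whitney, Kruskal–Wallis + Dunn);
* **synthetic cohort** — a fully seeded generator of paired samples with
  shared patient-level truth and sample-type-dependent tumour-cell
  fraction (CNB ≈ 52%, FNA ≈ 31%), so every stage is testable end-to-end
  against known answers without any data download.

See `docs/methods.md` for the models, defaults and their limitations.

## Worked example

Simulate a default 61-patient cohort and run the paired analysis:

```bash
ampliconcord simulate --seed 3 --out cohort/
ampliconcord concord  --seed 3 --out report/
```

which prints

```
cohort with 61 patients written to cohort
85/108 validated alterations concordant (79%)
```

`report/paired_alterations.tsv` lists each gene-level alteration with both
specimens' statuses and the concordance verdict, e.g.

```
patient_id  gene  alteration_class    cnb_result             fna_result             concordant  direction
P01         EGFR  pathogenic_variant  Heterozygous mutation  Heterozygous mutation  True        concordant
```

and `report/cohort_summary.json` holds the per-class tallies, actionability
counts and the allele-frequency correlation.  In this seeded cohort 85 of
108 validated alterations (79%) are detected in both specimens; the
discordances are dominated by homozygous deletions, whose copy-number
signal log2(1 − c) needs tumour-cell fraction c > 0.5 to cross the −1
calling threshold — the FNA samples, centred near 31% tumour cells, lose
them, while variants and high-level amplifications survive.

The same machinery is available as a library:

```python
from ampliconcord import SimulationConfig, simulate_cohort, run_pipeline

cohort = simulate_cohort(SimulationConfig(seed=3))
result = run_pipeline(cohort)
print(result.report.pooled_pct)            # 79.0
print(result.report.per_class_pct)         # per-alteration-class %
```

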