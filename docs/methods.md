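# Methods

`ampliconcord` re-implements, as a tested library, the analysis pipeline of
an amplicon-panel NGS assay used to compare tumour molecular profiles
between paired specimens: a core needle biopsy (CNB) and a fine-needle
aspirate (FNA) taken from the same lesion of the same patient.  The
scientific question the pipeline serves is whether the minimally invasive
FNA recovers the same clinically relevant alterations as the gold-standard
CNB.  This note records the models, the parameter choices, and their
limitations.

## Assay model

Each specimen is sequenced as two library barcodes ("A" and "B") of 75 bp
paired-end reads over a multiplex PCR panel (by default scaled down to 20
genes / 200 amplicons from an 87-gene / 1504-amplicon design).  Every
informative read pair starts and ends at one amplicon's primer-defined
ends, so assignment is positional: a pair is assigned to the unique
amplicon whose start and end both lie within ±3 bp of the pair's outer
aligned span.  Pairs whose two ends match different amplicons are
chimeras from the fusion of adjacent amplicons and are excluded; primers
are trimmed off before any per-base computation.  When two overlapping
amplicons both match, the tie goes to the smaller combined offset, then
manifest order (deterministic, favouring the better physical match).

## Copy-number calling

Raw per-amplicon counts are normalized in two median steps: by the median
over all amplicons within each barcode (library size), then by the median
over all barcodes within each amplicon (amplicon efficiency).  Zero
counts are replaced by a pseudocount of 0.5 before ratios are formed so a
homozygously deleted segment stays strongly negative rather than
undefined.  The two-step map is not idempotent in a single pass on
arbitrary input (the second step disturbs the first step's medians); it
has a fixed point at which both median invariants hold simultaneously,
reached after about two passes, and we state and test idempotence at that
fixed point.

The log2 ratios, ordered by genome coordinate and segmented per
chromosome, are fitted with an exact dynamic-programming minimizer of

    sum over segments of within-segment SSE  +  penalty x (number of segments)

with ties resolved toward fewer segments.  The default penalty is a
modified-BIC form `2 * sigma^2 * log(n)` with `sigma` estimated from the
median absolute successive difference (divisor 0.9539); it is exposed as
a parameter.  The DP is verified against exhaustive enumeration of all
2^(n-1) segmentations for n <= 12.

Each segment is summarised by the **median** log2 of its amplicons and
thresholded: median < -1 is a homozygous deletion and median > 2 an
amplification (both strict, the assay's published decision points);
median <= -0.41 is a heterozygous deletion and >= 0.58 a gain.  The two
intermediate cutoffs are not published for this assay; they are the ideal
single-copy-change values at 50% tumour content (log2 0.75 and log2 1.5)
and are configurable, flagged as an extrapolation.  A gene-level call
requires the same status in both barcodes (dual-barcode consensus) and
reports barcode A's value.

## Variant reporting and validation

A candidate variant is reported when three inclusive conditions hold:
alt reads >= 1, depth >= 30, allele fraction >= 1%.  Indels longer than
10 bp route to a dedicated intermediate-size indel strategy (external to
this package; only the routing is modelled).  Dual-barcode consensus
keeps variants found by both barcodes, reporting barcode A's frequency
and depth.

Validation turns reported variants and CNV calls into gene-level
pathogenic alterations via a deterministic rule cascade driven by a
pre-materialised knowledge base (gene roles, hotspot lists, known
inactivating missense changes, population frequencies, actionability
rules) — no live database queries, so runs are reproducible offline:

* population frequency > 0.1% -> Benign (polymorphism), before any other
  rule;
* oncogene: hotspot missense / in-frame indel -> Pathogenic (or Likely
  pathogenic for in-silico-only hotspots); silent/truncating -> not
  activating; other missense -> Uncertain significance;
* tumour suppressor: nonsense, frameshift, splice, intragenic large
  del/dup and known inactivating missense are inactivating (Pathogenic);
  silent changes are Likely benign unless within 2 bp of an exon edge
  (possible splice effect -> Uncertain significance);
* only Pathogenic / Likely pathogenic variants at allele fraction >= 5%
  are considered further (both classes enter the validated set by
  default; a switch restricts to Pathogenic);
* tumour suppressors require **bi-allelic** inactivation: a homozygous
  inactivating variant, two distinct heterozygous inactivating variants,
  a heterozygous inactivating variant plus a co-located deletion call
  (our operational criterion for loss of heterozygosity, which the assay
  description leaves undefined), or a homozygous deletion.

Zygosity without a matched normal is assigned by nearest expectation:
at tumour-cell fraction c, a clonal heterozygous variant is expected at
AF = 0.5c and a homozygous one at AF = c; a co-located heterozygous
deletion upgrades a het-AF variant to homozygous.  Every validated
alteration carries an ordered evidence trace of the rule ids that fired.

## Concordance and statistics

Alterations are paired across the two specimens of a patient by gene +
alteration class.  A pair is concordant when both specimens carry the
same validated alteration; a one-sided finding is a discordance
attributed to the silent side.  For tumour-suppressor mutations only
bi-allelic (homozygous) findings are validated, but a heterozygous-only
finding facing an empty partner sample is kept visible as a discordance;
an activating oncogene mutation is concordant regardless of the het/hom
label, since the alteration itself is present in both.  Printed
percentages round half-up to the nearest integer.

Cohort statistics: Pearson correlation of arcsine-square-root transformed
paired allele frequencies; per-pair Pearson correlation of overlapping
segment log2 ratios (overlap taken on the shared ordered-amplicon axis,
pairs with fewer than 3 overlapping segments or a constant profile
excluded), Benjamini-Hochberg adjusted across pairs at FDR 5%; two-sided
Mann-Whitney comparisons of CNB vs FNA QC metrics; Kruskal-Wallis with a
hand-implemented Dunn post-hoc (tie-corrected rank variance, Bonferroni
adjustment) across DNA-concentration strata, since no installed package
provides Dunn's test.

## Synthetic cohort

No patient-level data are deposited for the motivating cohort, so the
generator emulates its design with patient-level truth shared between the
two specimens of each pair: 61 patients; truncated-normal cellularity
with CNB mean 0.52 and FNA mean 0.31 (sd 0.15, floor 0.10 = the DNA
extraction eligibility rule, cap 0.95); Poisson event loads calibrated to
the cohort's validated-alteration counts (1.4 driver variants, 0.38
amplifications, 0.25 homozygous deletions per patient, plus 1.7
non-driver passengers); two barcodes per specimen as independent noise
realizations.

Observation model.  A variant's allele fraction is
`AF = ccf x c x (0.5 het / 1 hom)` observed through binomial sampling at
the site depth; germline polymorphisms sit at 0.5/1.0 independent of
cellularity.  Amplicon counts are negative-binomial
(dispersion 0.005, i.e. ~7% CV at the default mean depth of 3700 pairs
per amplicon per barcode, the cohort's per-amplicon scale) around
`depth x efficiency x [(1 - c) + c x cn/2]`, with lognormal per-amplicon
efficiencies (sdlog 0.5) shared across barcodes.  Total tumour copy
numbers are 0 (homozygous deletion), 1 (heterozygous deletion / LOH), 3
(gain) and 30 (amplification; high-level amplifications must stay above
the log2 > 2 cutoff at FNA-typical cellularity, as the cohort's 91%
amplification concordance implies).

The (1 - c) residual of homozygous deletions is the mechanism behind the
cohort's signature observation: a deletion's segment sits at
log2(1 - c), which crosses the -1 threshold exactly at c = 0.5, so
deletions drop out of low-cellularity samples (almost all FNAs) while
variants and amplifications survive.  No separate dropout parameter is
needed; deletion detectability *is* cellularity.

What the generator does not model: subclonal phylogenies and spatial
heterogeneity between the two sampling points (a private-event rate
exists as a knob, default 0, because the cohort does not quantify it);
allele-aware AF for mutation+LOH events (the exact form c/(2-c) is
replaced by the simpler 0.5c het model); sequence context, mappability
and GC effects on counts; passenger truncating mutations (passengers are
VUS missense, silents and polymorphisms only, so composite-het validation
cannot fire on a passenger/driver coincidence).  Passing tests therefore
show the *pipeline logic* is correct under a faithful abstraction of the
study design, not that the assay performs identically on real tissue.

## Problem sizes and numerical choices

The default synthetic panel is 20 genes x 200 amplicons (10 amplicons per
gene, 4 chromosomes), chosen so a full 61-patient cohort — 244 barcodes
normalized together, segmented per chromosome — runs in about one second
and a 100-cohort recovery battery in about 90 seconds.  Planted-event
recovery is evaluated in samples with cellularity >= 0.5 (below that,
homozygous deletions are undetectable by construction), pooled over
driver variants, amplifications and homozygous deletions; homozygous
deletions alone sit a few points lower because the CNB cellularity
distribution concentrates just above the c = 0.5 decision boundary, where
detection is a coin flip in each barcode and the dual-barcode consensus
squares the loss.  This boundary behaviour is intrinsic to thresholds
defined as ideal 50%-tumour values, not a tuning artefact.

Degenerate inputs: noiseless vectors give a zero estimated penalty, and
the DP's fewer-segments tie-break then returns the minimal exact
segmentation; an all-zero barcode is rejected at normalization; empty
cohorts and empty alteration lists propagate as empty-but-valid outputs
with percentage fields reported as missing.
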