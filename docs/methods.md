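# Methods

`mirmeth` implements a staged screen for microRNAs whose transcription
is silenced by proximal DNA methylation, of the kind run in colorectal
cancer cell lines by comparing a methylated parental line against an
isogenic, genetically demethylated derivative, with pharmacologic
demethylation (5-aza-2′-deoxycytidine) as orthogonal confirmation.
This note records the models, the tunable parameters, the numerical
choices, and what the synthetic data can and cannot show.

## Methylated-region calling (`mirmeth.methylome`)

MBD-pulldown sequencing enriches methylated DNA, so methylated regions
appear as read pileups over a genome-wide background.  The genome is
tiled into non-overlapping windows of `window_size` (default 500 bp,
matching the proximity scale of the screen) and each read is assigned
to exactly one window by its midpoint, with midpoints on a boundary
going to the higher-coordinate window so that counts conserve reads.

The background count per window is modelled as Poisson with rate
λ = `total_reads · window_size / genome_size`.  The significance
threshold is

    k* = min { k : P(Poisson(λ) ≥ k) < α / n_windows },

i.e. a Bonferroni-adjusted per-window level with default α = 0.01.
This is deliberately conservative: under a pure-background genome the
probability of *any* significant window is below α, which the
calibration tests verify by simulation.  Windows at or above k* are
merged into regions when separated by at most `merge_gap` bases
(default 0: book-ended windows only).  No CpG-density correction or
replicate-aware calling is attempted.

## Proximity screen (`mirmeth.proximity`)

A miRNA stem-loop is a candidate when the gap between its annotated
interval and a significant region in the reference (methylated) line is
at most 500 bp, inclusive, strand-ignored; gaps are counted in bases
strictly between half-open intervals, so book-ended features have gap
0.  Methylation in the reference line alone suffices for candidacy; the
demethylated line's profile is recorded as a retention flag and feeds
the concordance call.  Ties between equally near regions break toward
the lower start coordinate.  Distal promoters of long primary
transcripts are out of scope: methylation far upstream of the stem-loop
is invisible to this screen by design.

## Expression concordance (`mirmeth.expression`)

Expression matrices are median-scaled per sample to the grand median (a
monotone, auditable normalization recorded in the output provenance).
Each candidate is tested between cell lines with Welch's unequal-
variance t test (Welch–Satterthwaite degrees of freedom, two-sided) and
all p-values are Benjamini–Hochberg adjusted.  Concordance with the
methylation pattern is then:

- methylation **lost** in the demethylated line and fold-change
  (demethylated/reference group means, linear scale) **≥ 1.5** with a
  significant test → `consistent_upregulated`;
- methylation **retained** and fold **< 1.5** →
  `consistent_retained_silenced`;
- anything else → `inconsistent`; candidates without an expression row
  are `untested`, never dropped.

The 1.5-fold rule is the decisive gate.  The significance gate defaults
to the raw Welch p-value at 0.05; gating on the BH q-value instead is
available (`use_fdr=True`) but with triplicate designs and a
mostly-null candidate panel it is markedly conservative — at n = 3 and
CV 0.1 a true 3-fold reversal typically reaches p ≈ 10⁻³–10⁻² yet
q ≈ 0.07–0.11, halving sensitivity.  Note that Welch's test itself
under-rejects at triplicate scale (empirical size ≈ 0.034 at nominal
0.05); the suite asserts exact calibration at n = 10 and
conservativeness at n = 3.

## Drug re-expression by 2^−ΔΔCt (`mirmeth.qpcr`)

Relative expression uses the standard ΔΔCt construction: per replicate
ΔCt = Ct_target − Ct_reference (U6 for mature miRNAs, GAPDH for primary
miRNAs and host genes); ΔΔCt = mean ΔCt_treated − mean ΔCt_untreated;
fold = 2^−ΔΔCt with untreated normalized to 1.  A whole-plate Ct shift
cancels through the reference.  Significance is an unpaired, two-sided,
equal-variance Student t test on the replicate ΔCt values — the
approximately normal scale — and the re-expression call is directional
(requires fold > 1).  Replicates are treated as independent dishes.  A
target is *confirmed* when significant in the primary line and in every
validation line in which it was tested; partial confirmations are
reported separately.  Zero-variance degenerate inputs follow the
convention p = 1 for identical means, p = 0 otherwise.  No
amplification-efficiency correction is applied.

## Bisulfite clone scoring (`mirmeth.bisulfite`)

Bisulfite chemistry converts unmethylated C to T (via U) while
methylated CpG cytosines are protected.  Clones are scored against the
reference amplicon in a fixed coordinate frame (no aligner; indel
clones are out of scope): at each reference CpG, C → methylated, T →
unmethylated, anything else → ambiguous.  Ambiguous calls are excluded
from both numerator and denominator of per-CpG fractions.  Fewer than
eight clones per locus triggers a warning, not a failure.  Incomplete
conversion is *not* corrected: it surfaces as spuriously methylated
calls, matching the direct-reading presentation of clone diagrams.
Comparisons between conditions report per-CpG and mean deltas with
negative values meaning demethylation.  Only the converted top strand
is modelled.

## Genomic context and independence (`mirmeth.context`)

A stem-loop overlapping any exon is `exonic`; otherwise fully contained
in a transcript is `intronic` (host = smallest containing transcript,
all containing transcripts reported); otherwise `intergenic`.  The host
promoter is ±1000 bp around the strand-appropriate TSS, half-open; any
overlapping significant region sets the promoter-methylation flag.

The host response category is derived by comparing the cell lines in
which the host re-expressed significantly with those in which its
embedded miRNA did: nowhere → `no_change`; everywhere the miRNA
responded → `concordant_increase`; a strict subset →
`inconsistent_increase`; undetectable Ct throughout → `not_expressed`.
The independence decision table, applied only to confirmed responders:
intergenic → independent; intronic with host `no_change` or
`not_expressed` → independent; host increase of either kind →
possibly_coregulated; missing host data, and the exonic context (which
has no precedent in the screen) → indeterminate.

## Funnel orchestration (`mirmeth.funnel`)

Stages run as proximity → exclusion of already-known
methylation-regulated and imprinted-cluster miRNAs (known takes
precedence when both flags apply) → expression concordance → primary-
line re-expression → cross-line confirmation → independence.  Every
stage-1 candidate keeps a record with the stage at which it dropped
out; the report's per-stage counts must be weakly decreasing (with
exclusions accounted separately) and any inconsistency raises rather
than being corrected.  Candidates failing concordance can optionally be
routed onward (`rescue_inconsistent`, default off); when enabled, the
report's concordance-stage list includes the rescued ids so the
monotonicity invariant holds by construction.

## Synthetic world (`mirmeth.synth`)

The generator plants a complete two-cell-line study with known truth.
Defaults (all exposed in `WorldConfig`) and what they emulate:

| parameter | default | role |
|---|---|---|
| `genome_length`, `n_chroms` | 140 kb × 2 | desk-scale genome in 7 kb feature slots |
| `n_mirnas`, `n_transcripts` | 30, 12 | annotation density |
| `frac_methylated_mirnas` | 0.3 | fraction of stem-loops with a planted proximal region |
| `n_known_regulated`, `n_imprinted`, `n_coregulated` | 2, 1, 1 | funnel composition: exclusion-list members and one host-driven miRNA |
| `frac_retained_in_demethylated` | 0.75 | region-level retention in the demethylated line (most confirmed candidates retain methylation there) |
| `background_read_rate` | 0.02 reads/bp | Poisson background (λ = 10 per 500 bp window) |
| `peak_enrichment` | 8 | in-region read rate over background |
| `expression_silencing_factor` | 3.0 | re-expression fold when methylation is lost |
| `replicate_cv` | 0.1 | mean-one multiplicative lognormal replicate noise |
| `qpcr_ct_sd` | 0.1 cycles | Gaussian Ct noise |
| `aza_fold` | 4.0 | planted drug response of regulated miRNAs (and of co-regulated hosts) |
| `cpg_meth_high` / `cpg_meth_low` | 0.9 / 0.3 | per-CpG Bernoulli methylation before/after loss |
| `bisulfite_conversion_rate` | 0.99 | C→T conversion of unmethylated cytosines |
| `n_clones` | 8 | clones per locus and condition |

Geometry guarantees no placement collisions: each miRNA slot holds an
optional host transcript (TSS + first exon), the intronic stem-loop, a
500 bp window-aligned methylated region overlapping the stem-loop, and
the host's last exon; host promoters never overlap planted regions, so
host-driven regulation is planted through the qPCR layer (a concordant
host drug response), not through promoter methylation.  Reads are
fixed-length 36 bp (short-read-era single-end).  The demethylated line
keeps a retained subset of planted regions as a per-region flag, not a
genome-wide dilution.  Every stage is driven by an independent,
`crc32`-keyed substream of the seeded generator, so outputs are
byte-identical under a fixed seed.

The generator does **not** emulate realistic sequence composition,
read quality, alignment artifacts, CpG islands, probe-level array
effects, or PCR bias.  Passing recovery tests therefore demonstrates
the correctness and calibration of the pipeline's statistics and
bookkeeping under its stated noise model — not robustness to the full
messiness of real MBD-seq or array data.

With the defaults above, the planted independent set is recovered
exactly at zero noise, and with precision 1.0 / recall 0.98 over 20
seeds at default noise (the occasional miss is an expression-stage
false negative at triplicate power).

## Phenotype assays (`mirmeth.assays`)

Wound closure is (width₀ − width₁₆)/width₀, negative when the wound
widens (reported, not clipped), normalized to the mock-transfection
group mean.  BrdU incorporation is the percentage of BrdU-positive
among DAPI-stained nuclei with QC flags below 600 nuclei or 4 fields.
Transwell migration is the ratio of group to mock mean per-field
counts, flagged below 9 fields.  Group comparisons use the two-sided
pooled-variance Student t test at 0.05.  Growth/MTT curves are
summarized as per-timepoint means ± SD without curve fitting.

## Problem sizes

Tests and the acceptance script run the synthetic world at the default
280 kb genome (560 windows, ~6 000 reads per sample), 10 000-replicate
null simulations for test calibration, and a 5 Mb genome for the
Poisson goodness-of-fit check — sizes chosen so the full suite
completes in well under a minute while keeping Monte-Carlo error small
relative to the asserted bounds.

## Known limitations

- The published threshold rule for "significant methylation" defers to
  prior work; the Bonferroni–Poisson rule above is this package's own
  definition and is not guaranteed to reproduce the original counts.
- Candidacy uses the stem-loop annotation only; miRNAs regulated from
  distal primary-transcript promoters are systematically missed.
- The bisulfite scorer requires frame-exact clones; real traces need
  upstream alignment and trimming.
- Expression concordance joins mature-probe ids to stem-loop ids
  one-to-one; multi-copy mature miRNAs must be disambiguated upstream.
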