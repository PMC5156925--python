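# Methods

## Data model

`edcall` operates on per-position, per-sample, strand-resolved base-call
counts (`BaseCallProfile`) decoded from single-sample `samtools`-dialect
pileup text. Base calls below a Phred quality threshold (default 20) are
dropped at parse time; indel segments, read start/end markers, `N` calls,
deletion placeholders and reference skips are consumed without counting,
so the A/C/G/T total used by every downstream gate excludes them. Mapping
quality filtering and read-pair overlap clipping are assumed to have been
applied upstream, before pileup generation. Genomic coordinates are
1-based inclusive throughout; only BED output converts to 0-based
half-open.

The study design is two groups (control and deaminase-expressing, default
3 + 3 samples) × two aligner runs of the same libraries. The sample sheet
binds sample ids to groups per aligner; the two aligner datasets are kept
separate until the concordance gate.

## The filter cascade

Gates run in a fixed order within each aligner dataset (depth → candidate
variant → other-base contamination → dispersion → beta-binomial test with
BH adjustment → group specificity), then across datasets (concordance →
strand bias → final level); the order and each gate's decision are
recorded per site in `filter_trace`, and survivor counts per gate are
always reported. Three readings that the printed thresholds leave open are
resolved as follows and are configurable in `FilterThresholds`:

* the per-group depth floor of 9 is read as the group **mean** depth (a
  group-sum reading would be vacuous beside the per-sample ≥6 rule);
* the dispersion rule is (max−min)/mean of the six variation levels,
  with positions below 2 discarded;
* the group-specificity rule is: discard when the control-group mean
  level exceeds 0 **or** the treated-group mean is below 0.04. The
  control side is an exact-zero requirement: one variant-channel miscall
  in one control sample removes the position. This is the reading
  consistent with the output property that control levels are zero at
  every reported site, and it is the dominant determinant of the
  pipeline's sensitivity (see *Recovery characteristics*).

Thresholds are compared strictly as printed (`>0.05`, `≥0.02`); the two
comparisons whose left side is a derived float ratio (dispersion ratio,
final mean level) carry a 1e-9 guard because exactly symmetric count data
lands precisely on the boundary and bare IEEE comparison would flip the
documented inequality.

The transcribed strand is taken from read orientation when ≥90% of a
position's calls agree, else from a transcript table, else the site is
reported with unknown strand and its raw genomic variant type. Known
strands relabel the edit in transcript orientation: genomic C>T on `+`
and G>A on `−` both report as C>U.

## The beta-binomial group test

Counts are modeled per sample as beta-binomial with proportion μ and
intraclass correlation ρ (α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ; ρ→0 is the
binomial limit). The test is a likelihood-ratio test of a common μ
against group-specific μ's, with ρ shared in both hypotheses. Likelihoods
are maximized by coordinate golden-section search on (logit μ, log ρ),
vectorized across bootstrap replicates; the search floor ρ = 1e-7 is
numerically indistinguishable from binomial, and fits at the upper
boundary (ρ → 1) are clamped and flagged.

With three replicates per group the raw statistic is inflated: its null
mean is ≈1.29 rather than 1, and a plain χ²(1) reference rejects ≈7.7% at
α = 0.05. The default reference is therefore a **bootstrap Bartlett
correction**: the statistic is divided by its mean over 96 parametric
bootstrap replicates drawn from the null fitted to the observed data,
then referred to χ²(1). Because the ρ MLE collapses to the boundary for
roughly 30% of genuinely overdispersed null datasets, the bootstrap
generator uses a weakly penalized fit (add 0.2·log ρ to the
log-likelihood, a non-degeneracy penalty in the spirit of Chung et al.'s
variance-component estimator); the reported ρ estimate stays unpenalized.
Measured null rejection is 0.046 over 2,000 simulated null datasets at
μ = 0.05, ρ = 0.01, depths ≈100 (the suite asserts the exact binomial 99%
band). The correction preserves continuous p-values, which the downstream
Benjamini–Hochberg step needs; BH is applied within each aligner dataset
across all positions reaching the test.

When either group's total depth is below 50 the χ² reference is
abandoned for a direct parametric bootstrap p-value (default 2,000
replicates). Pinning ρ = 0 degrades the test to a plain binomial LRT
(uncorrected), which the suite checks against an independent
implementation. Two all-zero groups return p = 1 by convention.

## Sequence context, stem-loops, effects, Sanger

*Context.* Windows are 25 nt of transcript-sense RNA with the edited C as
the 13th nucleotide; minus-strand sites are reverse-complemented before
analysis, and T is rendered as U so DNA- and RNA-spelled inputs tally
identically. Outputs are the 5′-neighbor distribution, −2..0
trinucleotide counts, a column-stochastic position frequency matrix with
per-position information content (2 − entropy, in bits), and matching of
character-class motifs such as `[CGU]N[CU]C[AG]` over offsets −3..+1.

*Stem-loops.* Two searches over the window, both using strict
Watson–Crick reverse complement (no G·U wobble): the general flanking
search (left arm fully 5′ of the C, right arm fully 3′, arm length
3–10 nt by default, maximal arm returned; ties broken by smallest loop,
then most balanced placement — spans only, never the arm length) and the
hairpin-loop model in which the right arm starts immediately 3′ of the C
and the loop, ending at the C, has ≤7 nt. The loop model tolerates one
unpaired (bulged) nucleotide inside an arm, flagged `interrupted`, and
its arm floor is 2 nt since reported palindromes go down to that size.
The background fraction samples C-centered windows uniformly (with
replacement) from a transcriptome FASTA under a fixed seed. Both searches
are validated exactly against an independent exhaustive enumerator.

*Effects.* Transcript models are exon lists plus genomic CDS bounds.
Features follow interval arithmetic (5′UTR/CDS/3′UTR/ncRNA/intron;
"untranscribed" means within 1 kb of a transcription start or end;
otherwise intergenic). CDS sites are translated with the standard genetic
code: codon index = ⌊offset/3⌋, producing synonymous/missense/nonsense/
stop-loss and the conventional `c.C751T` / `p.R251X` strings. When several
transcripts overlap, the report prefers CDS > UTR > ncRNA > intron, then
lexicographic transcript id, and lists all overlaps; models whose spliced
CDS length is not a multiple of 3 are rejected with a warning.

*Sanger.* Editing level is minor/(major+minor) peak height. Base-calling
software only reports a minor peak at ≥5% of the major peak, so
levels below 0.05/1.05 ≈ 0.048 are unobservable: they are censored,
serialized as level 0 with a flag, and replicate means can include
(default) or exclude censored values.

## The synthetic-data generator

`simulate_dataset` emulates the study conditions with these defaults:
2,000 positions; 10% edited; true levels Beta(1.25, 8.75) scaled to
[0.04, 0.60] (mean ≈0.11, SD ≈0.06, matching the level distribution the
caller is meant to face); depth per sample ~ NB(mean 80, size 10);
per-base miscall probability 0.002 applied to the reference→variant
channel (a fixed transition map C→T, G→A, A→G, T→C), so the control-group
variant level converges to the error rate, a property the suite checks at
depth 10⁴; expected forward-read fraction 0.5; 1% of unedited positions
planted as strand-bias artifacts (treated-only variant calls drawn
entirely from one read direction — the misalignment signature the strand
gate exists to remove); and two aligner datasets produced by independent
binomial thinning (retention 0.95) of the same latent calls, which makes
the concordance gate meaningful without simulating alignment.

Two parameters the design left open were fixed once: between-treated-
sample level jitter is beta-distributed around the true level with
intraclass correlation 0.002 (visible replicate scatter without drowning
the depth-80 binomial noise), and other-base miscalls default to 0 so the
third-base contamination gate is exercised by dedicated unit fixtures
rather than by chance. Edited positions sit on alternating-strand
single-exon transcripts (blocks of 100 positions) whose table the caller
uses for strand assignment; 90% of edited windows embed the preferred
motif context and 90% a flanking inverted repeat (arm 3–6 nt, loop 3–4 nt
ending at the C) — arm embedding rewrites offsets +1..+arm and may
overwrite the +1 motif base, so the realized motif fraction is somewhat
below the nominal one. All randomness flows from one seeded generator in
a fixed draw order; identical seeds give byte-identical pileups.

What the generator does **not** emulate: alignment (reads, mapping
quality, splice junctions), germline SNPs and SNP subtraction, quality-
score/error correlation, position-dependent coverage, or real transcript
structure. Passing recovery tests therefore demonstrates that the cascade
and statistics behave as designed under the assumed noise model, not
pipeline performance on real libraries.

## Recovery characteristics

On the default conditions the cascade's sensitivity is dominated by the
exact-zero control gate: a position survives it only if no control sample
shows a single variant-channel miscall in either aligner dataset,
P ≈ ((1−0.002)⁸⁰)³ ≈ 0.62 at depth 80 — independent of the true editing
level — with further small losses where balanced-strand binomial noise
trips the strand-bias gate. Measured over seeds 1–3: sensitivity
0.57–0.69 for sites with true level ≥0.10 and depth ≥50, empirical FDR
0.000, mean absolute editing-level error 0.017–0.019. The acceptance
suite asserts sensitivity ≥0.90 alongside FDR ≤0.05 and MAE ≤0.02; the
sensitivity bound is not attainable under these study conditions and that
test is expected to fail, by the arithmetic above, while the FDR and MAE
bounds hold. At the study's own much lower coverage (group mean depth
≥9) the same gate is far milder, which is how the discovery design could
afford it.

## Problem sizes and numerics

Default problem sizes — 2,000 positions × 3 replicate seeds for recovery,
2,000 null datasets for calibration, 96 Bartlett replicates per test,
1,000 random windows against the stem-loop enumerator, 500 tables against
the Fisher oracle — were chosen so the whole suite and the acceptance
script each run in minutes on one CPU while keeping Monte-Carlo error
well inside the asserted bands. Golden-section searches use 30
iterations per coordinate and 2 coordinate rounds, matching the scalar
L-BFGS-B fits to ~1e-5 in the statistic. The Fisher test uses the
minimum-likelihood two-sided convention; BH adjustment is the standard
step-up.

## Known limitations

* No germline-variant subtraction: on real data, homozygous SNPs in the
  expressing line must be removed upstream or they will survive every
  gate except control-zero (which a DNA variant present in both groups
  does fail).
* The concordance gate requires the same variant base in both aligner
  datasets but does not model aligner-specific coverage gaps beyond
  thinning.
* The loop-model's single-bulge tolerance is a string-edit criterion,
  not a thermodynamic one; no folding energies anywhere.
* Sanger censoring assumes the fixed 5% software threshold; instruments
  differ.
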