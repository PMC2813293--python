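# Methods

## The surrogate reference

No reference sequence is bundled. `build_reference()` generates a 60 nt
5'-UTR and a 1473 nt CDS (491 codons incl. the terminal stop) from a
fixed-seed RNG subject to hard constraints, so that every catalogued variant
behaves exactly as published while all unconstrained bases are arbitrary:

- catalogue reference bases at c.-42, 385, 711, 804, 830, 936, 1125, 1297,
  1322, 1403 (b-only positions projected back through the insertion);
- codon contexts that realize the published consequences by translation
  (Q129X nonsense, R237/K268 synonymous, P277L, R433G, R441H, Q468R);
- a G immediately before the insertion point so the 6 nt insertion reads
  Gly-Lys in frame and flanking codons are untouched;
- codons 375–376 = CAA·ATG around rs4290270, so the T allele — and only the
  T allele — completes the NdeI site CA^TATG (which published material does
  not pin down; this is a package choice, configurable);
- no internal stop codons and no stray NdeI sites (re-rolled after
  constraint application).

Coordinates are HGVS-like c. positions (c.1 = A of ATG; negative = 5'-UTR).
Positions of b-only variants are stored on the TPH2b CDS, because only under
that convention do the published protein labels match ceil(c/3) exactly
(c.804 → codon 268, c.830 → codon 277, c.1403 → codon 468). The published
label "p.Q648R" for c.1403A>G is arithmetically impossible on either track
and is treated as a transposition of p.Q468R; consequences are always
derived by codon substitution and translation, never taken from label
strings. The insertion is stored only at the nucleotide level
(c.439_440insGCAAGG); its protein-level placement follows from translation.

## Synthetic clone libraries

Each clone is generated by: (1) drawing an allele of origin 50/50 from the
individual's diploid rs4290270 genotype (no allelic expression imbalance is
modeled); (2) applying the gating rule — transcripts from the blocked allele
are always TPH2a and never edited; (3) drawing the splice isoform with
probability `splice_fraction_b`; (4) drawing each in-scope editing position
independently (Bernoulli) with its stratum probability; (5) applying uniform
random substitutions at `error_rate` (default 1e-3/base, Sanger scale).
Independence across editing positions is the minimal assumption — partially
edited clones exist in the data but no dependence model is published; the
probability matrix is the hook for anything richer.

The running text and the stratified table disagree about which rs4290270
allele permits TPH2b/editing (text: T blocks nothing, A blocks; the table
labels edited strata "A"). The generator follows the text by default
(`permissive_allele="T"`), and the table-emulation scenario
(`generate_table1_libraries`) uses the table's convention so the stratum
labels match the printed rows. Nothing else differs between conventions.

Default stratum probabilities are the published ones: amygdala TPH2a-A
(0.33, 0.31, 0.33, 0.33) at n=48, TPH2b-A (0.78, 0.96, 0.96, 0.96) at n=27,
fully edited non-amygdala TPH2b at n=11, and the all-zero strata at their
printed counts. What the generator does **not** emulate: chromatogram-level
error structure, PCR/cloning bias, RNA secondary structure, per-individual
random effects on editing probabilities (available as an explicit scenario
choice, not a default). Passing round-trip tests therefore show the pipeline
is correct under substitution-type noise and the stated sampling design, not
that it is robust to every real-world artifact.

## Calling

Alignment is global with affine gaps (match +1, mismatch −1, gap open −5,
extend −1; a k-gap costs 5+(k−1); N scores 0 and never yields a call),
via Bio.Align.PairwiseAligner; an independent Gotoh dynamic program in the
test suite confirms scores on small instances. Gap placement is
canonicalized 3'-most (HGVS rule) before catalogue comparison.

Full-length dual alignment of every ~1.6 kb clone is exact but wasteful, so
the caller short-circuits the dominant case: when a clone's length equals
one isoform transcript, the optimal alignment against that transcript is
gapless and the optimal score against the other isoform differs by exactly
the canonical 6-column gap; both scores are then computed directly. This is
exact for substitution-only clones with up to 40 mismatches (a compensating
indel pair costs at least 10, more than 4 mismatches can repay). Length
mismatches, heavy corruption, and low scores fall back to the exact aligner,
with a reverse-complement retry when the forward score is below half the
maximum.

A TPH2b call requires both the higher score *and* GCAAGG in the insertion
window; the margin threshold defaults to 3 (an unambiguous single
substitution changes the margin by 2, a 6 nt indel by 10). QC passes clones
with ≤ 5 non-catalogue substitutions (≈ 4σ above the expected ~1.6 errors
per clone at the default error rate).

## Edit/SNP discrimination

A call is an RNA edit only when the genomic genotype is homozygous
reference at the site; if the observed base occurs among the genomic
alleles it is called a genomic allele — for heterozygotes this is
deliberately conservative, since editing cannot be separated from allelic
expression without phasing; anything else is discordant. Pattern indices
require the exact catalogue base change (an error producing a different
base at a catalogue position is not that edit); verified edits at the other
isoform's catalogue sites raise the exclusivity-violation flag; novel
(non-catalogue) rna_edit verdicts are reported in the sites table but never
join a pattern. Chemistry is reported sense-strand with A>G as A>I and C>T
as C>U; the default catalogue exercises all four mammalian classes (A>I,
C>U, U>C, G>A).

## Cohort statistics

The unit of replication for group comparisons is the individual
(per-individual edited fraction); pooling clone indicators across
individuals would be pseudo-replication. The published "two-tailed t-test
type 3" is read as the spreadsheet convention: two-sample, unequal variance,
i.e. Welch. No multiple-testing correction is applied across the four
editing positions by default (matching the source analysis); a Bonferroni
flag exists. HWE is the Pearson chi-square against np², 2np(1−p), n(1−p)²
with df 1; association is the Pearson chi-square on the 2×2 (AA vs rest)
or 2×3 table without continuity correction. The in-silico NdeI digest cuts
every CATATG between bases 2 and 3 and returns fragments 5'→3'.

## Kinetics

Substrate inhibition uses the Haldane single-site form
v = Vmax·S/(Km+S+S²/Ki) — no equation is named in the source; Haldane is the
standard uncompetitive-substrate-inhibition model, with velocity maximal at
S = √(Km·Ki). The inhibition constant Ki is not published; simulations use
Ki = 500 µM, chosen once so inhibition is pronounced above the physiological
Trp range (30–50 µM) while SI and MM predictions differ < 10% inside it.
Velocities are arbitrary normalized units; only Km (µM) and Vmax ratios are
interpreted.

The primary estimator is unweighted multi-start nonlinear least squares
(≥ 5 starts seeded from the Lineweaver–Burk estimate and a spread over the
substrate grid; tolerances 1e-10; best residual sum of squares wins).
1/v² weighting is available behind a flag. Degenerate data are flagged, not
guessed: saturation-only curves (Km driven to the boundary, or unbounded
standard error) set `km_not_identifiable`; curves without a descending limb
set `ki_unbounded`. Recovery simulations use an 8-point log grid spanning
10–600 µM Trp with 5% multiplicative lognormal noise (unit mean), 200
replicates, and medians rather than means, since whether published ± values
are per-experiment SEMs is ambiguous. The published BH4 value 37±69 µM is
internally odd and is used only as a generator input, never as a recovery
target.

## Problem sizes and numerical choices

Library-scale checks use 10,000 clones for the gating property and
convergence checks (3σ binomial envelopes), the printed stratum sizes
(48/17/27/8/19/11) for the frequency-table round trip, and 200 replicates
for kinetic recovery; these sizes give sampling error comfortably inside
the assertion tolerances. The gating check runs at sequencing error 0: it
isolates the generator/caller contract (rate exactly 0), which a nonzero
error rate would blur with error artifacts landing on catalogue sites
(~1.3 per 1,000 clones at default settings). All generators are
byte-reproducible under a fixed seed; seeds derived inside the tools stay
below 2³¹.

## Known limitations

- The caller handles the two catalogued isoforms only; novel splice forms
  (e.g. 3'-UTR variants) are out of scope and would surface as unclassified.
- No base-quality model: QC is a plain mismatch count.
- Heterozygous sites expressing the alt allele are never called edits
  (see above), so true editing at a heterozygous SNP would be missed.
- The association module does chi-square tests only — no odds ratios,
  covariates, or meta-analysis.
- Real cohort genotype counts and per-diagnosis editing percentages are not
  published at usable precision, so group-difference scenarios ("+20%",
  "−50%") are generator settings, not validated outputs.
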