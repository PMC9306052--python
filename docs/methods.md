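# Methods

`wgdkit` re-implements, as a tested pipeline, the comparative-genomics
workflow used to study a recent whole-genome duplication (WGD) in an
allotetraploid grass: codon-level divergence statistics, collinear-block
detection, Ks-peak dating, outgroup-guided subgenome phasing, and
homoeolog expression analysis. This note records the models, the defaults
and why they were chosen, what the synthetic fixture does and does not
emulate, and the numerical decisions that were genuinely open.

## Substitution statistics

**Ka/Ks (NG86).** Synonymous and nonsynonymous sites are counted per codon
by enumerating the three possible single-nucleotide changes at each
position; a change to a stop codon counts as nonsynonymous, so S + N = 3
per codon exactly. For a differing codon pair, synonymous and
nonsynonymous differences are averaged with equal weights over all minimal
substitution pathways, excluding pathways that pass through a stop codon
(if every pathway is blocked, the average falls back to all pathways —
the conventional resolution for this rare case). Proportions pS = Sd/S and
pN = Nd/N receive the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p),
which is undefined at p ≥ 3/4; saturation is returned as an explicit
undefined value (`None`/`NA`), never silently dropped. This estimator was
chosen over a maximum-likelihood codon model (YN00-style) because it is
exactly testable against brute-force enumeration; the cost is that it
ignores transition/transversion and codon-frequency biases, which matters
little for the Ks ranges (≤ 1) this pipeline dates. Columns containing
gaps, N, or a stop in either sequence are excluded from all counts, and
ambiguity codes are never resolved.

**4DTv.** A codon column is a fourfold-degenerate site when both codons
are gap- and N-free, their first two positions are identical, and that
two-base prefix encodes the same amino acid for every third position. The
prefix-identity requirement is stated explicitly because without it a
column can be assigned to two different degeneracy families under
amino-acid change. 4DTv is the fraction of those third positions that
differ by a transversion (purine ↔ pyrimidine). The raw proportion is the
primary statistic; an optional multiple-hit transform −0.5·ln(1 − 2·raw)
(undefined at raw ≥ 0.5) is available but off by default, since published
"4DTv distance" panels rarely state a correction and raw values keep the
axis comparable across studies. Ages are always computed from Ks, not
4DTv.

## Collinear blocks

Homology hits are filtered at E ≤ 1e-10 and the best five hits per query;
within-genome hits between genes fewer than 5 ranks apart on one
chromosome are collapsed (tandem arrays are not WGD signal). Genes get
dense rank coordinates per chromosome (sorted by start, ties by id), and
anchors are chained per chromosome pair and orientation by dynamic
programming maximizing Σ match_score + gap_penalty·(skipped ranks), with
per-axis rank gaps capped at `max_gap`. Defaults — match 50, gap −1 per
rank unit, max_gap 25, minimum 5 anchors per block — mimic MCScanX's
defaults, which is what "default parameters" means in most published
syntenies of this kind. Chains competing for anchors are resolved greedily
by descending score (then anchor count, then lexicographic chromosome
pair), and pruned chains are re-chained so every emitted block satisfies
the gap and monotonicity invariants; a validator runs on every output
block. On instances small enough to enumerate, the DP provably returns the
best single chain (tested against exhaustive subset search).

WGD-retained duplicate pairs are defined syntenically: an outgroup gene
anchored to exactly two distinct focal genes (in focal–outgroup blocks)
whose two focal genes themselves form an anchor in focal–self blocks.

## Ks distributions and dating

Ks values are filtered to [0.005, 2.0]: the lower bound removes
allelic/assembly artifacts (configurable, since genuine very recent
duplications can sit at Ks 0.02–0.03), the upper bound removes saturated
estimates. Modes are strict local maxima of a Gaussian KDE (Silverman
bandwidth by default; a fixed bandwidth is available for reproducibility)
on a 512-point grid, kept when their density reaches 5% of the global
maximum (suppresses grid noise) and merged when closer than one bandwidth.
A flat profile (max/median density < 1.5) flags the result low-confidence.
Ages follow T = Ks/(2λ) with λ = 6.5e-9 substitutions/site/year by default
(the standard average rate for grasses), always echoed in output metadata:
a Ks-0.27 mode dates to 20.8 Mya, 0.64 to 49.2 Mya, 0.48 to 36.9 Mya.
Within-genome modes are labelled WGD candidates and between-genome modes
divergence candidates; no mixture-model deconvolution is attempted.

## Subgenome phasing

The distance between two chromosomes is the mean NG86 Ks over their
single-copy syntenic ortholog pairs (undefined estimates excluded, at
least 10 genes per pair; provided pairs below that are flagged missing and
the matrix is rejected if more than 10% of provided pairs are missing).
Chromosome pairs that share no synteny have no distance at all — on any
allotetraploid-vs-outgroup comparison most of the full matrix is
necessarily empty — and the assignment step treats such entries as
effectively infinite cost.

Each outgroup chromosome is matched to its two focal partners by a global
minimum-cost assignment (Hungarian algorithm over duplicated outgroup
slots), which prevents two focal chromosomes from claiming the same
partner; within each matched pair the focal chromosome closer to the
outgroup is labelled A — the convention that subgenome A is
outgroup-proximal, overridable with a seed partition, which flips labels
but never partners or margins. The margin (distance difference) supports
each call; margins below 0.01 mark the call low-confidence rather than
failing, and when within-genome block-sharing weights are supplied, only
those low-margin pairs are re-oriented to maximize sharing with the
confident pairs. Neighbor joining (Saitou–Nei, with negative branch
lengths clamped to zero and the deficit moved to the sister branch)
provides the tree view; it is exact on additive matrices and is
cross-checked in the tests against an independent implementation.

## Expression analysis

HEB for an A/B pair is log2((A + c)/(B + c)) with pseudocount c = 0.1 FPKM,
computed per biological sample (replicate-mean FPKM per tissue ×
timepoint); a pair is untestable in a sample when neither member reaches
1 FPKM. Published analyses of this design state only the ratio thresholds
and the sign convention, so the log-ratio form, the pseudocount and the
floor are this package's explicit operationalization. Dominance uses the
2-fold rule with inclusive boundaries (ratio exactly 2 is dominant). The
headline "biased in ≥1 sample" set counts pairs dominant in at least one
sample; the direction fraction uses each pair's majority direction across
its dominant samples (ties excluded and counted separately), and an
event-level tally is also emitted because pair- and event-level fractions
genuinely differ.

DEGs follow the rule p < 0.05 and |log2FC| ≥ 1 with raw (uncorrected)
p-values, as is conventional for this rule; p-values come from Welch's
t-test on log2(FPKM + 0.1) — a deliberate substitution for read-level
count models, adequate because only the thresholded calls feed downstream
classification. The 0/1/2-DEG classification of WGD paralog pairs counts a
gene as differentially expressed if it is a DEG in any contrast (the six
tissue × timepoint comparisons are pooled). Subgenome balance is a
one-degree-of-freedom goodness-of-fit chi-square against equal
expectation; enrichment is a one-sided hypergeometric test with
Benjamini–Hochberg correction across terms.

## The synthetic allotetraploid

The generator builds an outgroup genome (10 chromosomes × 60 genes × 300
codons by default), duplicates it into subgenomes A and B, and adds a
sister focal species. Branch lengths are chosen so that d(A,B) equals the
target WGD divergence (Ks 0.27), the focal–outgroup distance centres on
0.48, and the sister species sits at 0.03 — the three peaks the real
system shows. A is constructed closer to the outgroup than B by an
asymmetry of 0.08 Ks units split across the A and B branches (the
magnitude is this package's choice; it leaves d(A,B) exact and gives
per-chromosome phasing margins ≈ 0.08, comfortably above the noise of a
60-gene mean). Twenty percent of B copies are deleted at random —
fractionation is unbiased by default, matching systems with no significant
biased fractionation; a bias knob exists for power studies.

Sequence evolution is a seeded proposal–acceptance scheme, not a matrix
exponential: substitution-event counts are Poisson with mean d·S on
synonymous sites (and ω·d·N nonsynonymous, ω = 0.2), and each event is a
uniformly proposed single-nucleotide change accepted when it has the
required effect and creates no stop. This hits target synonymous
divergence accurately (mean NG86 Ks within ~1% at d = 0.3 and ~4% at
d = 1.0 over 200 × 300-codon pairs) and is exactly reproducible; it is
intentionally approximate for Ka (no site-to-site rate variation, no
realistic amino-acid exchangeabilities). Realized event counts are
recorded per pair so estimator-recovery tests can compare against realized
rather than merely target divergence.

Gene orders stay collinear in segments of 10–25 genes whose breakpoints
are drawn once per ancestral chromosome and shared by the A and B copies
— so every planted collinear run is at least the minimum block length even
after fractionation — while inversion (10% of segments) and segment
shuffling are independent per subgenome. Homology hits cover all true
pairs plus 5% random noise hits that survive the E-value filter.

Expression: homoeolog pairs share a lognormal(3, 1) baseline FPKM so
unplanted pairs are unbiased; 10% of pairs are planted A-dominant and 15%
B-dominant (dominant member × 2^u, u ~ U[1.5, 3]); 5% of genes get a
±2-log2 DEG effect in the treated timepoints of one tissue; replicate
noise is multiplicative lognormal with CV 0.15 in a 2-tissue ×
{0,1,24,72} h × 3-replicate design. One RNG stream per channel
(sequences, orders, expression, noise hits), spawned from the master seed,
so changing expression parameters never perturbs sequences.

**What the fixture does not emulate** — and hence what passing tests do
not show about real data: indels and alignment error (all pairs align
trivially), transposable elements and tandem arrays beyond the collapse
rule, rate variation among genes and sites, biased fractionation,
count-based expression noise (mean–variance coupling of RNA-seq), batch
effects, and condition-dependent dominance. Recovery results on the
fixture demonstrate correctness of the algorithms under their stated
model, not robustness to everything real genomes do.

**Measurement conventions on the fixture.** A planted DEG effect moves one
pair member by 2 log2 units in 3 of 8 samples, which the dominance rule
rightly calls dominance there; planted-dominance *fraction* recovery is
therefore measured on pairs without planted DEG members, so the two
planted channels are not conflated. Fraction-recovery checks that need
tight tolerances (± 3 points) use a wider fixture (10 × 300 genes, 30-codon
genes — sequence length is irrelevant to expression) so that at least
2000 pairs remain after fractionation and DEG exclusion.

## Problem sizes and determinism

The default end-to-end run (simulate → Ka/Ks on ~3200 anchor pairs →
blocks → peaks → phasing → expression) takes well under a minute on one
CPU; the test suite sizes its simulations (200-pair estimator recovery,
20-replicate mode-detection study, 2000-pair expression fixture) to keep
the whole suite under a few minutes while leaving sampling error well
inside each tolerance. All randomness flows from explicit seeds; rerunning
any stage with the same seed and config reproduces byte-identical outputs
and an identical report fingerprint.

## Known limitations

- NG86 underestimates Ks slightly near saturation; values above 2 are
  excluded rather than modelled.
- KDE mode positions inherit bandwidth bias; with Silverman's rule on a
  mixture, modes can shift by a fraction of the bandwidth. The fixed-
  bandwidth override exists for sensitivity checks.
- The Welch-t DEG caller assumes approximately log-normal FPKM; it is not
  a replacement for count-based models when read counts are available.
- Phasing assumes a clean 2:1 focal:outgroup chromosome correspondence in
  strict mode; rearranged genomes fall back to nearest-outgroup labelling
  with a warning.
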