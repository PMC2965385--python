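# Methods

## Model

`mzdecay` analyses paired expression time courses from early embryos
(E1–E3) and unfertilized eggs (U1–U3). The biological premise: oocytes
stop transcribing before egg laying and zygotic transcription starts
only around 1.5–2 h after egg laying, so early abundance changes are
decay; unfertilized eggs never activate zygotic transcription, so they
expose the maternal decay machinery in isolation. Per transcript, with
maternal provision X_M (read off U1),

    embryos:            X(t) = X_M + ΔX_T(t) − ΔX_MD(t) − ΔX_ZD(t)
    unfertilized eggs:  X(t) = X_M − ΔX_MD(t)

Maternal decay is estimated from the egg series (U3 − U1, log2), net
zygotic activity from embryo-versus-egg divergence at matched times
(E3 − U3). Transcription and zygotic decay act concurrently and only
their **net** effect is observable; the classifier encodes exactly that
(the sign of the E − U divergence) and never attempts to deconvolve the
two.

## Synthetic data generator

The generator renders the model above with first-order decay kinetics.
On the linear (concentration) scale,

    X_U(t) = 2^X_M · exp(−k_m · max(0, t − t_m))
    X_E(t) = [X_U(t) + 2^X_M (2^{g·max(0, t − t_txn)/60} − 1)]
             · exp(−k_z · max(0, t − t_z))

with per-minute decay constants k_m (maternal) and k_z (zygotic) and a
transcription gain g in log2 units per hour (a pure-transcription gene
rises exactly g log2/h; mixtures stay additive in concentration).
Zygotic decay multiplies the whole pool, so with g = 0 the log2 signal
is exactly X_M − (k_m Δt_m + k_z Δt_z)·log2 e. Replicate noise is
i.i.d. Gaussian on the log2 scale, emulating variance-stabilized array
data (approximately homoscedastic in log space).

Defaults (all configurable through `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| sampling times | 45, 105, 165 min | midpoints of the 30–60 / 90–120 / 150–180 min collection windows; consecutive points 60 min apart |
| maternal onset t_m | 0 min | maternal machinery triggered by egg activation |
| zygotic onset t_z | 110 min | between the second sampling point and the reported 1.5–2 h transcription onset |
| replicates | 4 | the experimental design being emulated |
| noise SD | 0.2 log2 | plausible replicate scatter for variance-stabilized arrays; the source experiment does not report one, so it is swept in tests |
| maternal level X_M | U(8, 12) log2 | mid-range array intensities |
| detection floor | 4.0 log2 | background for non-expressed genes |
| maternal drop | U(1, 3) log2 over U1→U3 | clear effects, ≥ 1 log2 |
| zygotic drop | U(1, 2.5) log2 at E3 | idem |
| transcription gain | U(1.2, 2.5) log2/h | idem |

Nine ground-truth classes are generated: I (all rates zero), II
(k_m > 0), III (k_m > 0, g > 0), IV (k_z > 0), V (k_m, k_z > 0), purely
zygotic (X_M at the floor, g > 0), stable + transcription (g > 0 only),
not expressed (floor, all zero), and a non-classifiable complex pattern:
an early transcription burst (per-gene onset 50 min) erased by strong
zygotic decay after 110 min, which produces an embryo rise at t2
followed by a fall below the egg series at t3 — the signature the
classifier maps to its "complex/non-classified" bucket.

What the generator does **not** emulate: probe-level effects and
normalization artifacts, gene–gene correlation, heteroscedastic or
intensity-dependent noise, partial (spatially restricted) expression,
lag-phase decay onsets within a series, and any sequence dependence of
decay. Passing recovery benchmarks therefore demonstrates correctness
of the analysis pipeline under the model's own assumptions, not
performance on real arrays.

## Significance calls and classification

Change between two conditions is tested with a one-sided Welch t-test
on replicate log2 values, BH-adjusted (default FDR 10%), and flagged
only when the median difference also exceeds a minimum effect (default
0.5 log2). The exact calling procedure behind the original
classification is not recoverable from the main text, so these three
knobs are explicit configuration. When both replicate sets have zero
variance (noise-free simulations) the p-value is resolved by the sign
of the mean difference.

Evidence flags: preloaded (detected at U1), maternal decay (U3 < U1),
zygotic decay (E3 < U3), transcription (E3 > U3), transcription at t2
(E2 > U2). The decision table is in `mzdecay.classify`; contradictory
combinations (an embryo rise at t2 with a fall below eggs at t3) go to
NOT_CLASSIFIED rather than being forced into a class. Class percentages
are reported relative to the preloaded total, one decimal. Half-life
estimation routes classes II/III to U2–U3 and IV/V to E2–E3, where the
relevant machinery is visible.

The detection threshold defaults to the 5th percentile of U1 medians —
a fallback for real data with an unknown background. For simulated data
the background floor is known and the pipeline should be given an
explicit threshold (floor + 1 log2 in the benchmarks): with two of nine
classes sitting at the floor, a small-percentile rule lands inside the
floor distribution and is not meaningful.

## Kinetics

All decay quantities are log2 differences of replicate medians. The
half-life assumes exponential decay between t2 and t3 only
(k = (log2 X(t2) − log2 X(t3))·ln 2 / Δt, Δt = 60 min; t½ = ln 2 / k).
Decay curves with a lag phase make these lower-bound estimates; fitting
a lag + exponential model is deliberately not attempted with three time
points. A non-positive k yields an infinite half-life, reported as-is
and marked `censored`, never clipped. Medians (not means) feed the
formula, consistent with how replicate profiles are summarized. The
early/late partition (t2−t1, t3−t2) and the maternal/zygotic split
(U3−U1, E3−U3) are exact decompositions: components sum to the series
net change and to E3−U1 respectively by construction.

Under the default geometry the zygotic onset (110 min) lies after t2
(105 min), so E2–E3 half-lives for classes IV/V integrate only 55 of
the 60 min and are mild underestimates of the post-onset rate — the
lower-bound caveat again. Maternal half-lives from U2–U3 are exact for
first-order decay from onset 0.

## Enrichment

2×2 tables (query ∩ annotation within a fixed universe) are scored with
Fisher's exact test — two-sided by default, since both enrichments and
depletions are of interest — with odds ratio (a·d)/(b·c), infinite on a
zero denominator and zero on a zero numerator. Heatmap output uses a
Haldane–Anscombe (+0.5) corrected log2 OR so depleted cells stay
finite; the uncorrected statistics are reported alongside. BH
adjustment is applied across a whole enrichment grid at FDR 10%. The
default universe is the set of classified genes. Candidate-regulator
screens use strict thresholds: RBPs need t½ < 150 min and ≥ 5
quantified peptides; miRNAs need > 100 early reads and a strictly lower
later count.

## Motif landscapes

Genes are ranked most-decayed first and linked to their 3' UTRs. For
each word of length k and each of 40 cumulative bins (the leading
⌈i·N/40⌉ genes), the word's overlapping occurrences among the leading
sequences are scored against a hypergeometric null whose population is
the total number of unambiguous k-mer windows; the landscape is
−log10 of the upper-tail p. Windows touching ambiguous bases are
excluded from both numerator and population. Tail probabilities are
computed as exact pmf suffix sums (gammaln-based binomials), grouped by
per-word totals so words with equal totals share one tail table;
agreement with `scipy.stats.hypergeom.sf` is verified in the test suite
to ~1e-12. p-values are floored at 1e-300 before the log.

Two known sources of anticonservativeness are deliberately accepted and
matter when interpreting landscape maxima against a words-only
Bonferroni line: (i) the maximum is taken over ~40 nested bins per word
while the line corrects over words only, and (ii) occurrence-based
counting lets self-overlapping words clump within a sequence,
overdispersing counts relative to the hypergeometric null. On unplanted
uniform-random UTR sets (1,000 × 300 nt, k = 6) the landscape maximum
exceeds the words-only Bonferroni line in roughly 40% of seeds — a
multiplicity artifact, not a motif. No nucleotide-composition bias
correction is implemented; rankings of strong planted or biological
signals are unaffected (a 6-mer planted 3× in the top quartile of 200
UTRs is recovered as the top motif in 100/100 seeded runs), but
landscape peaks near the line should not be read as significant.

Seed matching declares a word of length L a match for a miRNA when it
equals the reverse complement of seed positions 2..L+1 (canonical
6/7-mer seed sites); RNA-alphabet seeds are accepted (U→T).

## Sample QC clustering

Arrays are clustered by complete linkage on 1 − Pearson r between
sample columns after median-centering each gene (deviation from the
gene's median across arrays). Without centering, shared gene-level
structure pushes every pairwise correlation towards 1. Two caveats on
synthetic data: embryo and egg samples are identical in distribution
before the zygotic onset (U1 ≡ E1, U2 ≡ E2), and correlation distance
is scale-invariant, so conditions whose centered profiles are
proportional cannot be separated either; a six-way cut is therefore
well-posed only when all six conditions carry distinguishable
signatures (as with real arrays). Zero-variance columns are excluded
with a warning.

## Benchmark problem sizes

The recovery benchmarks run at: 9 × 200 genes (4 replicates, noise 0.2)
for classifier accuracy; 3 × 100 genes for half-life recovery; every
2×2 table with universe ≤ 30 (24,615 tables) for the Fisher/enumeration
equivalence; 100 seeded runs of 200 × 200-nt UTRs for planted-motif
recovery and 20 seeded runs of 1,000 × 300-nt UTRs for null
calibration. All sizes give stable estimates while keeping a full run
in the tens of seconds on one CPU.
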