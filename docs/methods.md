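# Methods

This note documents the model, its parameters and numerical conventions,
what the synthetic data generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Classification model

Proteins are assigned to one of four nucleolar-association classes:
nucleolar-enriched, nucleolar-nucleoplasmic, nucleolar-cytoplasmic,
non-nucleolar. The declaration order of these classes is also their
precedence order, used solely to break exact ties deterministically.

Eight discrete feature channels describe each protein: four amino-acid
frequency bins (S, L, I, K), a 9-state targeting-motif bin, a
co-expression bin, a GO-dominance bin, and an interactor-proximity (NPI)
bin. Training counts, per channel × bin × class, the labelled proteins
falling in the bin, adds a pseudocount α to every cell, and divides by
the bin total regardless of class:

    P(class c | channel f in bin b) ≈ (n_fbc + α) / Σ_c' (n_fbc' + α)

Each bin row therefore sums to 1 and all entries are strictly positive;
a bin no protein occupies is exactly uniform (0.25 per class). The
pseudocount enters numerator and denominator (the denominator gains 4α) —
the one reading of "pseudocounts added to all bins" that preserves the
row normalisation.

Scoring multiplies the class prior by the protein's bin entries across
its available channels. Note these entries are per-bin class
*proportions*, a posterior-flavoured quantity, not class-conditional
likelihoods; the product-with-prior rule is implemented literally as the
method defines it rather than "corrected" to textbook naive Bayes, and
the semantics follow from that: channels shared by many classes pull all
scores together, channels dominated by one class pull strongly apart,
and the class-size imbalance is re-expressed in every channel. Scores
are accumulated in log space to avoid underflow and exponentiated for
reporting; raw products are reported without renormalisation across
classes (the reliability index is scale-invariant either way).

The label is the highest-scoring class, ties broken by precedence. The
reliability index (RI) is the top score divided by the second score;
pseudocounts keep it finite, and an exact tie gives RI = 1.

### Parameters

| parameter | default | notes |
|---|---|---|
| priors | 0.20 / 0.15 / 0.15 / 0.50 | per class, in precedence order |
| pseudocount α | 0.1 | > 0 required |
| aa bins | 5 (S, L, I), 4 (K) | thresholds configurable |
| targeting bins | 9 | fixed 3×3 grid, bin = 3·s_C + s_N |
| co-expression bins | 4 | one open question in the source material reports 5; 4 adopted, configurable |
| GO bins | 4 | dominant class or "all GOscores < 0.003" |
| NPI bins | 5 | default thresholds 0.4 / 0.8 / 1.6 / 2.4 |
| region distances D_r | 0.0 / 1.2 / 3.0 / 0.8 | nucleolus / other nuclear / cytoplasmic / bare "nuclear" |
| NoLS cutoffs | s_N = 2 if ≥ 0.9; 1 if [0.8, 0.9); else 0 | missing score → 0 |

The exact empirical amino-acid and co-expression thresholds behind the
original bins were never published. The packaged defaults were frozen
once by equal-frequency binning on the synthetic reference cohort
(preset "high", seed 42) and are plain numbers in `BinningConfig`;
any application to real data should recalibrate them on its own cohort
with `equal_frequency_thresholds` (bins within 20% of uniform occupancy
on the calibration data).

### Numerical conventions

- Bins are half-open `[t_i, t_{i+1})`; a value at a threshold goes to
  the upper bin, values at or beyond the last threshold to the last bin.
- Missing channels (no expression profile; no localisation-annotated
  interactor) are skipped at training and scoring — they contribute no
  factor — rather than occupying an extra bin. The GO channel is never
  missing: no usable terms maps to the below-threshold bin. An
  "extra-bin" treatment was considered and rejected because it would
  invent a bin count the method does not define.
- Whole-sequence identity uses a global alignment (match 1, mismatch 0,
  linear gap −1) with identity = identical columns / alignment columns;
  the two sequences are ordered canonically before aligning so the value
  is exactly symmetric even when co-optimal alignments disagree.
  Non-standard residues (X, U, B) count toward length but never as
  identical. Both the scoring and the denominator convention are
  configurable, since the 25% redundancy filter was described only as
  identity "over the entire sequence".
- Redundancy filtering is a greedy keep-first sweep in input order —
  deterministic and order-documented.
- Equal-frequency thresholds sit at k/n quantiles (linear
  interpolation); degenerate inputs (fewer distinct values than bins)
  are rejected.

## Holdout semantics

Three evidence sources are cohort-derived and would leak the query
protein into its own features: GO class counts, the co-expression
reference group, and interactor sets. Whenever a protein that belongs to
the training manifest is featurized, its own contribution is removed
from all three (self-holdout). Leave-one-out cross-validation
additionally removes the held-out protein from every *training*
protein's interactor set and from the class counts and reference group
before retraining. Proteome-wide term counts n_t are not held out: they
play the role of a fixed proteome denominator. Whether the original
analysis held the query out of its class counts was not stated;
holding out is adopted as the conservative choice, consistent with the
mandated interactor exclusion.

Evaluation reports sensitivity and PPV one-vs-rest per class; a metric
with a zero denominator is NaN, never 0, so undefined values cannot
deflate multi-run averages (which use nanmean/nanstd with the n−1
denominator). Multi-run evaluation shares the nucleolar groups and
resamples the non-nucleolar set per run with per-run seeds.

## SILAC ratio mapping

Each SILAC-measured protein carries nucleolar/cytoplasmic and
nucleoplasmic/cytoplasmic abundance ratios. Classes occupy closed,
pairwise-disjoint, axis-aligned rectangles in (log2, log2) ratio space —
the simplest shape consistent with per-axis thresholds; log2 is used
because fold-change thresholds are naturally symmetric there. The
original thresholds are not available, so regions are a calibrated
config artifact: each class gets the bounding box of its calibration
points expanded by a log2 margin (default 0.5); overlapping boxes are
shrunk to the midline of their overlap along the axis where the overlap
is smallest (the upper box's edge moved one ulp past the midline so
closed rectangles stay disjoint). Calibration fails if any calibration
point then leaves its class box — the classes are not separable by
rectangles. Calibration proteins are flagged and excluded from agreement
scoring, as are proteins whose ratios fall outside every region
("undefined").

## Annotation analyses

The ontology is a child→parent DAG (is_a edges by default; part_of
optional when reading OBO). The descendant closure of a term is the term
plus every term that reaches it — annotations with child terms roll up.
The census counts a protein toward (class, query term) when its RI
exceeds 10 (strict inequality by default, `inclusive` flag provided,
since the source material says both "greater than 10.0" and "above 10")
and at least one annotation lies in the closure; a protein counts once
per term regardless of how many closure annotations it carries.

Conservation fractions resample each class's protein set with
replacement (size preserved); the bootstrap SD is the SD of the fraction
across replicates, with the same resampled index sets shared across
organisms within a class. The default of 10,000 replicates is a
desk-scale choice whose SD estimates are stable to a few percent; the
original's 1,000,000 is reachable via `n_boot`.

## Synthetic cohorts

`nucleoclass.simulate` generates complete cohorts — FASTA, targeting
outputs, GO terms, a 79-tissue expression matrix, an interaction edge
list, localisation annotations, SILAC ratios, orthology — from a single
seeded RNG stream, byte-identical per (spec, seed). Class sizes default
to 30/22/24/200, the study's training-set sizes. Class-conditional
structure mirrors what each channel exploits:

- compositions: enriched lysine/serine-rich, nucleoplasmic serine-rich,
  nucleolar-cytoplasmic leucine/isoleucine-rich; sequence lengths
  200–800;
- targeting: secretory/TMD and mitochondrial signals concentrated in the
  non-nucleolar class; NoLS scores Beta-distributed, strongest in the
  enriched class;
- GO: disjoint per-class term pools plus a class-blind shared pool;
- expression: per-class template + independent Gaussian noise, so the
  nucleolar-cytoplasmic co-expression channel is realizable exactly as
  the method uses it;
- network: assortative edges (within-class probability 0.25 at full
  contrast vs 0.002 between);
- localisation: class-appropriate label mixes with a 10% corruption
  rate, so NPI bins are informative but imperfect and pseudocounts are
  exercised; the nucleolar-cytoplasmic class is profiled as the
  ribosomal-like group it represents (annotated nucleolus + cytosol, no
  secretory signals);
- SILAC: log-normal clusters whose centres separate every class pair on
  at least one log2 axis at full contrast (samples clipped at 2 SD so
  clusters stay rectangle-separable);
- orthology: Bernoulli per organism, with nucleolar classes conserved
  deep into the eukaryotes and the non-nucleolar class decaying with
  distance.

A `separation` preset scales every between-class contrast: high (1.0)
is the reference regime where class recovery should be nearly complete,
medium (0.85) a partial-recovery regime exercising the
reliability-index trade-off, low (0.55) a hard regime where the large
non-nucleolar class absorbs most calls. The weights were fixed by
charting LOOCV accuracy against the contrast scale during generator
design and have not been revisited.

What the generator does **not** emulate: real proteome composition or
identifier semantics, sequence homology (no shared domains or
families — the redundancy filter is exercised separately), annotation
biases that correlate across evidence sources, GO term-frequency
distributions, and the long-tailed degree distribution of real
interaction networks. Passing tests on synthetic cohorts therefore
demonstrate that the implementation recovers planted class-conditional
structure under the stated protocol — not that the method achieves any
particular accuracy on real proteomes.

## Problem sizes

The packaged analyses run at the study's own scale: 276-protein cohorts
for LOOCV (a few seconds each), ten-run averaging on a reduced
26 + 40-negative cohort, and 10,000 bootstrap replicates. The
acceptance script completes in well under a minute on one CPU.

## Known limitations

- The per-bin-proportion scoring re-expresses class imbalance in every
  channel; with a 200-protein negative class, weakly informative
  channels each multiply a systematic factor toward the majority class.
  This is faithful to the method as defined; users adding channels
  should be aware the priors are effectively compounded.
- Rectangles cannot represent non-axis-aligned SILAC class boundaries;
  calibration will correctly refuse inseparable inputs rather than
  produce overlapping regions.
- The co-expression channel is limited by construction: its top bin is
  an equal-frequency quantile of the whole cohort, so the small
  nucleolar-cytoplasmic class can never occupy it exclusively.
- `pairwise_identity` reports the identity of one optimal alignment
  (canonical argument order); among co-optimal alignments with different
  identities a different convention could differ by a few percent.
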