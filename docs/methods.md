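# Methods

This note documents the models, defaults and numerical choices behind
`cernet`, and what the synthetic validation does and does not show.

## Study design assumed

All inference operates on a three-condition design: one sensitive
parental line (`control`) and two resistant derivatives (`resistantA`,
`resistantAB`), each with ≥ 2 biological replicates (default 3), with
four RNA species (lncRNA, circRNA, miRNA, mRNA) profiled on the same
sample set. Expression values are log2 intensities assumed to be on a
common scale across samples.

Two comparison groups are tested (`AvsCtrl`, `BvsCtrl`) plus their
`merged` group: features DE in both comparisons with the same
direction. The merged group isolates candidates shared by both
resistant lines; conflicting directions are excluded, matching the
convention of reporting merged up- and down-regulated counts
separately.

## Differential expression

Per feature, an unpaired two-sample Student's t-test with pooled
variance (Welch optional via `welch=True`; at n = 3 the pooled test is
the classical default). Fold changes use the signed-ratio convention:
`+2^|lfc|` for up, `−2^|lfc|` for down, never inside (−1, 1).

Thresholds (per species, all configurable through `ThresholdPolicy`):

| species  | min \|FC\| | gated p  | α    |
|----------|-----------|----------|------|
| lncRNA   | 2.0       | BH q     | 0.05 |
| mRNA     | 2.0       | BH q     | 0.05 |
| circRNA  | 2.0       | raw t p  | 0.05 |
| miRNA    | 1.5       | BH q     | 0.05 |

BH adjustment is computed within each species × comparison family —
pooling across species would mix measurement platforms. Degenerate
t-tests (zero pooled variance) return p = 1 for equal means and p = 0
with a `degenerate` flag otherwise.

Multiplicity corrections are implemented directly from the step-up
(BH) and step-down (Holm) formulas and are verified in the test suite
against both a literal textbook re-implementation and
`statsmodels.multipletests`.

### Normalization

Quantile normalization (`quantile_normalize`) forces every sample onto
the row-wise mean of the sorted columns, with ties receiving the mean
of the reference values they span. It is exposed as a pipeline option
(`normalize: quantile`) but is **off by default**: quantile
normalization assumes the columns share a distribution up to technical
variation, which holds for full-size arrays with a small DE fraction
but demonstrably fails on small matrices where a large fraction of
features shifts in one direction (on synthetic data it collapsed a
−1.8 log2 effect to ~0). The default pipeline therefore treats its
input as already normalized, which is what the simulator emits and
what deposited, pre-processed series matrices provide.

## Co-expression networks

Edges connect DE features of two species when the sample Pearson
|r| ≥ 0.99 and the two-sided p < 0.05, with p from
t = r·√((n−2)/(1−r²)) on n−2 df; |r| = 1 maps to p = 0. Correlations
for a comparison group use the samples of its two conditions (n = 6,
df = 4); the merged group uses all samples (n = 9, df = 7). Which
samples enter the correlation is genuinely underdetermined in this
kind of study; the per-comparison choice is the default and the
sample set is an explicit argument. The |r| threshold applies to the
absolute value with the sign recorded separately, so the same
machinery serves sign-free networks (lncRNA–mRNA, circRNA–mRNA) and
the negative-only miRNA–mRNA network. Self pairs and duplicate
unordered pairs are excluded.

## miRNA target prediction

A transparent canonical-seed scanner replaces alignment/energy tools.
Site classes, scanned 5'→3' on the target:

- **8mer** (weight 4): reverse complement of seed 2–8, followed by A;
- **7mer-m8** (3): reverse complement of seed 2–8;
- **7mer-A1** (2): reverse complement of seed 2–7, followed by A;
- **6mer** (1): reverse complement of seed 2–7.

U is normalized to T internally. One binding register (keyed by its
seed-2–7 core) is reported once, at its highest class. The default
retention gate is ≥ 1 site of class ≥ 7mer-A1. No thermodynamic duplex
energy, conservation, or 3'-compensatory pairing is modeled; the
scanner is deliberately exact and fully testable, and is isolated
behind the module interface so an energy-based adapter could be
swapped in.

## ceRNA triplets

(sponge, miRNA, mRNA) with sponge ∈ {lncRNA, circRNA} is emitted iff:

1. a positive sponge–mRNA co-expression edge exists;
2. the miRNA has predicted sites in both the sponge and the mRNA;
3. miRNA–sponge and miRNA–mRNA correlations are negative and pass the
   same |r| ≥ 0.99 / α = 0.05 gates (the magnitude for the miRNA legs
   is a policy choice — the sign is the hard constraint; the default
   applies the edge rule uniformly, configurable down).

Triplets are assembled per comparison group from that group's DE sets.
A miRNA's own DE direction is recorded but not used as a gate. Output
ordering is lexical in (sponge, miRNA, mRNA).

## Cis / trans lncRNA regulation

**Cis**: same-chromosome lncRNA–gene pairs within 10 kb, classified
with the precedence *intronic* (lncRNA wholly inside a gene intron,
either strand) > *sense* (overlap, same strand) > *antisense*
(overlap, opposite strand) > *divergent* (no overlap, opposite
strands, head-to-head, TSS-to-TSS gap ≤ 1 kb) > *neighbor* (gap ≤
window). "Head-to-head" requires the upstream feature on −, the
downstream on +. Candidates are filtered by r ≥ 0.99 (positive) and
Holm-adjusted p < 0.5 across the candidate family; the permissive 0.5
is kept as the conventional default for this filter and is
configurable.

**Trans**: Smith–Waterman local alignment (match +1, mismatch −1,
linear gap −2) of the full lncRNA against the 3'UTRs of its
co-expressed mRNAs only; hits need length ≥ 20 and identity ≥ 0.9.
The DP kernel is numba-compiled; ties on the optimum resolve to the
smallest (end_a, end_b) cell with a diagonal-preferring traceback —
enumerating all optimal alignments to minimise start coordinates
instead would be exponential and changes nothing checked here. Note
the optimum maximizes score, not identity: a perfect shared segment
flanked by lucky near-matches can extend into an alignment whose
overall identity falls below the gate; the identity gate is therefore
a conservative filter.

**Promoter/TF scan**: the promoter window spans 2000 bp upstream to
500 bp downstream of the TSS — genomic [tss−2000, tss+500) on +, the
mirrored [tss−500, tss+2000) on −, reverse-complemented, clipped at
chromosome ends with a flag. (The − window mirrors interval endpoints,
so the base at the TSS itself sits one position differently than on
+; a one-base convention choice.) PWMs are count matrices converted
to probabilities with +1 pseudocount over a uniform background; the
per-position score is Σ log2(p/bg) and hits require
score ≥ 0.8 × maximum attainable, both strands scanned.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) via
the stable survival function, with k DE genes in a term of size K,
n DE genes total, background N (default: all genes on the platform).
q-values are BH within namespace (BP/CC/MF/pathway separately); terms
below the minimum size (default 2) are dropped; GO hierarchy
propagation is deliberately not modeled (terms are flat sets).

## Synthetic data: what is emulated

The generator lays out a single linear chromosome (`chrS`), places
mRNA genes, lncRNAs, circRNAs (as subsequences of host genes) and
miRNA loci without overlap except where planted, and derives all
sequences from the chromosome so annotation, FASTA and expression are
mutually consistent. Planted structure, all recorded in a truth
object:

- **DE features**: a fraction (default 0.1) of non-reserved features
  per species shifted by ±2 log2 units (the default effect) in one or
  both resistant conditions, over N(0, 0.25²) replicate noise.
- **Correlated pairs / triplets / cis pairs**: members share a latent
  condition-driven driver. The driver is the DE pattern scaled by a
  per-driver amplitude multiplier U(1.1, 1.5), plus per-sample jitter
  N(0, 0.3²) shared by the members; each member adds tiny independent
  noise N(0, 0.02²). The jitter decorrelates distinct drivers
  (cross-driver population r ≈ 0.91, so chance |r| ≥ 0.99 edges are
  ~1% of driver pairs) while within-pair r ≈ 0.9996 stays above the
  0.99 edge threshold; the amplitude multiplier keeps planted members
  safely past the FC/q gates at n = 3. These constants were set by
  variance analysis and Monte-Carlo simulation of the pooled t and
  Fisher-z tails before the recovery tests were frozen.
- **Triplets** additionally plant an exact 8mer site for the shared
  miRNA in both the sponge body and the mRNA 3'UTR (sponge↑, mRNA↑,
  miRNA↓).
- **Cis pairs** cycle through all five positional categories with
  coordinates that make the classification unambiguous.
- **Trans pairs**: each planted lncRNA–mRNA pair shares an exact
  40-nt segment with its partner's 3'UTR.
- **Motifs**: strong-consensus PWMs planted in promoter windows of
  designated lncRNAs, which are also made DE so the DE-driven TF stage
  sees them.

One master seed drives everything through fixed-offset child
generators, so identical (config, seed) gives byte-identical datasets;
a disk round-trip (TSV/GTF/FASTA/GMT/JASPAR/JSON) reproduces the
bundle exactly.

**Not emulated**: probe effects, batch/dye bias, real genome
coordinates, back-splice structure of circRNAs, miRNA biogenesis.
Passing recovery tests on this data shows the inference chain is
correct and calibrated under its own assumptions (Gaussian log-scale
noise, planted linear correlation); it does not certify performance on
real arrays, where normalization artefacts and correlated noise can
dominate.

## Problem sizes used in validation

Default scale: 300 mRNAs, 150 lncRNAs, 150 circRNAs, 60 miRNAs,
9 samples; 10 planted pairs, 8 triplets, 10 cis pairs, 3 motifs × 4
promoters. Error-control runs use a smaller pure-null configuration
over 50 seeds. These sizes give tight Monte-Carlo estimates for every
asserted bound while keeping the full suite and the acceptance script
fast on a single CPU.

## Known limitations

- Exact DE counts from any specific published study are not
  reproducible here: proprietary array summarization upstream of the
  thresholds cannot be re-run, so validation is property-based
  (recovery, error control, oracle equivalence) rather than
  count-matching.
- The seed scanner ignores binding energetics; site classes are a
  coarse ordinal proxy for affinity.
- `divergent` and `bidirectional` are treated as one category
  (head-to-head within 1 kb).
- The hash-checked rerun operates at whole-run granularity: any config
  or output change reruns all stages rather than the minimal dirty
  subset.
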