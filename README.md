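# cernet

Competing-endogenous-RNA (ceRNA) network inference from multi-species
expression profiles, with a planted-truth simulator for end-to-end
validation.

## The problem

In transcriptome studies of drug-resistant cancer cell lines, long
non-coding RNAs (lncRNAs) and circular RNAs (circRNAs) can act as
*sponges*: they carry miRNA recognition elements and compete with mRNAs
for miRNA binding, de-repressing the mRNA. Detecting such regulation
from expression data requires a chain of inferences — differential
expression, co-expression networks, miRNA target-site prediction,
sign-constrained triplet assembly — each with its own thresholds and
failure modes. `cernet` implements that chain as a tested, reusable
library plus CLI, for a three-condition design (a parental line and two
resistant derivatives, three biological replicates each) profiled for
four RNA species: lncRNA, circRNA, miRNA and mRNA.

Because every stage is threshold-driven, the package ships a
first-class synthetic-data module that generates a complete fake study
(expression, annotation, sequences, gene sets, TF motifs) with known
planted structure, so the whole chain can be validated against ground
truth without any external downloads.

## The method

For each comparison group (resistant-A vs control, resistant-AB vs
control, and their direction-consistent merge):

1. **Differential expression** — per-feature two-sample t-test on log2
   intensities; a feature is DE when |signed fold change| ≥ 2 (1.5 for
   miRNA) and the Benjamini–Hochberg q < 0.05 (raw t-test p < 0.05 for
   circRNA). The merged group keeps features DE in both comparisons
   with the same direction.
2. **Co-expression networks** — edges between DE features of two
   species with sample Pearson |r| ≥ 0.99 and p < 0.05 (two-sided, from
   t = r·√((n−2)/(1−r²))); miRNA–mRNA edges must be negative.
3. **miRNA targeting** — canonical seed matching: sites are classified
   8mer / 7mer-m8 / 7mer-A1 / 6mer by reverse-complement matches to
   miRNA seed positions 2–8 plus an optional target adenosine.
4. **ceRNA triplets** — (sponge, miRNA, mRNA) is emitted iff the
   sponge–mRNA edge is positive, the miRNA has predicted sites in both,
   and both miRNA correlations are negative and pass the |r|/α gates.
5. **lncRNA regulation** — *cis*: protein-coding genes within 10 kb,
   classified (sense / antisense / intronic / divergent / neighbor) and
   filtered by r ≥ 0.99 with Holm-adjusted p < 0.5; *trans*:
   Smith–Waterman local alignment (match +1, mismatch −1, gap −2) of
   the lncRNA against 3'UTRs of its co-expressed mRNAs (length ≥ 20,
   identity ≥ 0.9); *TF prediction*: PWM log-odds scan of the promoter
   window 2000 bp upstream to 500 bp downstream of the TSS.
6. **Enrichment** — hypergeometric upper tail P(X ≥ k) per gene set,
   BH-corrected within namespace (BP/CC/MF/pathway).

## Worked example

```python
from cernet import SimulationConfig, generate_dataset, ThresholdPolicy
from cernet import pipeline

bundle, truth = generate_dataset(SimulationConfig(seed=1))
calls = pipeline.stage_de(bundle, ThresholdPolicy())
sets = pipeline.de_sets(calls)
print({sp: len(ids) for sp, ids in sets["merged"].items()})
```

prints

```
{'mRNA': 47, 'lncRNA': 42, 'circRNA': 19, 'miRNA': 15}
```

i.e. 47 mRNAs, 42 lncRNAs, 19 circRNAs and 15 miRNAs are called DE in
*both* resistant lines with consistent direction — the candidates most
likely tied to the shared resistance phenotype. Continuing,

```python
from cernet import CorrelationRule
nets = pipeline.stage_coexpress(bundle, sets, CorrelationRule())
tmap = pipeline.stage_targets(bundle, sets, "7mer-A1")
trip = pipeline.stage_cerna(bundle, sets, nets, tmap, CorrelationRule())
print(len(trip["merged"]), "ceRNA triplets")   # -> 8 ceRNA triplets
```

recovers all 8 planted sponge–miRNA–mRNA triplets at this seed, each
satisfying all three correlation sign constraints.

Or run everything from the shell:

```bash
cernet run-all --config config.yaml --seed 1
```

with a config such as

```yaml
outdir: results/run1
seed: 1
simulate: {}          # default synthetic study; or use input_dir: <dir>
correlation: {min_abs_r: 0.99, alpha: 0.05}
cis_window: 10000
```

The results directory contains one TSV per stage (DE calls, edge lists,
target sites, triplets, cis/trans/TF tables, enrichment) plus
`manifest.json` with parameters, row counts and content hashes; reruns
with an unchanged config skip completed stages via the hash check.

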