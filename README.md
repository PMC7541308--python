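# protnet

Weighted protein co-expression network analysis for two-batch TMT
proteomics.

`protnet` reimplements, as a tested and reusable pipeline, the computational
analysis used to characterise the progranulin-deficient (*Grn*−/−) mouse
brain proteome: sample-connectivity quality control, per-protein
differential abundance (one-way ANOVA with Tukey HSD post-hoc tests and
volcano classification), weighted co-expression network construction with
module detection, module–trait correlation, cell-type and ontology
enrichment, and mapping of proteins quantified in only one TMT batch.  It is
aimed at proteomics groups running multi-batch isobaric-labelling designs
(two genotypes × two ages × n replicates, one TMT batch per age group) who
want the full analysis as a library and command-line tool rather than a
collection of scripts.

## The method

Starting from a log2 abundance matrix **X** (proteins × samples):

- **QC** — inter-sample Pearson correlation *C* gives each sample a network
  connectivity *k*ᵢ = Σ_{j≠i} *C*ᵢⱼ; samples with standardized connectivity
  |*Z*ₖ| > 3 are flagged as outliers.
- **Differential abundance** — per protein, one-way ANOVA over the four
  design cells, *F* = MSB/MSE on (k−1, N−k) df, then Tukey HSD
  *q*ᵢⱼ = |mᵢ − mⱼ| / √((MSE/2)(1/nᵢ + 1/nⱼ)) with p-values from the
  studentized range distribution.  A protein is increased on a contrast when
  p ≤ 0.05 and its log2 ratio exceeds log2(1.25) — a minimum 25% fold
  change (decreased symmetric).
- **Network** — pairwise correlation *r* → soft-threshold adjacency
  *a* = |r|^β (β = 29, unsigned) → topological overlap
  ω = (L + a) / (f(kᵢ,kⱼ) + 1 − a) with the *mean* denominator →
  average-linkage clustering of 1 − ω → dynamic hybrid tree cut
  (deepSplit 4, minimum module size 25, PAM stage) → modules merged at
  eigenprotein correlation distance 0.07 → kME-based reassignment at
  p < 0.05.  A module's **eigenprotein** is the first principal component of
  its standardized profiles; **kME** is the Pearson correlation of a protein
  with a module eigenprotein.
- **Module–trait** — biweight midcorrelation (bicor) of each eigenprotein
  with binary genotype/age traits, Student-t p-values, jointly and per age
  stratum.
- **Enrichment** — one-tailed Fisher exact (hypergeometric) overlap of
  modules with marker sets, Benjamini–Hochberg corrected; GO-Elite-style
  Z-score over-representation with finite-population correction; Cohen's
  kappa clustering of enriched terms at κ = 0.3.
- **Half-missing proteins** — proteins quantified in exactly one batch (50%
  missing by construction) never enter the network; they are mapped
  afterwards to the eigenprotein they best correlate with (bicor over their
  n = 8 cognate samples) and flagged as reduced-confidence.

Because the study's raw data are not publicly deposited, the package ships a
first-class synthetic-data generator (`protnet.simulate`) that emulates the
design — 16 samples, planted co-expressed modules with genotype/age-driven
eigenprofiles, background proteins, batch-wise missingness, and marker sets
with known module overlap — with full ground truth for recovery testing.

## Worked example

```bash
protnet simulate --seed 7 --out sim/
protnet run --matrix sim/abundance.tsv --samples sim/samples.csv \
            --markers sim/markers.gmt --out out/
```

which prints

```
simulated 440 proteins x 16 samples -> sim/
done: 400 complete proteins, 40 half-missing, 5 modules -> out/
```

The simulated dataset contains 5 planted modules of 40 proteins, 200
background proteins and 40 half-missing proteins; the pipeline detects the
5 modules from the 400 complete proteins, writes the eight result tables
(`de_results.tsv`, `module_assignments.tsv`, `eigenproteins.tsv`,
`kme.tsv`, `module_trait.tsv`, `enrichment.tsv`, `qc_report.json`,
`run_config.json`) plus a run manifest, and annotates the 40 half-missing
proteins into the detected modules.  In `module_trait.tsv` the module
matching the planted genotype-driven eigenprofile shows bicor ≈ 0.9 with
genotype, and in `enrichment.tsv` the marker set planted with 0.8 overlap
into that module attains the smallest BH-adjusted p-value.

The same analysis is available as a scikit-learn-style estimator:

```python
from protnet import CoexpressionModules, SimConfig, simulate

matrix, truth, markers = simulate(SimConfig(seed=7))
model = CoexpressionModules().fit(matrix.values[matrix.complete_index()])
model.labels_          # module label per protein (0 = unassigned)
model.eigenproteins_   # modules x samples
model.kme_             # proteins x modules
```

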