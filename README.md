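# polyapv

Differential-translation analysis of polysome-profiling experiments, built
around an ANCOVA ("analysis of partial variance") of polysome-associated on
cytosolic log2 expression with random-variance-model (RVM) empirical-Bayes
moderation. The package also provides interferon-stimulated gene (ISG)
calling on the cytosolic fraction, TOP / TOP-like 5'-motif classification of
cap-anchored sequences, gene-set overlap enrichment, polysomal-to-cytoplasmic
ratio statistics, and a seeded synthetic-data generator that emulates the
paired cytosolic/polysomal experimental design so every stage is testable
without real array data.

## Method summary

- **Translation analysis** (`translation_apv`): per gene, fit
  `P = alpha_condition + beta * C + eps` with a single common slope across the
  two contrast conditions. The condition effect (shift in adjusted means) is
  tested with an RVM-moderated F; genes are significant when the BH-adjusted
  p is at most `maxRvmPAdj` (default 0.15), the translational-activity
  difference `|dPT| = |dP - dC|` reaches `selDeltaPT` (default log2(1.5)),
  and the slope is not credibly outside `[minSlope, maxSlope] = [-1, 2]`
  (one-sided boundary t-tests at `slopeP = 0.01`).
- **RVM** (`rvm`): per-gene precisions are modelled as Gamma(a, b) so that
  `a*b*s^2 ~ F(m, 2a)`; (a, b) are fitted by maximum likelihood, variances
  are shrunk via `(m*s^2 + nu0*s0^2)/(m + nu0)` with `nu0 = 2a`,
  `s0^2 = 1/(a*b)`, and the moderated F gains `nu0` denominator df.
- **ISG calling** (`cytosolic_de`): two-sample RVM-moderated comparison on
  cytosolic values; an ISG must rise at least 1.5-fold (linear scale, closed
  bound), by default also passing the BH significance gate.
- **Motif classification** (`motif`): TOP = cytidine at position 1 followed
  by an uninterrupted run of 5–15 pyrimidines; TOP-like = a pyrimidine
  stretch of length >= 5 starting within the first 4 bases; otherwise
  non-TOP. All bounds are configurable.
- **Enrichment** (`enrichment_ratios`): exact hypergeometric overlap test
  (one-sided enrichment by default; two-sided Fisher optional) with
  `fold = (overlap/|A|)/(|B|/universe)`; the universe is always explicit.
- **Synthetic data** (`synthetic_data`): per-gene variances are drawn from
  an inverse-gamma (the exact structure the RVM assumes), condition effects
  are additive on the log2 scale, planted gene classes include
  TOP-repressed, ISG, ISG-with-TSS-switch, buffered and null genes, and
  ground truth is emitted for recovery testing.

## CLI

Every stage is a subcommand of a single entry point; all randomness flows
through one seed and reruns are byte-identical.

```sh
# end-to-end on simulated data (expression, design, TSS FASTA, truth,
# yields, per-stage tables and report.json in OUT)
polyapv run --out OUT --seed 1 [--config cfg.yaml]

# individual stages on plain files
polyapv simulate --out sim --seed 1
polyapv translation --matrix sim/expression.tsv --design sim/design.tsv \
    --contrast IFN:IFN+Torin1 --out translation.tsv
polyapv de --matrix sim/expression.tsv --design sim/design.tsv \
    --contrast control:IFN --out de.tsv --isg-out isgs.txt
polyapv motif --fasta sim/tss.fasta --out classes.tsv
polyapv enrich --set-a repressed.txt --set-b isgs.txt --universe universe.txt
polyapv ratios --table qpcr.tsv --groups IFN:IFN+Torin1
polyapv fit-rvm --table translation.tsv --df 5
```

File formats are plain text: tab-separated matrices (gene ids in the first
column, sample ids in the header), a design TSV with columns
`sample_id / fraction / condition / replicate`, standard FASTA with
`gene_id[|condition]` headers, and one-id-per-line gene sets. A YAML config
mirrors the `AnalysisSettings` fields plus the simulation layout; CLI flags
override it.

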