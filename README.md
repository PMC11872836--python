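# epireverse

Analysis toolkit for quantifying epigenetic rejuvenation in DNA-methylation
aging studies. Given a CpG × sample beta-value matrix, a sample sheet
(young / old control / old treated groups) and a CpG annotation (genomic
context, CpG-island flag, chromatin state), it provides:

- **Epigenetic clocks** (`epireverse.clock`) — elastic-net age prediction on
  beta values with an optional relative-age transform (age divided by the
  species' maximum lifespan, e.g. 122 y for humans and 3.8 y for rats), plus
  Welch group comparison of predicted DNAm age with one- and two-sided
  p-values.
- **EWAS scans** (`epireverse.ewas`) — per-CpG Pearson-correlation scans for
  the age contrast (young vs old control) and the treatment contrast (old
  control vs old treated), mapped to signed standard-normal Z statistics;
  joint classification of CpGs as rejuvenated / aggravated / age-only /
  treatment-only / null; overlap counts; CpG-level reversal correlation;
  top-hit tables.
- **Chromatin-state analysis** (`epireverse.state_analysis`) — per-state
  trimmed-mean methylation per sample, state-level age and treatment Z
  statistics, and the state-level reversal correlation with per-state
  classification (gain_reversed / loss_mitigated / concordant / neutral).
- **Context enrichment** (`epireverse.enrichment`) — TSS-distance-bin odds
  ratios with Fisher exact p-values, island vs non-island Z comparison, and
  chromatin-state hypergeometric enrichment of hits.
- **Stereology** (`epireverse.stereology`) — optical-dissector total-count
  estimator `N = RQ_sum / (ssf · asf · tsf)`.
- **Synthetic cohorts** (`epireverse.synthetic_methylome`) — a seeded
  generator producing the 6/6/8 three-group design with age-directional
  methylation drift organized by chromatin context (gains in
  bivalent/TSS/PRC2/island CpGs, losses in heterochromatin/quiescent/
  intergenic CpGs) and a treatment that reverses a tunable fraction of the
  age-affected CpGs, together with a ground-truth table. The generative
  model is linear on the logit-beta scale.
- **I/O** (`epireverse.meth_io`) — validated readers/writers for the TSV/CSV
  formats of all the above.

## CLI

```sh
epireverse simulate --n-cpgs 5000 --seed 1 --reversal-fraction 0.6 --out-dir sim/
epireverse clock train --beta sim/beta.tsv --samples sim/samples.csv --out clock.csv
epireverse clock apply --beta sim/beta.tsv --coefficients clock.csv --out pred.tsv
epireverse clock compare --predictions pred.tsv --samples sim/samples.csv
epireverse ewas --beta sim/beta.tsv --samples sim/samples.csv \
    --annotation sim/annotation.tsv --contrast age --out ewas_age.tsv
epireverse states --beta sim/beta.tsv --samples sim/samples.csv \
    --annotation sim/annotation.tsv --out-dir states/
epireverse enrich --scan ewas_age.tsv --annotation sim/annotation.tsv --out-dir enrich/
epireverse stereo --input counts.tsv --out stereo.tsv
epireverse run --seed 1 --out-dir run/          # full pipeline -> report.json
epireverse run --config cfg.yaml --seed 1 --out-dir run/
```

`epireverse run` orchestrates simulate → clock → ewas → states → enrich and
writes every stage table plus a versioned `report.json`; identical config
and seed give a byte-identical report. A YAML config can override any
threshold (`alpha`, `secondary_alpha`, `trim`, `state_z_threshold`), the
simulation design, or point `inputs:` at existing beta/sample/annotation
files to skip simulation.

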