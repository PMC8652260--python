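# crossreg

Comparative calling and cross-species analysis of super-enhancers (SEs) and
broad H3K4me3 domains (BDs) from ChIP-seq peaks and fragment intervals:

- **SE calling** — stitch enhancer peaks within 12.5 kb, rank stitched
  regions by background-normalized signal (rpm), and split the ranking at
  the slope-1 tangent ("hockey stick") cutoff into SEs and typical
  enhancers (TEs).
- **BD calling** — top 5% broadest H3K4me3 peaks, with per-bp
  input-normalized peak intensity.
- **Peak-level filters** — 50% reciprocal-overlap replicate concordance,
  top-20,000-by-signal fallback for unreplicated samples.
- **Gene association** — closest-TSS assignment, RPKM, rank-sum
  comparisons of element-associated expression.
- **Tissue specificity** — width unification (2/4/8 kb) and single-linkage
  cross-tissue grouping at matched merge distances, with paired
  signed-rank tests of SE-vs-TE (BD-vs-ND) specific fractions.
- **Conservation** — UCSC chain parsing, interval liftover with a 0.2
  minimum-match filter, three-species orthologous-overlap classification,
  and per-element conservation-score aggregation from fixedStep WIG or
  bedGraph tracks.
- **Synthetic data** — a seeded generator that emits every input the
  pipeline consumes (peaks, fragments, genes, counts, chains, score
  tracks) with planted ground-truth labels.

Coordinates are 0-based half-open (BED) throughout.

## CLI

```bash
# generate a synthetic panel (3 species x 3 tissues by default)
crossreg simulate --seed 1 --out-dir panel/

# run the full analysis on it
crossreg run --config panel/run.yaml --out-dir run/
crossreg summarize --run-dir run/

# individual stages
crossreg call-se --peaks panel/spA/tissue1.enh.peaks.bed \
    --chip panel/spA/tissue1.enh.chip.bed \
    --control panel/spA/tissue1.enh.control.bed \
    --manifest panel/manifest.tsv --out-prefix out/spA.t1
crossreg call-bd --peaks panel/spA/tissue1.prom.peaks.bed \
    --chip panel/spA/tissue1.prom.chip.bed \
    --control panel/spA/tissue1.prom.control.bed \
    --manifest panel/manifest.tsv --out-prefix out/spA.t1
crossreg specificity --panel tissues.tsv --chrom-sizes panel/spA.chrom.sizes \
    --width 2000 --distance 2000 --out spec.tsv
crossreg conserve --elements se.bed --chain a_to_b.chain --reference b.bed \
    --other c.bed --other-chain c_to_b.chain --scores a.wig --out-prefix cons
```

`crossreg run` writes `elements.tsv` (counts, median widths/signals and
associated-gene RPKM with rank-sum p-values), `specificity.tsv` +
`specificity_tests.tsv`, `conservation.tsv`, per-stage BED/TSV
intermediates under `calls/`, and a `run.log`. Every summary number is
recomputable from the shipped intermediates.

### Simulation config

`crossreg simulate --config cfg.yaml` accepts a YAML overriding any field
of `SimulationConfig` (see `src/crossreg/synthetic_data.py`): seed,
species/tissue labels, chromosome geometry, background peak counts and
widths, planted SE-cluster geometry and effect size, planted BD widths,
private/shared fractions, three-way ortholog counts, chain block/gap
geometry, expression baseline and proximity boost, and conservation-score
levels (`conserved_scores_high: false` reverses the planted direction).
The generator also writes `run.yaml`, `truth_elements.tsv` and
`truth_genes.tsv` so a full run and its evaluation need no hand-wiring.

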