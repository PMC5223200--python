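# glycolect

Lectin-microarray glycopattern analysis as a tested, reusable pipeline:
from spot-level fluorescence tables through NFI normalization, group
aggregation, differential glycan calling, and cross-disease-model
comparison, with a synthetic slide simulator providing planted ground
truth for every downstream stage.

## What it does

- **array_core** — domain types (lectin panel, spot records, group
  manifests), a built-in 37-lectin panel registry, and readers/writers for
  a minimal tab-delimited GenePix-Results-style spot-table dialect
  (columns `Slide, Block, Row, Column, Name, F532 Median, B532 Median,
  Flags`; GPR-style metadata lines are skipped tolerantly).
- **simulate** — synthetic slides with the standard replicate geometry
  (3 spots/lectin/block × 3 blocks/slide × 3 slides/group = 9
  blocks/group), multiplicative log-normal spot noise, block/slide batch
  effects, additive background, saturation, dropout, and planted
  per-lectin fold changes on raw net intensity. Because NFIs are closed
  (sum to 1 per block), a planted fold `f` on a lectin of baseline weight
  `w` yields a measurable NFI ratio `f / (1 + (f - 1) w)`;
  `expected_nfi_ratio` returns this closed form for any config.
- **quantify** — per-block NFIs: background subtraction (per-spot local or
  block-mean), floor at 0, replicate median per lectin, normalization to
  the block sum; then per-group mean ± sample SD over blocks.
- **differential** — fold-change calling (up ≥ 1.5, down ≤ 0.67,
  inclusive, configurable) with a hand-implemented pooled-variance
  Student's t-test gate (`--p-gate {lt,gt,off}`, optional Welch and
  Benjamini–Hochberg variants), cross-model shared/opposite-lectin
  comparison with any-timepoint semantics, and monosaccharide motif
  summarization (longest-match tokens: GalNAc, GlcNAc, Gal, Glc, Man,
  Fuc, Sia).
- **report / cli** — deterministic agglomerative clustering (1 − Pearson,
  average linkage by default; implemented directly, tie-broken by panel
  order), green–black–red heat maps with a plain-text sidecar of the
  plotted column-standardized values, table exports, and the `glycolect`
  CLI.
- **datasets** — published mean-NFI fold-change reference tables (an
  Alzheimer's-model contrast and a two-timepoint cerebral-ischemia-model
  contrast) bundled so that significance counts and the cross-model
  overlap can be re-derived from printed ratios.

## CLI

```sh
# full pipeline from one JSON config (simulate -> quantify -> diff -> compare -> report)
glycolect run --config examples/demo_config.json --seed 1

# or stagewise
glycolect simulate --config sim.json --out-dir spots/
glycolect quantify --spots spots/*.tsv --manifest spots/manifest.tsv \
    --out profiles.tsv --blocks-out blocks.tsv --bg-mode per-spot
glycolect diff --profiles profiles.tsv --blocks blocks.tsv \
    --contrast SAD:SAD-C --p-gate lt --out calls_sad/
glycolect compare --calls-a calls_sad/calls.tsv --calls-b calls_mcao/calls.tsv \
    --out cross.json
glycolect report --profiles profiles.tsv --calls calls_mcao/calls.tsv \
    --out-dir report/
```

`glycolect run` writes spot tables, ground truth, NFI profiles, call
tables, the cross-model JSON, a clustered heat map (+ `.tsv` sidecar),
and a `run_manifest.json` recording seed, thresholds, background mode and
p-gate. Runs are byte-for-byte reproducible under a fixed seed (images
excepted; their sidecars are covered).

## Notes

- 23 of the 37 registry lectins carry published specificity strings; the
  remaining 14 slots are clearly marked placeholders with common
  specificities (the original slide layout is not public) and the whole
  panel can be overridden with a `Name <tab> Specificity` TSV.
- Simulator noise defaults (`spot_cv 0.1`, `block_sd 0.05`,
  `slide_sd 0.05`) are artifact choices, not estimates from real data.
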