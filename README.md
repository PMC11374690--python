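# svcna

Somatic structural-variant (SV) hotspot detection and allele-specific
copy-number (CNA) state analysis for whole-genome-sequenced tumour
cohorts, with a synthetic-cohort generator so every stage can be tested
without access-controlled data.

## What it does

- **Genome layout / binning** (`svcna.genome`): chromosome layouts,
  0-based half-open intervals, non-overlapping 1-Mb bin grids with a
  callability mask.
- **CNA state layer** (`svcna.cna`): whole-genome duplication (WGD) call
  from the mean genome copy number `psi_ave` and the LOH fraction `H`
  (WGD iff `2.9 - 2H < psi_ave`), six-category CNA classification
  (HD/LOH/OLOSS/NOC/Gain/AMP, thresholds doubling under WGD),
  ploidy-normalized SegCN records clipped to [-2, 2] for recurrence
  analysis, sample-level pass/fail logic, purity/ploidy re-estimation
  from the top-CCF SNV cluster, arm-level events and fraction-LOH.
- **SV catalogue** (`svcna.catalog`): BEDPE ingestion, graph-based
  multi-caller consensus merging (400-bp breakpoint tolerance, >= 2
  callers or a single caller rescued by a CN boundary within 3 kb),
  footprint/cluster grouping, simple-SV classification and kinase-fusion
  detection. Orientation convention for records ordered `bnd1 <= bnd2`:
  `(+,-)` deletion-like, `(-,+)` duplication-like, `(+,+)` head-to-head
  inversion, `(-,-)` tail-to-tail inversion (`+` = retained fragment
  extends toward lower coordinates).
- **Complex events** (`svcna.complex_events`): chromothripsis calling
  (copy-number oscillation, >= 6 interleaved intrachromosomal junctions,
  orientation multinomial FDR > 0.2), chromoplexy calling (breakpoint
  chain over >= 3 chromosomes, >= 50% balanced-translocation footprints,
  3-30 junctions), and permutation-based per-bin complex-SV enrichment.
- **Background model** (`svcna.background`): z-scored genomic covariates
  and NB2 negative-binomial regression of per-bin breakend counts
  (Poisson fallback at the zero-dispersion boundary) producing the
  expected breakend surface `b_j`.
- **Null simulation** (`svcna.simulate`): count- and length-preserving
  re-placement of each SV with bins drawn proportional to `b_j`,
  fair-coin partner direction, whole-SV redraws on mask hits, and
  counter-based per-replicate RNG substreams.
- **Hotspot detection** (`svcna.hotspots`): exact penalized
  least-squares PCF segmentation of log10 inter-mutational distances
  (dynamic programming, numba-accelerated), per-segment enrichment
  `beta = d_obs / d_exp`, empirical FDR against simulated replicates,
  parameter grid selection, CNA-support filtering, hotspot collapsing,
  fragile-site triage (>= 3 of 6 criteria, driver exclusion) and
  candidate-gene annotation.
- **Synthetic cohorts** (`svcna.synthetic`, `svcna.fixtures`):
  covariate-driven NB breakend rates, injectable hotspot bins with a
  multiplicative excess, planted chromothripsis/chromoplexy clusters
  with truth labels, and WGD/non-WGD CN profiles.

## CLI

```sh
svcna synth --out demo --seed 1 --n-svs 2000 --n-tumours 100
svcna classify --bedpe demo/cohort.bedpe --out demo/clusters.tsv
svcna bins --chrom-sizes sizes.tsv --mask mask.bed --out bins.tsv
svcna cna --segments battenberg_like.tsv --out cna_summary.tsv
svcna run --config config.yaml            # full synthetic pipeline
```

`run` expects a YAML config (see `tests/test_pipeline_cli.py` for a demo)
and writes `hotspots.tsv`, `cluster_calls.tsv`, `cna_summary.tsv`,
`bins.tsv`, truth tables and the resolved config into the output
directory. Outputs are bitwise-deterministic for a given config and seed.

## Conventions and caveats

- Internal coordinates are 0-based half-open; 1-based inclusive segment
  TSVs (Battenberg-like) are converted on read/write.
- Footprint/cluster grouping uses distance thresholds (defaults
  `d_fp = 10 kb`, `d_cl = 1 Mb`), not a likelihood model; cluster
  membership is an approximation of published likelihood-based tools.
- OLOSS (WGD-only) is defined as `c_min >= 1`, `t_CN <= 4`, not `2+2`;
  HD as `t_CN = 0`. Both are documented interpretations.
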