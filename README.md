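# enhancerscope

Integrative ChIP-seq/RNA-seq analysis of enhancer co-occupancy, built around
the observation that the Paf1 complex (assayed through its Ctr9 subunit)
occupies active enhancers in mouse embryonic stem cells. The package covers
the desk-scale analyses of that study design:

- **Occupancy calling** — region × factor binding matrices under the 1-bp
  intersection rule, chromatin-state classification (active / poised /
  unmarked from H3K27ac and H3K4me1), Venn subset counts, and peak context
  annotation (TSS / TES / gene body / intergenic).
- **Positional statistics** — strand-aware summit-to-TSS offsets for the
  promoter-proximal factors (NELFA, RNAPII Ser5p, Ctr9) and NELFA-anchored
  nearest-Ctr9 summit distances on enhancers with a laterality call.
- **Metagene profiling** — expression-stratified scaled gene-body profiles,
  TSS-centered windows, anchor-oriented heatmap matrices, and quantile
  normalization across factors.
- **Enrichment** — per-region occupancy density, super-enhancer (SE) vs
  typical-enhancer (TE) class contrasts with Wilcoxon rank-sum p-values, and
  length-matched shuffled genomic controls.
- **Knockdown response** — median-based occupancy fold changes between
  control and knockdown coverage tracks, and per-group fractions of
  down-regulated genes after associating genes to SEs / TEs by proximity.
- **eRNA containment** — overlap of enhancer-RNA intervals with Ctr9/Ser2p
  occupancy.
- **Synthetic data generator** — a calibrated simulator that plants all of
  the above structure with known parameters, so every stage can be validated
  by recovering what was planted.
- **Pipeline + CLI** — config-driven orchestration with a checksummed output
  manifest, and `enhancerscope` subcommands for the individual stages.

All genomic coordinates are 0-based half-open (BED convention); the gene
table on disk is 1-based, converted on read.

## Worked example

Simulate a small study and run the SE-vs-TE Ctr9 enrichment contrast:

```console
$ enhancerscope simulate --profile minimal --seed 1 --outdir demo/data
$ enhancerscope enrichment --track demo/data/track_Ctr9.bedGraph \
      --enhancers demo/data/enhancers.bed
{
 "fold": 2.4473824786325227,
 "mean_SE": 4.8338614022260105,
 "mean_TE": 1.97511481937508,
 "p_value": 0.11666666666666667
}
```

The `minimal` profile has only 3 SEs and 7 TEs, so the fold estimate is noisy
and the rank-sum test is underpowered — at study scale (profile `paper2020`,
8,794 enhancers) the same contrast recovers the planted 2.7-fold enrichment
with p ≪ 1e-6.

Run every stage at once from a config:

```yaml
# demo/config.yaml
outdir: out
seed: 0
inputs:
  peaks:
    Ctr9: data/peaks_Ctr9.narrowPeak
    NELFA: data/peaks_NELFA.narrowPeak
    Ser5p: data/peaks_Ser5p.narrowPeak
    Ser2p: data/peaks_Ser2p.narrowPeak
    H3K27ac: data/peaks_H3K27ac.narrowPeak
    H3K4me1: data/peaks_H3K4me1.narrowPeak
  tracks:
    Ctr9: data/track_Ctr9.bedGraph
    Ser2p: data/track_Ser2p.bedGraph
  tracks_knockdown:
    Ser2p: data/track_Ser2p_kd.bedGraph
  genes: data/genes.tsv
  enhancers: data/enhancers.bed
  expression: data/expression.tsv
  ernas: data/ernas.bed
  genome: data/genome.json
```

```console
$ enhancerscope run --config demo/config.yaml
$ ls out
class_contrast.json  ctr9_density.tsv  enhancer_states.tsv  erna_calls.tsv
erna_summary.json    expression_contrast.json  heatmap_Ctr9.tsv  ...
$ cat out/tss_offsets.tsv
factor	n	mean	median	q25	q75
NELFA	14	18.571	17.000	16.000	20.750
Ser5p	14	39.214	40.000	35.250	42.000
Ctr9	14	183.214	182.000	181.250	185.000
$ cat out/erna_summary.json
{
 "ctr9_containment": 1.0,
 "n_erna": 2.0,
 "n_erna_ctr9": 2.0,
 "n_erna_ser2p": 2.0
}
```

Even on 14 promoters the characteristic positional ordering is visible:
NELFA sits closest to the TSS, Ser5p next, Ctr9 furthest downstream. The
manifest (`out/manifest.json`) records a sha256 per output; re-running the
same config on the same inputs reproduces it checksum-for-checksum.

## Library usage

```python
from enhancerscope import (
    default_profile, simulate, call_occupancy, factor_offset_summary,
)

ds = simulate(default_profile("paper2020"), seed=42, with_tracks=False)
matrix = call_occupancy(ds.enhancers, {"Ctr9": ds.peaks["Ctr9"]})
summary = factor_offset_summary(ds.peaks["Ctr9"], ds.genes)
print(summary.n, round(summary.mean, 2))   # 1491 184.05
```

Every planted quantity is recorded in `ds.plant_map`, so any downstream
statistic can be checked against ground truth without re-simulation.
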