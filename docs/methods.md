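# Methods

This note documents the analytical conventions, the synthetic-data model,
and the numerical choices behind `enhancerscope`. The package targets the
statistical structure of an integrative ChIP-seq/RNA-seq enhancer study in
mouse embryonic stem cells (Ctr9/Paf1C occupancy of super enhancers); since
the underlying sequencing data are not reproducible at desk scale, all
validation is by recovery of parameters planted by a calibrated simulator.

## Coordinate and format conventions

All in-memory coordinates are 0-based half-open (BED convention). Two
intervals intersect when they share a chromosome and overlap by ≥ 1 bp;
half-open adjacency (`end == start`) is not an overlap. The gene table on
disk uses 1-based TSS/TES columns (the convention of common annotation
exports) and is converted on read/write. Chromosome names are compared by
exact string match. Expression tables may be transcript-level; the reader
collapses to one representative per gene by maximum control tpm.

Coverage tracks are piecewise-constant binned signals (default bin width
10 bp). All interval queries (region mass, resampling, window extraction)
integrate the step function exactly, length-weighting partial bins, using
cached per-chromosome cumulative sums (O(1) per query after an O(n) build).
rpm normalization scales values by 1e6 / total raw mass, so a whole-genome
rpm track integrates to one million.

## Analysis stages

**Occupancy.** A region is bound by a factor when ≥ 1 peak of that factor
intersects it (1-bp rule), computed with per-chromosome interval trees and
validated against the quadratic all-pairs definition. Enhancer chromatin
states use the two histone marks alone: H3K27ac⁺ → active, H3K4me1⁺ and
H3K27ac⁻ → poised, otherwise unmarked.

**Positional.** Summit-to-TSS offsets are signed on the gene's own axis
(downstream positive; the sign flips on minus-strand genes). Peaks are
assigned to the nearest TSS by summit distance (ties toward the smaller
coordinate) and kept within a 2-kb assignment window. On enhancers, the
anchor is the strongest NELFA peak overlapping the region; the reported
distance is the unsigned gap to the nearest Ctr9 summit in the same region,
with a bilateral call when Ctr9 summits flank the anchor on both sides.

**Enrichment.** Region density is track mass divided by region length. The
SE:TE contrast reports the ratio of class means plus a two-sided Wilcoxon
rank-sum p-value over the per-region density distributions. Shuffled
controls are length-matched: one interval per input region, placed uniformly
on a uniformly chosen chromosome that can host it.

**Rank tests.** The rank-sum/Mann-Whitney p-value is exact (scipy's exact
null distribution) when the pooled sample is tie-free and n₁+n₂ ≤ 50;
otherwise the normal approximation with tie-corrected variance is used,
without continuity correction, so that a perfectly balanced U gives p = 1.
Full permutation enumeration is only feasible for tiny samples — C(50, 25)
≈ 1.3e14 splits — so it is kept as an independent test oracle
(`exact_enumeration_p`) rather than a production path; the exact-path p
equals the enumeration p whenever both are defined (two-sided distance
measured as |U − n₁n₂/2| on a symmetric null).

**Metagene.** Gene bodies are rescaled to 60 bins by length-weighted
averaging, which conserves body mass up to float rounding; flanks keep fixed
bp width (2 kb / 20 bins). Minus-strand genes are profiled on their 5'→3'
axis. Anchored heatmaps center on NELFA summits and are oriented so the
nearest Ctr9 summit lies to the right. Quantile normalization maps each
matrix's values onto the mean order-statistic distribution via average ranks
and linear interpolation — a monotone map, so within-row rank order is
preserved.

**Knockdown.** Occupancy fold change is the ratio of per-class medians of
region read counts (rpm × bp) between control and knockdown tracks —
median-based to be robust to the skewed per-region mass distribution.
Expression response keeps genes with control tpm ≥ 1 (boundary inclusive),
computes log2(kd/ctrl) with ε = 0 (a zero knockdown tpm yields a logged
−inf sentinel rather than a silent pseudocount), assigns genes to SE / TE /
other by nearest enhancer within 100 kb (TSS-to-edge distance, SE wins
ties; the assignment rule is a declared operationalization — the source
study does not state one), and reports the percentage with log2fc < 0.

**Prediction.** Candidate active enhancers are H3K27ac peaks that overlap at
least one Ctr9 peak and do not touch any TSS ± 1 kb window (removing
active-promoter H3K27ac); survivors are merged.

## Synthetic data model

The generator (`synthetic_data`) plants every quantity the stages measure.
Calibration lives in one dataclass (`CalibrationProfile`); the `paper2020`
profile encodes the study-scale magnitudes: 231 SEs (10 kb) and 8,563 TEs
(1 kb); promoter summit offsets 21 / 39 / 184 bp (sd 5) for NELFA / Ser5p /
Ctr9; NELFA–Ctr9 enhancer distances 465 bp on SEs and 163 bp on TEs (sd 50);
Ctr9 on 72% of SEs and 7% of TEs; H3K4me1/H3K27ac on 90%/88% of SEs and
83%/31% of TEs; a 2.7-fold SE:TE Ctr9 density ratio; knockdown
down-regulation of 73.5 / 63.8 / 53.7% of SE / TE / other genes; and Ser2p
knockdown occupancy divisors 1.5 (SE) and 1.3 (TE). A `minimal` profile
(2 chromosomes, 10 enhancers, 20 genes) serves unit tests.

**Layout.** Block-based: each enhancer occupies its own block, optionally
followed (3.5–8 kb downstream) by its target gene; blocks are separated by
40-kb spacers so each gene's nearest enhancer is provably its own, and
enhancer-free genes live on a dedicated chromosome. This makes the planted
gene→enhancer association exactly recoverable by the distance rule.

**Exact-count planting.** Wherever the calibration specifies a population
fraction (occupancy rates, down-regulation fractions, bilateral fraction),
membership is drawn as a uniformly random subset of exactly round(n·p)
elements rather than independent Bernoulli trials. The planted fraction is
then a recoverable constant and only the member identities are random —
which is what lets, e.g., the 72% SE occupancy come back as exactly 166/231.
Containment constraints are enforced by construction: Ser2p and eRNAs occur
only on Ctr9-bound enhancers, and every eRNA-positive enhancer is also
Ser2p-positive (transcribing enhancers carry the elongation mark).

**Tracks.** Coverage is built from triangular kernels (half-width 150 bp) at
each planted summit, plus a uniform Ser2p gene-body floor on expressed genes
and per-bin Poisson noise (rate 0.05). The SE Ctr9 kernel height is solved
analytically so the expected SE:TE mean-density ratio equals the planted
2.7, accounting for class occupancy rates, the expected number of kernels
per bound region (1 + P(NELFA) × bilateral fraction), and the Poisson noise
floor (the per-bp noise density equals the Poisson rate, since bin values
are depths). The knockdown Ser2p track divides enhancer-overlapping bins by
the class divisor and leaves everything else unchanged, so the median-based
fold estimator recovers the divisor.

**Expression.** Control tpm is drawn from stratum-specific uniform ranges
(silent/low/medium/high). Among genes passing the expressed filter, the
exact-count down-regulated subset per association group receives a negative
log2 effect (|N(1.0, 0.4)|, floored at 0.05 so no planted effect is exactly
zero); the rest receive a positive effect. Knockdown tpm is
ctrl × 2^effect.

**Determinism.** One `numpy.random.default_rng(seed)` drives the whole
simulation; a fixed (profile, seed) reproduces every array bit-for-bit. The
plant map records all planted per-gene and per-enhancer truths, so any
statistic can be recomputed without re-simulation.

**Realism limits.** The generator is a statistical emulator, not a
sequencing simulator: no read-level noise, mappability, GC bias, replicate
structure, or peak-calling uncertainty; peaks are planted directly rather
than called from coverage; enhancer and gene spacing is regular rather than
drawn from a genome annotation. Conclusions about the analysis code
transfer; conclusions about biology do not.

## Open questions resolved by declared convention

- Gene→enhancer assignment ("SE target genes") — nearest enhancer within
  100 kb by TSS-to-edge distance, SE preferred on ties.
- "Decreased" expression — log2fc < 0, with no magnitude threshold.
- The TE-class NELFA–Ctr9 distance is calibrated to the 163-bp
  promoter-context value, the only non-SE magnitude printed.
- eRNA detection — eRNA intervals are consumed as input (BED), not derived
  from run-on reads.
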