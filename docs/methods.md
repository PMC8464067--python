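# Methods

## The analysis in brief

`exoregulon` takes strand-specific counts of ChIP-exo read 5′ ends along a
single bacterial chromosome and produces, per transcription factor: a
filtered set of binding sites, their target genes and location classes,
their RNAP/σ70 promoter co-occupancy types, a direct regulon inferred
against knockout-vs-wild-type differential expression, a regulator class,
and COG functional enrichment of the target set. A synthetic-data
generator with complete ground truth stands in for sequencing data so that
every stage can be validated quantitatively.

## Peak model and filters

ChIP-exo's lambda-exonuclease step digests each immunoprecipitated
fragment 5′→3′ until it reaches the protein–DNA crosslink. A genuine
binding event therefore produces two sharp 5′-end borders: forward-strand
ends accumulate just upstream of the protected region and reverse-strand
ends just downstream. The caller operationalizes this as:

- **Border detection.** Each strand's 5′-end track is smoothed with a
  centered moving average (window 5, odd by construction) and local maxima
  with height above a threshold become candidate borders. Plateaus report
  their leftmost position; maxima closer than 10 bases collapse to the
  highest (leftmost on ties) so that sampling noise inside one border does
  not split it. The default height threshold is the track's own noise
  floor (below).
- **Bimodal pairing.** Scanning forward borders left to right, each is
  paired with the nearest unused reverse border 5–100 bases
  (`d_min`–`d_max`) to its right. For this interval-compatibility
  structure the greedy choice attains the maximum possible number of
  pairs (verified against exhaustive matching in the tests). Borders
  without a partner — no bimodal shape — are dropped.
- **Noise floor.** Over the M nonzero genomic positions of a pooled
  track, the floor is the smallest value among the top ⌈0.05·M⌉ signals,
  so at most 5% of nonzero positions strictly exceed it.
- **S/N filter.** Two selectable references. *Mock mode* divides the IP
  5′-end sum over the peak window (both strands, window `[fwd−pad,
  rev+pad]`, pad 0) by the mock sum over the same window plus a pseudocount
  of 1. *Noise-floor mode* (default, for runs without a sequenced mock)
  divides the peak's mean per-position 5′-end count over its two border
  neighborhoods (half-width 2, matching the smoothing half-window) by the
  floor value. The border-neighborhood definition matters: an exo peak's
  reads sit at its borders, and averaging over the whole protected span
  would dilute a strong site toward the background and make the S/N < 1.5
  removal rule meaningless. Peaks with S/N < 1.5 are removed; a peak at
  exactly 1.5 is retained.
- **Replicates.** Tracks are scaled to a common sequencing depth (per
  sample, pooling strands). A peak must appear in *every* biological
  replicate (centers within 20 bases); merged coordinates are the rounded
  mean and the reported S/N is the minimum across replicates — the
  strictest reading of calling from biological duplicates.

## Target assignment and co-occupancy

The peak anchor is its center, the floor of the border midpoint. A center
inside a gene body is **intragenic** and targets that gene. Otherwise the
site is **regulatory** and targets the nearest downstream gene start on
each strand within `upstream_max` = 300 bases — a typical bacterial
promoter span; the cutoff is configurable because no standard extent
exists. A site between divergently transcribed genes targets both but
counts once in all tallies; a regulatory site upstream of an operon's lead
gene lists the remaining members as secondary targets without
re-counting. Gene starts are strand-aware transcription starts (leftmost
base for + genes, rightmost for − genes).

The promoter interval of a gene is 300 bases upstream to 50 bases
downstream of its start, clipped to the genome. A regulatory site is
`RNAP_RPOD` if its target promoter intersects (≥1 base) both the RNAP and
the RpoD peak sets, `RNAP_ONLY` with RNAP alone, and `OTHERS` otherwise;
every intragenic site is `OTHERS` by definition. For two-target sites the
most-occupied class wins (RNAP_RPOD > RNAP_ONLY > OTHERS). A promoter
with RpoD but no RNAP is biologically incoherent for this typology and
classifies as `OTHERS` with a warning. Overlap is tested against the
target promoter rather than the binding interval itself; a `mode="site"`
switch tests the peak interval instead.

## Differential expression and the regulon

The thresholds are fixed by convention: a gene is DE when |log2 FC| ≥ 1
(inclusive) and BH-adjusted P < 0.05 (strict), with the fold change
measured knockout over wild type. BH adjustment is the step-up rule
q(i) = min_{j≥i} m·p(j)/j on the ascending sort, capped at 1.

The built-in count-based test is an explicit stand-in for a full DE
framework and is intended for simulated or exploratory data; real studies
should import an external DE table (gene, log2FoldChange, pvalue, padj),
from which only the threshold rule and BH are applied. The stand-in:
counts are scaled to counts-per-million; the negative-binomial dispersion
α (variance = μ + αμ²) is estimated by method of moments per gene and
pooled with the ratio-of-sums estimator Σ(s²_g − m̄_g)/Σ m̄_g², which is
nearly unbiased at two or three replicates where the per-gene median is
not; the Wald statistic is the log2 ratio over its delta-method standard
error with the NB variance evaluated at the pooled (null) mean. With the
dispersion pooled across hundreds of genes the variance is effectively
known, so the normal reference calibrates well: simulated null data put
the raw-P rejection rate at nominal level within the exact binomial 99%
envelope (the acceptance suite re-measures this).

The direct regulon is bound ∩ DE. Direction semantics are fixed: up in
the knockout ⇒ repressed by the TF, down ⇒ activated. Regulator classes
follow target counts — 1 single-target, 2–100 local, >100 global, with a
nucleoid-associated label only behind an explicit higher threshold.
Because published tallies sometimes count binding sites and sometimes
distinct target genes, the per-TF summary reports both and classifies on
distinct genes by default (`count_basis="sites"` switches).

COG enrichment is the upper-tail hypergeometric probability of k or more
category members among the n labelled targets given K of N labelled
universe genes, evaluated through the survival function (log-space
internally); unlabelled targets are excluded from n and their count
reported. Significance is P < 0.01 per category, uncorrected, matching
the screen-style usage.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed); child RNG
streams derive from the top seed by fixed component labels, so adding a
component never perturbs the others.

- **Genome and annotation.** Uniform random sequence at a configurable GC
  fraction (default 0.51). Gene lengths uniform in 300–1500 bases;
  remaining slack spread multinomially over the intergenic gaps on top of
  a 60-base minimum, exactly tiling the genome. Genes join the previous
  gene's operon with probability 0.25, sharing its strand; every gene
  gets a COG letter uniformly from 11 categories. Defaults (1 Mb, 800
  genes) keep the gene density of a bacterial chromosome at desk scale.
- **Planted sites.** round(n_sites × regulatory_fraction) sites go to
  intergenic windows within 300 bases upstream of a gene start, the rest
  inside gene bodies at ≥ 30 bases from boundaries; centers stay ≥ 150
  bases apart, and in the packaged scenario each site targets a distinct
  gene. The consensus motif (default the TTC…GAA inverted repeat with a
  6-base spacer) is realized per site from its IUPAC letters and written
  into the genome, so motif recovery is exact by construction.
- **Exo coverage.** Per site and replicate, Poisson(reads_per_site = 200)
  forward 5′ ends at center − 20 and reverse ends at center + 20, with
  Gaussian jitter (σ = 3 bases); uniform Poisson background at 0.01
  reads/base/strand. No published border geometry exists, so offset and
  jitter are free parameters chosen to match the sharpness ChIP-exo
  profiles show in genome browsers. The mock sample places ~20 000
  sheared fragments of uniform length 300–500 bp and records both 5′
  ends, site-independent. Per-replicate depth scale factors exercise the
  depth normalization.
- **Occupancy.** Each operon-lead promoter draws a class from the
  configured fractions (default 0.5 / 0.25 / 0.25 for both / RNAP-only /
  neither); peaks cover the promoter window, and RpoD never appears
  without RNAP. Site-level truth labels are then derived geometrically —
  best class over the site's qualifying target promoters by brute-force
  interval overlap against the emitted peak lists — an independent code
  path from the classifier under test.
- **RNA-seq.** NB(μ, α) counts, default baseline mean 500 and dispersion
  0.05 with 3 replicates per condition (α = 0 degenerates to Poisson);
  planted |log2 FC| = 2 on the chosen direct targets, 80% up in the
  knockout. The default scenario — 50 sites, 60% regulatory, 20 direct
  targets of which 16 repressed — mirrors the shape of a well-behaved
  local regulator.

Not emulated: raw reads (no sequencing error, mappability or PCR
duplicates), multi-chromosome references, condition-dependent binding,
alternative sigma factors, per-gene baseline expression variation,
overdispersion heterogeneity, and correlated biological replicates.
Passing the recovery suites therefore demonstrates the correctness of the
algorithmic chain under its stated signal model, not robustness to every
artifact of real libraries — the filters' thresholds are the published
conventions, and real data enter through the same bedGraph/BED/TSV
surfaces.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere in memory; BED/bedGraph
  serialize as-is, GFF3 converts to 1-based inclusive at the boundary.
- Tie-breaks are deterministic and leftmost: plateau maxima, equal-height
  suppression, and pairing all prefer the smaller coordinate.
- The noise floor is undefined on an all-zero track (error); border
  detection on an all-zero track returns no candidates.
- S/N with a sequenced mock uses pseudocount 1 in the denominator, so an
  empty mock window yields a finite ratio.
- Reports are deterministic: provenance carries the config hash, seed and
  package version but no timestamps, so identical configurations produce
  byte-identical reports.
- Problem sizes in the packaged checks (1 Mb × 5 seeds for site recovery,
  800 genes × 10 seeds for DE calibration, 200 kb fixtures for unit
  tests) were chosen as the smallest scales at which the binomial
  envelopes of the stochastic assertions are meaningfully tight. The
  compact fixtures raise the background rate to 0.03 reads/base so the
  ratio of background to site positions — which the top-5% noise floor
  depends on — matches the genome-scale regime.

## Known limitations

- Candidate border detection is a smoothed-local-maximum heuristic; an
  occupancy-level change-point method could localize borders below the
  jitter scale.
- The stand-in DE test has no dispersion shrinkage and assumes a common
  dispersion across genes; genes with atypical variability are better
  served by an external DESeq2/edgeR table.
- Co-occupancy uses binary interval overlap; promoter strength and peak
  intensity are ignored.
- The S/N and noise-floor references are two published conventions whose
  original interaction is underdetermined; both are implemented and the
  choice is a config flag, but neither is claimed to replicate the
  original computation bit-for-bit.
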