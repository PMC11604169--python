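# Methods

This note documents the models, defaults and design choices behind
`damid-kit`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Region partitioning

GATC is its own reverse complement, so a single forward-strand scan
demarcates both strands; windows containing N never match, and matching
is case-insensitive. An internal region runs from the first base of its
upstream GATC motif to the base before the next motif's first base: the
motif belongs to the region it starts. Nothing forces this convention —
the motif could equally be split or assigned downstream — but it makes
the regions a partition: together with the terminal flanks (chromosome
ends outside the outermost motifs, which are emitted and flagged), the
regions of a chromosome tile `[0, length)` exactly, a property the test
suite asserts on random genomes. Flanks are eligible for testing like
any region, subject to the ordinary filters. Coordinates are 0-based
half-open internally and converted only at I/O boundaries (SAF and GFF3
are 1-based inclusive).

## Counting

A read (or, in paired mode, a properly paired fragment spanning the full
TLEN-derived template) is assigned to exactly one region, the one with
the largest overlap, ties to the leftmost. Single assignment avoids
double counting across the dense region tiling; for typical read lengths
(≪ median region width) the choice of tie-break is immaterial.
Unmapped, secondary, supplementary and QC-fail records are excluded.
Defaults: MAPQ ≥ 10 (excludes multimappers; configurable), duplicates
*kept* — PCR amplification of methylated fragments is part of the DamID
protocol signal, not an artifact to remove. Orphan and discordant pairs
in paired mode are counted as single reads and logged. A chromosome-name
mismatch between regions and a BAM header is a hard error, never a
silent zero count.

## Filtering

Regions wider than 10 000 bp (strict inequality) are removed — they are
GATC deserts whose counts mix many binding events — as are regions
failing CPM ≥ 0.5 in at least *k* samples, where *k* defaults to the
size of the smaller group. Both thresholds are configurable; each
removed region carries a machine-readable reason (`width`/`low_count`)
and appears in the results as `Not_included`.

## TMM normalization

Composition bias matters in DamID: enrichment in the Fusion library
displaces sequencing depth from everywhere else. The trimmed mean of
M-values assumes most regions are unchanged. The reference sample is the
one whose upper-quartile count fraction is closest to the mean
upper-quartile. For each sample, M (log2 ratio vs reference) and A
(average log abundance) are computed over regions nonzero in both
samples; the top and bottom 30% by M and 5% by A are trimmed; the factor
is 2 to the precision-weighted mean of the surviving M-values, with
inverse delta-method variances as weights; factors are rescaled to
geometric mean 1. The implementation is cross-checked against the
reference R implementation (edgeR's `calcNormFactors`) in the test suite
to ~1e-6.

## Differential testing

Per region, counts follow an NB GLM with log link and offsets
log(library size × TMM factor). The workflow:

1. **Common dispersion.** A single NB dispersion φ maximizes the
   Cox–Reid adjusted profile likelihood pooled across regions (profile
   likelihood minus ½ log det X'WX), optimized by bounded scalar search
   on log φ over [1e-5, 5]; each evaluation refits all regions by
   vectorized IRLS.
2. **IRLS.** Up to 100 iterations, relative deviance tolerance 1e-12,
   coefficients clipped to ±30, with step halving whenever a proposed
   update increases the deviance (this makes updates at the coefficient
   box — regions where one group is all zeros — settle instead of
   oscillate). Regions that still fail get p = NA and are excluded from
   FDR, with their count logged.
3. **All-zero groups.** A region where an entire group has zero counts
   has an infinite group-coefficient MLE. Such regions (detected from
   the data, so the treatment is invariant to which group is baseline)
   receive a stabilizing prior of 0.125 counts per sample before
   fitting, and their deviances are excluded from the moderation pool.
4. **Quasi-dispersion and moderation.** s²_g = deviance_g / df_residual;
   empirical-Bayes moderation estimates the prior df d₀ and prior
   variance s₀² by moment-matching the log-variances against a scaled F
   distribution (trigamma inversion), then shrinks:
   s²_post = (d₀ s₀² + df s²_g)/(d₀ + df).
5. **Test.** F = (deviance_null − deviance_full)/s²_post, referred to
   F(1, d₀ + df_residual). logFC is the group coefficient on the log2
   scale; BH FDR across regions with finite p.

The framework is named after its published components (TMM; NB
quasi-likelihood with EB moderation); the contract here is statistical
behavior, not bit-identity with any existing implementation. Under a
null simulation (3v3, ~2000 regions, dispersion 0.1) the observed
fraction of p < 0.05 is ~0.040–0.044 (slightly conservative, as
expected for the QL F test at small n), the p-value histogram passes a
KS uniformity check, relabeling the groups negates every logFC and
leaves p-values unchanged to ~1e-10, and the dispersion is recovered
within a few percent.

**Significance gate.** Peaks are built from regions passing raw
p < 0.01 *and* log2FC ≥ 1 (`Upreg`), matching the convention of ranking
by representative p rather than gating on FDR; FDR is reported alongside
and both thresholds are flags.

**Replicate factor.** Optional dummy-coded replicate terms absorb
replicate-specific effects. With a fully balanced paired design,
replicate effects cancel exactly in the group contrast, so the factor
mainly buys power there. Its type-I benefit appears in *confounded*
designs — e.g. an extra Fusion-only replicate — where replicate-specific
region effects masquerade as enrichment under a group-only model; the
acceptance simulation constructs exactly that case and verifies that the
replicate factor strictly reduces false positives. A replicate factor
fully confounded with group makes the design rank-deficient and is
rejected with an explicit error.

## Peak calling

Upreg regions are scanned left to right per chromosome; the next
significant region is merged into the open peak when the gap between the
open peak's end and its start is strictly less than 150 bp (gap measured
between significant regions; intervening non-significant sequence inside
a merged span is absorbed into the peak's coordinates). The 150 bp
default was tuned for transcription-factor fusions — broad chromatin
marks likely need a different setting, and `--gap` exposes it. Peaks are
ranked by their representative (lowest) region p-value, ties broken by
larger maximum logFC then genomic order. Peak-level FDR is the
representative region's BH FDR; no separate peak-level error control is
claimed. The caller is verified against a brute-force transitive-closure
merge on random layouts of up to 12 regions.

## Candidate genes

Candidates per peak are (a) every gene whose span overlaps the peak and
(b) every gene whose TSS lies within 5 kb (configurable) of the peak
midpoint (lower median base for even widths). Distances are signed
midpoint→TSS; distance 0 when the midpoint falls inside an overlapping
gene. Genes are used at gene granularity — alternative TSSs collapse to
the gene's 5′-most start per strand. The 5 kb radius is a package
default, not an empirically calibrated value; revisit it for genomes
with long-range regulation.

## GO testing

Bias value = number of GATC regions overlapping the gene body ±2 kb
(a `--window` flag switches the width; measuring from the TSS instead is
not currently offered). The probability weighting function
P(significant | bias) is fitted by isotonic regression — deterministic,
dependency-light, and monotone by construction, in the same spirit as
the monotone spline used for RNA-seq length bias — floored/capped at
1e-6/1−1e-6 and rescaled so the mean weight equals the observed
significant fraction. Each category's p-value is the upper tail of a
Wallenius noncentral hypergeometric distribution (population = all
genes, draws = total significant genes) with odds ratio
[w̄_in/(1−w̄_in)] / [w̄_out/(1−w̄_out)] — the standard two-group
mean-weight approximation. `--exact-mc` replaces it with weighted
sampling without replacement (per-gene odds, exponential-race
implementation); the approximation tracks the sampling oracle to within
about 0.01 absolute / 5% relative in p, which is the tolerance the tests
assert. With constant bias the odds ratio is 1 and the result reduces
exactly (|Δp| < 1e-9) to the central hypergeometric. Category maps are
user-supplied two-column TSVs; no ontology-graph handling (no
parent-term propagation) — a documented limitation.

## Visualization

Every plot is assembled from a *manifest* of tidy tables first and
rendered second, so tests assert numbers, never pixels. Track figures
stack per-sample count bars (y-scale shared within group), logFC bars
colored by call, peak boxes, GATC ticks and strand-aware gene glyphs.
The QC figure partitions each sample's total counts into
in-peak / tested-not-in-peak / not-tested segments that provably sum to
the total. SVG output is deterministic (fixed hash salt, no timestamp
metadata).

## Synthetic data

The generator emulates: Poisson-spaced GATC motifs on a random genome
(the post-injection rescan, including incidental motifs, is the ground
truth); width-proportional NB region counts with a gamma variability
factor; planted 2^logFC enrichment at a chosen fraction of regions,
under a fixed per-library sequencing depth so enrichment causes a
realistic composition shift; replicate depth skew; and optional
replicate-specific log-normal region effects at a minority of regions
(default fraction 0.1 when enabled) to emulate accessibility or
copy-number differences between biological replicates. Emitted BAMs
place reads fully inside their region so counting round-trips exactly —
this makes them a sharp oracle for the counter, and deliberately *not* a
test of boundary-straddling assignment, which unit tests cover with
hand-built alignments.

Defaults are a small two-replicate transcription-factor design: 2 Dam +
2 Fusion, 3 injected motifs/kb (plus ~4/kb incidental, comparable to the
1/256 background 4-mer rate), NB dispersion 0.1, 5% of regions enriched
4-fold. The simulation-scale choices used in tests and in
`scripts/acceptance.py` (single 200–300 kb chromosome giving ~1500–2200
testable regions; 3v3 for calibration/power runs; 20 category
configurations with a 50 000-draw oracle) keep full determinism under a
seed while exercising every code path.

Not modeled: fragment-length and GC effects, PCR duplicates, mappability
variation, chromatin-scale broad binding. Passing the synthetic suite
therefore demonstrates algorithmic and statistical correctness under the
NB model, not robustness to every artifact of real libraries.

## Known limitations

- A single pooled dispersion plus EB-moderated quasi-dispersions; no
  trended dispersion curve. Adequate at DamID region counts, but strong
  mean–dispersion trends would be misfit.
- Raw-p peak gate by default (FDR reported); both thresholds are flags
  because the right choice is dataset-dependent.
- No CRAM input, no motif-enrichment analysis on peak sequences, no
  interactive genome-browser export.
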