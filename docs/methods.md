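# Methods

This note documents the statistical models, estimators and numerical
choices behind `germscan`, the assumptions they make, and what the
synthetic panels do and do not establish about real data.

## Data model

The substrate of every stage is an accessions × markers ALT-dosage matrix
with entries in {0, 1, 2, missing}. Dosage orientation is arbitrary: every
statistic in the package (MAF, He, r², r²_V, F_ST, G_ST, D, IBS, distance)
is invariant under g → 2−g, which is verified by property tests, so which
homozygote class of the array caller maps to 0 never matters. Marker maps
carry linkage group and cM position, optionally scaffold and 1-based bp
(present together or not at all). Group labels are an *input*: the package
deliberately does not infer population structure — clusters from any
upstream method (model-based or not) are consumed as a two-column table.

Missing data policy differs by statistic and is chosen to match each
estimator's algebra:

* per-marker frequencies, He, MAF spectra — computed over called
  genotypes only, no imputation;
* distance / IBS — pairwise-complete markers per accession pair;
* r² — pairwise-complete accessions per marker pair;
* kinship — mean imputation (zero after centering), because the
  cross-product needs a complete matrix;
* r²_V — only accessions complete at both markers, with the kinship
  matrix restricted accordingly.

## Marker QC

Markers are discarded at missing rate ≥ `max_missing` (default 0.2) or
observed heterozygosity ≥ `max_het` (default 0.05) — inbred lines should
be near-homozygous, so an excess of heterozygous calls marks a clustering
artifact — and kept at MAF ≥ `min_maf`. Two filtered views of one input
are used downstream: MAF ≥ 0.02 for structure/diversity work and
MAF ≥ 0.05 for LD, where rare alleles make r² unstable. The missing-rate
bound is computed as an exact integer ratio so a marker at exactly the
threshold is discarded.

## Diversity

Gene diversity is Nei's He = 2p(1−p) with within-group frequencies; no
small-sample correction is applied by default (the plain estimator is the
field's convention for array panels; means are compared between groups at
equalized sample sizes instead). The size-equalizing resampler draws
`reference_n` accessions without replacement `n_reps` times (default 50)
and averages mean-He over replicates; with `reference_n` equal to the
group size every replicate equals the full-group value exactly.

Joint allele-frequency histograms need one consistent allele per marker
across both groups; per-group MAF does not provide that (the minor allele
can differ between groups), so the default axis is the within-group
frequency of the *globally* minor allele on 10 equal bins of [0, 1], with
`axis="per_group"` available. Markers monomorphic within a group are kept
at frequency 0 (the wild-group spectrum depends on them); a flag drops
them.

## Relatedness

Allele-sharing distance counts non-shared alleles over pairwise-complete
markers: each marker contributes 2 − |g_i − g_j| shared alleles of 2, so
IBS = 1 − distance exactly on the same marker set. The computation uses
dosage-class indicator cross-products, avoiding an explicit pair loop.

Kinship is the centered-standardized cross-product (VanRaden-style):
x = (g − 2p)/√(2p(1−p)) with panel-wide frequencies, K = XXᵀ/m over
polymorphic markers. Expected values: off-diagonal ≈ 0 for unrelated
outbred lines, diagonal ≈ 1 + f, hence ≈ 2 for fully inbred lines — both
checked by simulation. K is symmetric PSD up to 1e−8.

Ward clustering applies the Lance–Williams Ward update to the precomputed
distance matrix (scipy linkage; verified against a naive O(n³)
transcription of the recurrence). Newick branch lengths are derived from
merge heights and are cosmetic — the allele-sharing distance is not
ultrametric, so the dendrogram scale is not a divergence-time estimate.
IBS networks connect accessions with IBS strictly above a threshold
(default 0.8), optionally recomputing IBS on a marker subset (e.g. only
markers polymorphic within a focal taxon, which spreads out otherwise
saturated clusters).

## Linkage disequilibrium

r² is the squared Pearson correlation of dosages. For near-fully inbred
material genotypic and haplotype r² coincide, so no phasing or EM is
attempted. All within-linkage-group pairs are evaluated (indicator
algebra gives every pair its own pairwise-complete accession set without
looping); pairs with zero variance on the joint-called set are flagged
undefined and excluded from profiles. Decay profiles bin pairs at 0.5 cM
default width and report the 5–95% quantile grid per bin, suppressing
bins with fewer than 10 pairs. Physical-distance LD uses only pairs
sharing a scaffold.

r²_V removes structure-induced LD: with V the kinship submatrix on the
usable accessions and L its lower Cholesky factor (ridge 1e−6 added if V
is not positive definite), both dosage vectors are whitened by L⁻¹, the
whitened intercept is projected out, and the squared correlation of the
residuals is clipped to [0, 1]. With K = I this reduces to r² exactly
(tested to 1e−10). For heatmap matrices of a whole linkage group, missing
dosages are mean-imputed so a single whitening serves all pairs; the
pairwise `r2v` function keeps the exact per-pair restriction.

## Differentiation

Weir–Cockerham variance components per marker, with r groups of n_k
called individuals, ALT frequency p_k and observed het fraction h_k:
n̄, n_c, p̄ (weighted), s², h̄ as in the 1984 framework, then

    a = (n̄/n_c)[s² − (p̄(1−p̄) − (r−1)s²/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − (r−1)s²/r − (2n̄−1)h̄/(4n̄)]
    c = h̄/2,   θ = a/(a+b+c)

Groups without calls at a marker are dropped marker-wise; fewer than two
usable groups, n̄ ≤ 1 or a+b+c = 0 give a flagged NaN. Negative θ values
are retained in scans and means (clipping would bias multilocus
summaries). The multilocus estimate is the ratio of sums Σa/Σ(a+b+c);
the simple mean of per-marker θ is reported alongside because the two
answer different questions and a "mean F_ST" quoted without
qualification could be either.

G_ST and Jost's D use *unweighted* group means: H_S = mean 2p_k(1−p_k),
H_T = 2p̄(1−p̄), G_ST = (H_T−H_S)/H_T and D = [(H_T−H_S)/(1−H_S)]·k/(k−1).
Closed-form anchors: reciprocal fixation gives exactly 1 for both; equal
frequencies give 0; p = (0.9, 0.1) gives G_ST = 0.64 and D = 0.78049.
Both are validated against independent scalar transcriptions on 1,000
random inputs to 1e−10.

The Manhattan coordinate is cM plus cumulative linkage-group offsets
(5 cM inter-LG gap, cosmetic). Outlier flagging is an empirical quantile
of the observed θ distribution (default 0.995), labelled
`empirical_quantile` in the output: it is a ranking device, not a
significance test, and carries no control of false positives under a
neutral model — a deliberate choice to keep the scan free of demographic
assumptions.

## Synthetic panels

The generator emulates an array-genotyped selfing-crop collection, not
any species' history:

1. ancestral frequencies p ~ Uniform(0.05, 0.95) per locus;
2. group frequencies from the Balding–Nichols Beta distribution around p;
3. per group, `n_founders` haplotypes drawn site-independently from the
   group frequencies;
4. each sample haplotype copies founders piecewise along each linkage
   group, switching founders at Poisson points (`switch_rate_per_cM`);
   with probability `inbreeding_prob` (default 0.97) the second haplotype
   is a copy of the first;
5. residual heterozygous calls at rate 0.01, missing entries at 0.03;
6. optional ascertainment: loci below a MAF floor in the pooled
   non-wild groups are dropped, mimicking array design bias;
7. physical coordinates: consecutive markers within 0.5 cM share a
   scaffold, bp = cM offset × 5.6 Mb/cM (a genome-scale figure typical of
   large legume genomes).

Defaults: 3 groups ("wild", "winter", "spring") × 100 lines, 7 linkage
groups × 286 markers on 100 cM, drift 0.3 per group, 8 founders, switch
rate 0.1/cM. All randomness flows from one master seed split into named
child streams (map, ancestral, drift, founders, mosaics, het, missing),
so each stage is reproducible independently of execution order.

**Drift semantics.** Resampling a finite founder pool adds drift of its
own (variance ≈ p(1−p)/n_founders), so the Beta stage is deflated,
F_beta = (F − 1/n_f)/(1 − 1/n_f), making `drift_F` the *realized*
group-level drift. Without this, 8 founders at nominal F = 0.3 would
realize ≈ 0.39. The Balding–Nichols moments (mean p, variance F·p(1−p)
across loci) are verified at the founder-pool level in the tests, and the
multilocus ratio-of-sums estimate recovers the configured drift within
±0.03 at default panel size across seeds.

**Outlier planting.** "A locus differentiating the pair at F" is
implemented as a deterministic symmetric split: pair frequencies μ ± δ
with δ² = F·μ(1−μ) (the two-group parametric closed form), μ clamped
into [F/(1+F), 1/(1+F)] so both frequencies stay in [0, 1]. Drawing the
pair independently from a high-F Beta instead realizes *bimodal*
differentiation (both groups often drift to the same tail), which is not
what "planting an outlier" means. At the planted frequencies the
Weir–Cockerham θ expectation is 2F/(1+F) (≈ 0.89 at F = 0.8).

**Recovery experiment sizing.** The neutral per-locus pairwise θ
distribution at drift 0.3 is heavy-tailed: about 0.4% of loci exceed the
planted level even at infinite sample size, and estimator noise at 100
lines/group widens the tail further, so at that size the top-1% flag set
is partly occupied by neutral loci and planted-locus recovery is
unreliable (the README example shows 4/10). The documented recovery
experiment therefore contrasts two groups of 500 lines with a founder
pool of 2n (so realized frequencies track the planted values); there,
≥ 8/10 planted loci are recovered at the 0.99 quantile. This is a
statement about estimator precision, not a tuning of the generator: the
planted effect and the neutral drift are unchanged.

**What the synthetic panels do not show.** Founder mosaics are not a
coalescent: LD decay scale and amount are set by two knobs, not by a
demographic history; allele-frequency spectra are Uniform×Beta, not the
site-frequency spectrum of any mutation model; groups drift
independently (no admixture, no gene flow, no domestication bottleneck
sequence). Passing recovery tests shows the estimators measure what the
generator planted — it does not validate demographic inference on real
collections, which this package does not attempt.

## Pipeline and reproducibility

The pipeline applies the two filtered views, then relatedness, diversity,
LD and the scan, writing every artifact with a SHA-256 checksum, the
thresholds, seed and package version into `manifest.json`; marker and
accession counts are logged after every filter so published counts can be
audited. Reruns with identical config and seed are byte-identical
(asserted in tests). The kinship-corrected heatmap is capped at 60
markers per linkage group by default to keep the whitened correlation
matrix cheap; the cap is a parameter.

`scripts/acceptance.py` recomputes the headline quantities from scratch
at the documented study conditions: the default panel for multilocus
F_ST, group He (raw and size-equalized), wild polymorphism fraction
under ascertainment, pooled LD-decay medians, F_ST–D concordance and the
ANOVA; a 2 × 500 panel for planted-outlier recovery; ten replicate
default panels for drift recovery error. Problem sizes (~2,000 markers,
100–500 lines per group) are the package's documented desk-scale
conditions throughout.
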