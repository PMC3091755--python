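# Methods

This note documents the statistical procedures implemented in `escapex`, the
synthetic data model that drives the test suite, and the numerical and design
choices a maintainer should know about.

## Biological setting

In female mammals one X chromosome is transcriptionally silenced (X
inactivation, XCI) for dosage compensation. A minority of X genes escape
silencing and remain biallelically expressed, producing female-biased
expression; Y-linked genes are male-specific; Xist, the lncRNA that initiates
XCI, is expressed essentially only in females (~10⁴-fold female/male). The
pipeline screens sex-balanced expression matrices for sex-biased genes,
asks where they sit in the genome, and tests whether female-biased lncRNAs
cluster non-randomly with coding XCI escapees in confined X-chromosome
domains that also lack the repressive chromatin mark H3K27me3.

## Screening model

**Standardization.** Every array (sample column) is affinely rescaled to
mean 8 and SD 2 on the log2 scale. The population (1/n) SD convention is
used; either convention is defensible, but one must be fixed for
bit-reproducibility, and the population choice makes the map an exact fixed
point under re-application.

**Xist sex QC.** For each Xist probe, a threshold is placed at the midpoint
of the recorded-female and recorded-male medians (medians are robust to the
mislabeled arrays being hunted). A sample is flagged only when *all* its
Xist probes fall strictly on the wrong side of their thresholds — with two
probes this is the "opposite quadrant" of a scatter plot. One-probe
discordance is deliberately not flagged (conservative rule). Degenerate
inputs (a missing sex group, coincident medians) raise errors rather than
guessing.

**Balancing.** After dropping flagged arrays, the larger sex group of each
tissue is down-sampled uniformly at random with an explicit seed. Balancing
is per tissue because each tissue is screened as its own family.

**Test and FDR.** Each probe gets a two-sided Wilcoxon–Mann–Whitney test
(females vs males). For combined n ≤ 12 without ties the exact null
distribution is used; otherwise the normal approximation with midranks, tie
correction and continuity correction. p-values are clipped into (0, 1].
Benjamini–Hochberg step-up adjustment is applied across all probes of one
tissue; hits are probes with adjusted p ≤ 0.05. Fold changes are reported on
the linear scale with the sign convention FC = 2^(Δ log2 mean) if ≥ 1, else
−1/FC (positive = female-up). No pre-test probe filtering is applied.

**Chromosome enrichment.** Counting is over distinct gene symbols (a gene
with several significant probes counts once). Expected counts are
n_sig × (genes on chromosome / genes annotated); the test is the
hypergeometric upper tail P(X ≥ obs). The hypergeometric (without
replacement) is the natural choice because the sampling frame — genes on the
array — is finite; expected counts sum to n_sig exactly.

**Cross-tissue overlap.** Hit lists are intersected at the gene-symbol level
within an array platform; every Venn region is computed exactly (each gene
of the union belongs to exactly one region). Shared sex-chromosome genes are
split into *known* (a curated, editable fixture of documented sex-biased
X/Y genes: Xist, Jpx, the coding escapees Kdm5c/Eif2s3x/Kdm6a/Ddx3x and
their Y paralogues) and *novel*; everything else is autosomal.

## Escapee-domain analysis

**Pairing.** Every female-biased non-coding X gene is paired with the
nearest female-biased coding X gene whose edge-to-edge gap (0-based
half-open; 0 when overlapping or nested) is at most 50 kb, or which contains
it. Relations: `nested_intronic` (containment), `head_to_head` (opposite
strands, 5′ ends facing across the gap), `tandem` otherwise. Ties in gap are
broken by genomic position. Unpaired candidates are returned, not errors.

**Permutation null.** With the anchor set (Xist-like, Jpx-like and the
coding escapee loci — Kdm6a included) held fixed, each of 10⁴ permutations
draws k = 4 distinct X-linked probes uniformly *without replacement* from
the universe of non-anchor X probes, and succeeds iff all four lie within
50 kb of an anchor gene body (gene interval extended ±50 kb; body-anchored
rather than TSS-anchored windows, since the distance is stated relative to
the genes). Excluding anchor-owned probes matters: drawing an anchor's own
probe would trivially inflate successes and is not a null for the four
candidate lncRNAs. The success probability has the closed form
C(n_in, k)/C(n_total, k), used as an independent oracle in the tests; the
estimator's binomial standard error is √(p(1−p)/n_perm).

**Peak coverage.** Coverage of an interval is the length of the union of
intersecting peaks divided by the interval length (interval-tree union;
tests verify against a sweep-line oracle). A domain's depletion ratio is
inside-coverage over the mean coverage of its two 100 kb flanks, with an
infinity marker when the flanks are peak-free.

## qPCR model

Ct values (background-subtracted upstream by the instrument software) are
converted to relative copy numbers via a per-gene standard curve
Ct = a + b·log10(input) fitted by least squares to a dilution series
(≥ 3 distinct levels required); amplification efficiency is
E = 10^(−1/b) − 1, so the ideal slope −1/log10(2) ≈ −3.32 gives E = 1.
Copies are normalized per sample to the geometric mean of the two reference
genes (Actb, Gapdh), which is invariant to global rescaling. Sexes are
compared per gene and tissue by a two-sided Welch (unequal-variance) t-test
on the *linear* normalized values — mirroring the ratio-of-means reporting;
the scale is a convention, stated here because the log scale would also be
defensible. Significance tiers: * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001. When the
group means are identical the t statistic is 0/0 and p is defined as 1.
Note that because all targets in a sample share one reference-gene factor,
null genes show mildly correlated fluctuations across targets; occasional
nominal p < 0.05 for a no-effect control across many tissue/seed
combinations is expected behaviour, not a bug.

## Synthetic data model

The generator is the package's ground-truth instrument; its defaults are the
study conditions the pipeline is meant for.

* **Genome.** Two autosomes plus X (166 Mb) and Y. Four escapee-domain
  templates are realized exactly: a lncRNA 33 kb upstream of a Ddx3x-like
  gene (head-to-head), one inside an Eif2s3x-like intron, one 2.6 kb
  downstream of a Kdm5c-like gene (tandem), and a head-to-head pair
  separated by 9.7 kb. Fixed singleton loci: Xist-like (two probes, as used
  for QC scatter plots), Jpx-like, Kdm6a-like, an X-inactivated Rps4x-like
  control, four Y-linked genes, and two autosomal housekeeping genes.
  Filler genes are placed uniformly per chromosome with weights
  length × `gene_density`; the default densities (X 0.09, Y 0.008 relative
  to autosomes) reproduce the sparse sex-chromosome representation of
  expression arrays (~4% of genes on X, ~0.2% on Y), without which Y
  enrichment could never reach significance at realistic hit counts.
* **Expression.** Per-probe Gaussian baseline (mean 8, SD 1.5 on log2) ±
  half the planted effect by true sex, plus N(0, noise_sd) noise.
  noise_sd defaults to 0.5 — a typical residual SD for standardized array
  data; it is a free parameter with no external anchor. Planted effects:
  random probes draw magnitudes uniform in log2(1.1)..log2(2.0) with random
  sign; escapee-domain genes and Jpx draw from the upper half of that band
  (log2 1.5..2.0, female-positive), where validated escapees sit; Xist uses
  a detection-floor model (females at floor + 13.3 log2 units ≈ 10⁴-fold,
  males at the floor), Y genes the mirror image (32-fold male-up by
  default). The planted budget is round(frac_sex_biased × n_probes),
  special genes first. Mislabeling flips only the *recorded* sex label —
  Xist and Y signals follow true sex, which is exactly what makes the QC
  rule able to catch the flips. Y probes in females emit floor-level noise
  rather than missing values, as arrays report intensities for all probes.
* **Peaks.** The X is tiled with 1 kb peaks every 1.5 kb (coverage ≈ 0.67,
  position-jittered), skipping peaks that touch an escapee-domain span —
  emulating an H3K27me3 track over a largely inactivated X with escapee
  holes. Coverage inside domains is exactly 0 by construction; the test
  criteria (< 0.05 inside, > 0.5 over the control gene) are deliberately
  weaker than the construction.
* **qPCR.** Ideal slope −3.32 with per-gene intercepts near 20 and Ct noise
  SD 0.15; per-sample inputs encode the planted female/male ratios
  (escapee pairs 1.3–1.8, Xist 10⁴, Rps4x and references 1.0), group size
  16 per sex.

**What the synthetic data do not emulate:** probe-level normalization
artifacts (rank-invariant/RMA upstream steps), cross-probe correlation
structure, batch effects, platform-specific probe sets, tissue-specific
effect heterogeneity (planted effects are shared across tissues), or real
mm9 coordinates. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
every artifact of real array data.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng` seeds. The pipeline
derives per-stage sub-seeds as SHA-256(global seed : stage name) mod 2³¹, so
stages can be re-run in isolation with identical randomness and a config +
seed pair is bit-reproducible end to end.

Test problem sizes were chosen to exercise the study conditions at desk
scale: null FDR calibration uses 200 replicates of 1,000 probes at 43 vs 43
arrays; power checks plant 2-fold effects at 60 vs 60; QC sensitivity runs
100 replicates; the co-localization oracle grid uses thousands of
permutations per point; the headline permutation runs the full 10⁴
permutations over ≥ 1,000 X probes. The whole suite completes in well under
a minute on a laptop-class machine.

## Known limitations

* The Mann-Whitney exact/asymptotic switch (combined n ≤ 12, no ties) is a
  fixed convention; boundary cases near the switch are approximation-
  dependent, as in any implementation.
* The screen assumes exchangeability within sex groups; no covariates,
  batch terms or moderated variance models are offered.
* Gene-level enrichment treats multi-probe genes as single draws; probes of
  one gene are not independent and the hypergeometric frame is a modelling
  choice, not a derived property.
* The co-localization null fixes the anchor list a priori; sensitivity to
  anchor choice (e.g. dropping Kdm6a) must be explored by re-running with a
  different `PermutationSpec.anchors`.
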