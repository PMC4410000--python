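# Methods

This note documents the statistical models implemented in `dimorphseq`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Count model and dimorphism testing

Gene-level read counts `K_gs` (gene g, sample s) are modelled as negative
binomial with mean `sf_s · q_g · exp(β_g · male_s)` and variance
`μ + α_g μ²`. The log-link GLM has sex as the single covariate, so
`β_g / ln 2` is the log₂ fold change male over female; it is tested with a
Wald test (normal reference) on the sex coefficient.

**Size factors** are the median-of-ratios estimator: the reference is the
per-gene geometric mean over samples, computed over genes with non-zero
counts in every sample; each sample's factor is the median ratio to the
reference, rescaled to geometric mean 1. When no gene is non-zero
everywhere (very sparse libraries), total-count factors are the documented
fallback (used automatically only by sex calling, where sparse eight-cell
style libraries are expected).

**Dispersion** `α_g` is a method-of-moments estimate on normalised counts:
within each sex group, solve `var = mean + α·mean²`; pool the two groups
weighted by degrees of freedom; floor at 1e-8. The gene-wise estimates are
then moderated toward a fitted mean–dispersion trend `α(μ) = a0 + a1/μ`
(non-negative least squares with one robustness reweighting pass) as the
equal-weight average `0.5·α_g + 0.5·α_trend(μ_g)`. This is deliberately
simpler than empirical-Bayes dispersion shrinkage in full differential
expression frameworks; no numeric parity with any of them is claimed. The
MoM step treats normalised counts as NB directly rather than correcting
the Poisson share by `mean(1/sf)`: with geometric-mean-1 size factors the
bias is O((mean(1/sf)−1)/μ), i.e. negligible, and the omission makes
fold-change estimates exactly invariant to global depth rescaling.

**Sex-exclusive genes.** When one sex has all-zero counts (e.g. *Xist*,
*Eif2s3y*), the GLM separates. Such genes fall back to a moment-based Wald
test on pseudocounted (+0.5) group means with a delta-method standard
error. Their fold changes are reported (the sign and magnitude are the
scientifically relevant part) but are inherently pseudocount-dependent.

**Multiple testing.** Benjamini–Hochberg (step-up, cumulative-minimum
construction) over *tested* genes only. A gene is tested if it passes the
expression filter — default `all_samples_nonzero`, a literal
"expressed in every sample" rule; `mean_ge:<t>` on normalised means is the
alternative. Untested genes keep their effect-size estimates but carry no
adjusted p and cannot enter a signature.

**Signatures** are the rows with `padj < 0.1` and `|log₂FC| > 0.5`, both
strict inequalities, with the thresholds recorded on the object.

Calibration (checked by the test suite and the acceptance script): on
2000-gene null simulations at 6 vs 6 and dispersion 0.05 the Wald type-I
error at nominal 0.05 lands near 0.05 (acceptance band 0.03–0.07), and
planted |log₂FC| = 2 effects at 12 vs 12 are recovered with ≥ 90%
sensitivity at empirical FDR ≤ 0.1 under the signature thresholds.

## Sex calling

Samples are points in the 2-D space of log₂(normalised + 1) expression of
the two marker genes. A deterministic two-centre assignment replaces
seeded k-means so calls are exactly reproducible: centres initialise at
the farthest pair of samples (ties broken by sample order), samples are
assigned to the nearer centre, centres are recomputed once and samples
reassigned. The group with higher mean male-marker expression is labelled
male. A per-sample margin (distance difference between the two centres) is
reported so users can flag ambiguous samples; no rejection threshold is
imposed, since any such cut-off would be arbitrary at these sample sizes.
All-identical marker profiles raise a degenerate-input error.

## Signature projection

Projected log₂FC in a target dataset is the difference of group means of
variance-stabilised counts, `mean(VST male) − mean(VST female)`, where
VST = log₂(normalised + 1). A mean difference is used instead of a
re-fitted GLM because comparison datasets can have as few as 2–3 samples
per sex, where GLM fits are unstable; the pseudocount keeps zero-count
groups finite. Genes absent from the target are listed, never silently
dropped. A conservation flag marks |log₂FC| > 0.5 (configurable).

**Directional consistency** between two logFC tables counts same- versus
opposite-sign genes among shared genes (optionally excluding |logFC| below
a floor; exact zeros carry no sign and are excluded) and tests
(n_same, n_opposite) against 50:50 with a 1-df goodness-of-fit chi-square,
no continuity correction — algebraically `(n_same − n_opp)²/n`. The
statistic is discrete, so calibration holds in the type-I-rate sense
rather than p-value uniformity.

**X:autosome expression ratio** is the mean normalised count over
expressed X-linked genes divided by the mean over expressed autosomal
genes within one sex; Y genes are excluded from both terms. Under full
dosage compensation with an up-regulated active X the ratio approaches a
common value in both sexes; the female/male ratio of ratios isolates the
X-dosage effect (≈ 2 in a simulation with uncompensated 2× female X).

## Chromosome dosage model for ChIP-seq

Inputs are per-gene TSS-window signals (window TSS ± 1500 bp by default;
totals or averages — the two differ by a constant that cancels in every
ratio, and the per-gene table records which was used). The TSS is the
annotated start on the + strand and the annotated end on −. Replicate
tracks are averaged gene-wise before any total is formed. chrY is removed
from every total.

With male library totals `N_total` (all non-Y genes) and `N_x` (chrX
genes), the scaled male density for X gene i is `S_i = 2·N_i/(N_total + N_x)`
— doubling chrX both per-gene and in the library total, i.e. the female
expectation under pure 2× dosage. The observed female density is
`A_i = N_i_female/N_ftotal`. Genes with zero signal in both sexes are
retained with S = A = 0 and flagged.

A gene set's fold enrichment is read-weighted, `FE = ΣA_i / ΣS_i`, rather
than a mean of per-gene ratios — robust to near-zero S_i; this aggregation
is this package's definition. Significance comes from permuting same-size
sets drawn uniformly from the fitted X genes with S > 0;
`p = (b + 1)/(n_perm + 1)` with b the number of null FEs at least as
extreme, two-sided on |log FE| by default (enrichments in both directions
are of interest). The +1 convention keeps p > 0 always. Permutations are
vectorised in chunks, so 10⁴ permutations over a few hundred background
genes take well under a second.

Identities checked by the suite: exact A = S (hence FE = 1 for any set)
when female counts are exactly twice male on X with matched totals; FE → 1
under simulated pure dosage as read depth grows (|FE − 1| < 0.05 at
≥ 500 reads/gene); A and S invariant to rescaling either sex's track.

## Gene-set overlap and pathway enrichment

Overlap fold enrichment of sets A and B in background U is
`|A∩B| / (|A||B|/|U|)`; the permutation null redraws A uniformly from U
(upper tail, (b+1)/(n+1)), and the one-sided hypergeometric p is reported
alongside since either convention may be wanted. Pathway enrichment is
upper-tail hypergeometric per pathway after intersecting pathways with the
background; pathways disjoint from the background are excluded from both
testing and the Bonferroni denominator. Backgrounds are always supplied by
the caller — the choice of universe (all expressed genes, detected X genes,
…) is a scientific decision the software must not make silently. No
pathway database is bundled.

## Synthetic data generator

The generator inverts the analysis model, so that what the pipeline
assumes is exactly what the simulator produces:

- per-gene baseline log₂ means ~ Normal(5, 2) (≈ 32 counts median, heavy
  right tail), NB sampling via gamma–Poisson with dispersion 0.05 by
  default (typical bulk RNA-seq for inbred animals);
- per-sample library sizes log-normal with CV 0.2, applied
  multiplicatively (exercises size-factor estimation);
- female X genes shifted by `x_dosage_log2` (default 1.0 = full 2× dosage
  before X inactivation; set toward 0 to emulate XCI, with escape genes
  representable as planted effects);
- Y genes exactly zero in females (makes sex-calling ground truth
  deterministic; the marker *Eif2s3y* carries the reference effect size
  +5.94 log₂ units, *Xist* −9.01, both from the bundled eight-cell
  signature);
- a fraction of autosomal genes planted dimorphic with sign-balanced
  effects of magnitude `effect_size_log2`. Effects are planted only on
  genes with baseline log₂ mean ≥ 4: real dimorphic signatures are defined
  within the detected-gene universe, so recovery rates measure the test
  rather than the expression filter;
- effects applied symmetrically (±t/2 to the two sexes) so the
  male/female mean ratio is exactly 2^t;
- TSS window counts are Poisson about log-normal per-gene expectations,
  with the female X expectation a tunable multiple of the male one and an
  optional additionally-scaled enriched set.

Defaults emulate a 6 vs 6 discovery design with a 2110-gene genome
(2000 autosomal / 100 X / 10 Y); calibration and recovery experiments at
these sizes run in seconds, which is why the acceptance checks use them.

What the generator does **not** model: read-level artefacts (it starts
from counts), allele-specific expression and XCI escape at the allele
level, litter/batch structure (a config hook exists but is off by
default), gene length effects, and correlated genes. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to every artefact of real libraries.

## Numerical notes

- Coordinates are 0-based half-open everywhere; GTF input (1-based
  inclusive) is converted on read; the TSS of a − strand gene is the
  annotated end.
- TSS windows truncated at position 0 average over the remaining width;
  genes on chromosomes missing from a coverage file get 0 with a logged
  warning; overlapping bedGraph intervals are a format error.
- BH adjustment uses the cumulative-minimum construction and a stable
  sort, so ties are handled identically to the step-up definition.
- The farthest-pair initialisation of sex calling breaks distance ties by
  sample order, making calls invariant to sample permutation.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces output
  bit-for-bit, including across the pipeline driver.

## Known limitations

- The NB test is a two-group design only: no covariates, interactions,
  outlier replacement or logFC shrinkage. Exact parity with any specific
  differential-expression package (and hence with published gene counts
  derived from one) is explicitly not claimed.
- The moment fallback for sex-exclusive genes reports pseudocount-
  dependent fold changes; only their sign and rough magnitude are
  meaningful.
- The dosage model assumes TSS windows capture the relevant signal and
  that library composition outside chrY is comparable between sexes; it
  performs no input/IgG correction and no peak calling.
- Microarray-derived comparison data enter only as precomputed logFC
  tables; the package does no array processing.
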