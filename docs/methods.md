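# Methods

`phosphosig` implements the comparative analysis used in small paired
TMT-multiplexed (phospho)proteomic studies of Barrett's esophagus (BE):
biopsies of the metaplastic lesion and of adjacent normal squamous
epithelium from the same patients, processed as one TMT plex per cohort,
plus biopsies from healthy (non-BE) control patients.  This note documents
the statistical model of each stage, the synthetic-data generator used to
validate the pipeline, the numerical choices, and the known limitations.

## Preprocessing

Phosphosites are filtered at localization probability >= 0.7 (inclusive:
"minimum of 0.7" is read as the lowest allowed value).  Zero or blank
reporter intensities are treated as missing — a zero reporter intensity is
a non-detection, not a measurement.  Missing data are handled complete-case
per cohort: TMT within-plex quantification is near-complete, and imputation
would introduce a modelling choice the analysis does not need.  Intensities
are then log2-transformed and quantile-normalized *within* each plex
(channels of one plex share acquisition; normalizing across plexes would mix
batches).  Ties in quantile normalization receive the mean of the reference
values across the tied rank span, which makes the operation deterministic,
order-independent and idempotent.  An optional per-channel multiplicative
factor on raw intensities represents vendor label-lot correction (default
1.0).

## Paired differential analysis

The BE vs adjacent contrast is fit as a one-sample problem on
within-patient differences `delta_f = log2(BE) - log2(ADJ)`, which for a
balanced pair design is equivalent to a patient-blocked two-group linear
model and removes the patient random effect exactly.  Per-feature variances
are shrunk by empirical Bayes: sample variances with d residual degrees of
freedom are moment-matched on the log scale to a scaled F distribution
`s0^2 * F(d, d0)` (Newton inversion of the trigamma function), giving the
prior degrees of freedom d0 and prior variance s0^2.  The moderated
statistic uses the posterior variance
`s~^2 = (d0 s0^2 + d s^2)/(d0 + d)` and is referred to a t distribution on
`d0 + d` degrees of freedom; `d0 = +inf` (no excess variance spread) gives
complete shrinkage and normal-distribution p-values.  p-values are
two-sided; multiple testing uses Benjamini–Hochberg.

Features with zero sample variance across pairs are excluded from
hyperparameter estimation; with finite d0 they are flagged and assigned
p = 1 rather than a spuriously confident statistic (in the complete
shrinkage limit the statistic does not involve the sample variance and is
computed normally).

The unpaired ADJ vs non-BE contrast uses the same shrinkage machinery with
a pooled two-sample variance.  **Replication unit:** replicate biopsies of
one patient are averaged before this contrast.  Control patients contribute
two normal biopsies each; treating them as independent samples understates
the variance of the group mean (the shared patient effect makes them
correlated) and inflates the type-I error to ~0.09 at nominal 0.05 in
simulation.  Patient-level averaging restores nominal calibration.

Phosphosite statistics are *not* adjusted for parent-protein abundance;
site-level changes therefore mix phosphorylation-state changes with protein
abundance changes.  This is deliberate and documented rather than silently
corrected.

## Signature selection and empirical FDR

The disease signature is the top 1% of features ranked by moderated-t
p-value (ties broken by |t|, then feature id; the candidate count uses ceil)
intersected with |log2FC| >= 0.75 — a strict bound given that isobaric
reporter ratios are compressed toward zero.  Direction follows the sign of
the fold change.

Reliability is quantified by a randomization-based empirical FDR: each of
n_rand = 100 randomizations independently flips the sign of every patient's
paired-difference column with probability 1/2 (the exact exchangeability
null for a paired design), reruns hyperparameter estimation, the moderated
t and the full selection, and records the null selection count; the
estimate is mean(null count) / max(1, observed count).

**Limitation (small n).**  The iid sign-flip group contains 2^n patterns,
including the identity and the global flip, each of which reproduces any
two-sided selection exactly.  The count-ratio estimate therefore has an
irreducible floor of about `2/2^n` — 0.25 at 3 pairs, 0.0625 at 5 pairs —
before any real leakage.  Two further effects raise it: near-trivial
patterns (one flip out of five) leave planted markers with 60% of their
fold change, enough to clear the 0.75 bound while variance shrinkage keeps
them competitively ranked; and with realistic per-feature variance
heterogeneity a few truly null features clear both filters per
randomization at n = 5.  In simulations at this package's default
conditions the estimate settles around 0.2 for strongly planted signatures
regardless of effect size.  The estimate is reported as computed; it should
be read as a conservative upper bound at plex-scale n, and decisive
empirical-FDR claims below ~0.1 require more pairs than one TMT plex holds.

## Classification of independent cohorts

Samples of an independent cohort are clustered on the signature features
only: rows are standardized (centered/scaled across samples; constant rows
dropped with a warning), samples are ordered lexicographically (so the tree
is invariant to input order), and agglomerative clustering uses
1 − Pearson correlation with average linkage.  The cut at k clusters is
scored against known tissue labels by purity and adjusted Rand index.
Cross-omics projection onto transcriptome profiles matches signature
members by upper-cased gene symbol; unmatched members are reported, never
silently dropped.

## Preranked GSEA

Features are ranked by moderated t (phosphosites first collapsed to genes
by keeping the site with the largest |t| per gene).  The enrichment score
is the weighted Kolmogorov–Smirnov statistic: members increment the running
sum by `|t|^w / sum |t|^w` (w = 1), non-members decrement by `1/(N - |S|)`;
ES is the signed maximum deviation.  The null draws random same-size member
sets from the ranked universe (gene permutation — sample permutation is
meaningless with a handful of pairs), 10,000 draws by default, computed
from sorted hit positions in vectorized form and cached per set size.
p-values are one-sided within the sign of the observed ES with the +1
correction, NES divides by the mean |null ES| of the same sign, and FDR is
Benjamini–Hochberg across sets.  Set size bounds default to 5–500.

## Kinase–substrate enrichment

For kinase k with m >= 3 quantified substrate sites (matched exactly on
canonical `GENE_S123` ids; unmatched map edges are counted and reported):

    z_k = (mean(substrate t) - mean(all site t)) * sqrt(m) / sd(all site t)

with a two-sided normal p-value; positive z = inferred activity elevated in
BE.  The z-score is invariant to affine transformations of the site
statistics.  An independent permutation p (random same-size site draws)
agrees with the analytic p within Monte-Carlo error on large backgrounds
and serves as a cross-check.  No kinase-level multiple-testing correction
is applied to the p < 0.05 call (matching how such analyses are usually
reported), but BH q-values are included in the output.  Sequence-motif
scoring is out of scope; only curated kinase–substrate edges are used.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth, so every claim the pipeline makes can be checked against
planted signal.  Per feature f on the log2 scale:

    value = b_f + patient_effect + class_effect + noise

- baseline `b_f ~ N(24, 2)`; raw intensity `2^value`;
- patient effect `~ N(0, 0.3)` per (feature, patient), shared by both
  biopsies of a patient — it cancels in the paired contrast, which is the
  point of pairing;
- planted differential features (1% of features) carry a true effect with
  random sign and magnitude `U(2.2, 3.2)` log2 units; the observed BE class
  effect is `0.7 x` that (a single multiplicative ratio-compression
  factor);
- non-BE control samples carry a field-effect offset of 0.6x the compressed
  magnitude with an *independent* random sign per feature.  Adjacent mucosa
  from BE patients differs from truly normal epithelium along its own
  molecular direction; geometrically, if the healthy-vs-adjacent offset
  were a scalar multiple of the BE axis, correlation-distance clustering
  could not separate three collinear class profiles at any noise level;
- technical noise `~ N(0, sigma_f)` with per-feature variances drawn from a
  scaled inverse-chi-square prior around `0.25` log2 units (prior df 8) —
  the variance heterogeneity across peptide features that empirical-Bayes
  moderation exists to handle;
- cells go missing independently with probability
  `logistic(3.0 - 0.3 x value)` (~2% overall, concentrated at low
  abundance); localization probabilities are a mixture of `U(0.7, 1]`
  (weight 0.85) and `U(0, 0.7)`;
- cohort sizes mirror the emulated design: a discovery plex with 3 BE
  patients (BE+ADJ pairs) and 2 controls (two normal biopsies each), a
  validation plex with 2 BE patients and 3 controls; 6,000 proteins and
  6,000 phosphosites, matching the scale at which the top-1% signature has
  ~50 members;
- planted gene sets (3 of 50) draw ~80% of their members from
  same-direction differential proteins; active kinases (3 of 20) draw their
  10 substrates from same-direction differential sites.  Decoy kinases draw
  substrates from *unaffected* sites only — they model kinases whose
  substrate programs are untouched, so the false-positive rate among decoys
  measures specificity rather than chance contamination by planted sites;
- the correlated transcriptome cohort (7 BE vs 7 normal, mirroring a small
  paired expression study) gives each differential gene a transcript effect
  `rho * beta + sqrt(1 - rho^2) * eps` (rho = 0.8, eps scaled to the spread
  of the protein effects); non-differential genes stay null at the mRNA
  level.

Both cohorts share the planted biology but have independent patients and
noise — this is what makes cross-cohort validation meaningful.  All
randomness flows from a single integer seed through named generators; the
same seed reproduces every output bit-for-bit.

What the generator does **not** emulate: peptide-level structure and
protein inference, interference/co-isolation structure in reporter ions,
correlated missingness between sites of one protein, batch effects beyond
per-channel scaling, and biological covariance between features (features
are independent given the class).  Passing tests therefore demonstrate that
the statistical machinery is correct and calibrated under the stated model,
not that the model captures every property of real biopsy data.

## Numerical choices

- Trigamma inversion by Newton iteration from `x0 = 0.5 + 1/y` with
  closed-form guards for extreme arguments; convergence tolerance 1e-10
  relative.
- Quantile-normalization reference = row-wise means of column-sorted
  values; written TSV floats use `%.17g` so re-reading reproduces IEEE
  doubles exactly (parsing uses correctly-rounded `float()`).
- GSEA null sampling draws with replacement and redraws the few rows
  containing duplicates; null distributions are cached per set size within
  one call.
- Clustering requires a complete matrix and errors on zero-variance sample
  profiles instead of producing undefined correlations.
- The pipeline derives one child seed per stage from the master seed via
  `numpy.random.SeedSequence.spawn`, so stages are independently
  reproducible; manifests record seeds, parameters and input digests but
  never wall-clock times, making whole runs byte-reproducible.

## Known limitations

- The empirical-FDR floor at plex-scale pair counts, discussed above.
- Complete-case filtering discards ~15% of features per cohort at default
  missingness; with informative (abundance-dependent) missingness this
  slightly biases the analyzed set toward abundant features.
- Phosphosite statistics are confounded with parent-protein abundance by
  design (no protein-level adjustment).
- The unpaired contrast assumes equal within-class variances after
  patient-level averaging; classes whose units are means over different
  replicate counts violate this mildly.
- Kinase inference is only as good as the curated substrate map; motif
  evidence is not used.
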