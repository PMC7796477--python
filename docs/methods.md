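# Methods

This note documents the statistical machinery, the synthetic-data model, the
numerical choices, and the design decisions taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scales and differential testing

Methylation is analysed on two linked scales. The beta value
β = meth/(meth+unmeth+offset) is the interpretable methylation fraction
(offset default 100, the usual array regularisation); betas are clipped to
[1e−6, 1−1e−6] so the M-value M = log2(β/(1−β)) stays finite. All linear
modeling runs on M (approximately homoscedastic); all effect-size filters
(Δβ) use differences of group-mean betas, because a fixed Δβ means the same
amount of methylation change anywhere in the range.

The shared two-group engine fits per-feature means and a pooled residual
variance with d = n_A + n_B − 2 degrees of freedom. With moderation on (the
default), residual variances are shrunk toward a prior estimated by
method-of-moments on the log residual variances: writing
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2)
determines the prior degrees of freedom d₀ (via the inverse trigamma,
solved by Newton iteration) and the prior variance s₀²; the posterior
variance is the usual weighted combination (d₀s₀² + d s²)/(d₀ + d) and the
moderated t has d + d₀ degrees of freedom. When the log-variance spread is
no larger than its sampling noise, d₀ = ∞ and all features share s₀².
The test suite verifies this implementation against the reference R
implementation (limma) to 1e−6 and the unmoderated path against the
closed-form pooled t to 1e−10. Zero-variance features are flagged, not
dropped; 0/0 t statistics are defined as 0 (p = 1).

Multiple testing is Benjamini–Hochberg, applied within one analysis run
over exactly the features tested in that run. Probe-level DM filters use
the raw p (the cascade thresholds are stated as p-value cuts); fMET and DEG
selection use the BH-adjusted p. All thresholds are strict inequalities.

## The cascade

Per-regimen DM probes (raw p < 0.05, |Δβ| > 0.1 by default) are restricted
to promoter probes — region classes TSS1500, TSS200, 5'UTR, 1stExon,
configurable — and summarised to genes by the minimum-p promoter probe,
with ties broken by larger |Δβ| then lexicographic probe id. A probe
annotated to several genes contributes to each of them (so gene count can
exceed probe count; the alternative, nearest-gene-only, is deliberately not
used because the annotation's gene/region pairs already restrict the map to
promoters).

fMET detection regresses log2 expression on the unweighted mean promoter
beta (median and most-variable-probe aggregation are available); R² of the
simple regression equals the squared Pearson correlation, and the inverse
direction is enforced through the slope sign since R² is direction-blind.
The regressor stays on the beta scale — bounded and interpretable — with the
M scale available by transforming the input.

The regimen cascades intersect DM genes with fMET genes and apply the
stringency tiers (FOLFOX p < 0.01, Δβ > 0.2, R² > 0.5; FOLFIRI p < 0.05,
Δβ > 0.1, R² > 0.5), hypermethylated-in-resistant direction only. The
refine step clusters the reference cohort on the candidates (Ward linkage,
Euclidean distance, sample vectors of promoter-probe M-values), labels the
cluster with larger mean signature beta "hyper", re-tests each candidate
hyper vs hypo at gene level, and keeps genes with p < 0.05 and either
Δβ > 0.2 or M-scale logFC > 1 (signed, hyper-in-hyper-cluster). Expression
plays no role in the refine step; expression logFC enters only the DEG
analysis. Per-regimen signatures are combined by set union with per-gene
provenance.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines; ties use the standard hypergeometric variance at tied event
times and censoring at an event time counts after the event. The wrapper
returns p = 1 with a warning when no events exist. OS, RFS and EFS are
three independent runs; no multiplicity correction across endpoints, since
each endpoint is reported separately. Tests verify the product-limit
estimate against hand computation and the empirical survival function
(no censoring), the log-rank statistic against a textbook O−E/V computation
to 1e−10, and the rejection rate against scikit-survival.

## Enrichment and overlap testing

Over-representation is the upper-tail hypergeometric P(X ≥ k) per gene set,
sets intersected with the background first, BH within each collection. The
default background is the tested universe (all genes in the relevant
matrix); the full array universe can be supplied instead. Positional sets
group genes by chromosome arm (arm from the annotation or a cytoband file),
dropping arms below a minimum size (default 10).

For m ≥ 3 gene lists the total-intersection p-value is computed exactly:
with sets of fixed sizes n₁…n_m drawn independently and uniformly from a
background of N genes, the running intersection size after adding a set of
size n_i is hypergeometric given the previous size, so the pmf of the m-way
intersection follows by sequential convolution; the support is trimmed to
min(previous support, n_i) at each step. m = 2 reduces exactly to the
hypergeometric tail, and the three-set pmf is validated against direct
enumeration (N = 3) and 200,000-draw Monte-Carlo (N = 20).

## CIMP classification

Two classifiers over a configurable marker panel (≥ half the panel must be
present; samples below 50% panel coverage are labeled unclassified):

* `cluster3` (default): Ward/Euclidean 3-cluster cut on the panel **beta**
  values, clusters ranked by mean panel beta into CIMP-H / CIMP-L /
  no-CIMP. Beta, not M, is deliberate: Euclidean distance on M-values
  blows up the variance of markers near the 0/1 boundaries (the logit's
  derivative is 1/(β(1−β))), letting an unmethylated stratum dominate
  Ward's objective — in simulation it splits the no-CIMP stratum and merges
  H with L, while beta-scale clustering recovers the planted strata
  essentially perfectly.
* `threshold`: a marker is methylated at β > 0.3; > 60% methylated markers
  → CIMP-H, 20–60% → CIMP-L, else no-CIMP. The constants are documented
  conventions exposed as parameters, and the rule is monotone in every
  marker beta.

Neither variant claims to reproduce any specific published panel's calls;
the panel is an input. Association between CIMP status and signature
clusters uses the two-sided Fisher exact test (sum of hypergeometric
probabilities ≤ that of the observed table), validated against exhaustive
enumeration for all tables with N ≤ 30. The prognostic comparison runs the
same survival machinery per stratifier per endpoint, binarising CIMP as
CIMP-H vs rest for the two-group test.

## Synthetic cohorts

The generator emulates the structure the cascade assumes, with one master
seed driving deterministic per-block substreams (structure, methylation,
expression, clinical, gene sets), so identical seeds give bitwise-identical
cohorts.

Design defaults mirror the targeted study design: two regimen datasets
(16 resistant + 4 sensitive; 8 + 8) profiled for methylation only, and a
33-sample reference cohort (22 hypo / 11 hyper) with paired expression and
survival. 300 genes with 2 promoter probes each, ~90 gene-body probes, and
a 10-probe CIMP panel (700 probes total). Null probes sit at baseline
β = 0.30; planted fMET genes have promoter β = 0.20 in hypo/sensitive
samples, elevated by Δβ = 0.40 in the hyper cluster (and, for signature
genes, in the resistant arm of their regimen). Noise is truncated Gaussian
with sd 0.05 (clipped to (1e−4, 1−1e−4)); a Beta-distribution mode with
matched mean and variance is available. The truncated-Gaussian default
exists because every cascade threshold is defined on mean beta differences,
which this noise model controls directly.

Expression for planted genes is baseline + slope × (realised promoter
beta) + Gaussian noise, slope −4 log2 units per unit beta and noise sd 0.3
(at the default cluster gap this yields R² ≈ 0.85, comfortably above the
0.5 cascade cut while leaving realistic scatter); null genes' expression is
independent of methylation. The planted signature splits 5 + 4 genes across
the two regimens with one shared gene (union 8).

Survival is exponential — memoryless, so the planted hazard ratio (default
3, poor-prognosis = resistant or hyper-cluster samples) has a closed form
checked by large-n simulation — with independent exponential censoring
tuned to a 30% censoring fraction via μ = λ̄·c/(1−c). Endpoint baselines:
median 24 (OS), 18 (RFS), 15 (EFS) months. CIMP strata (means
0.7/0.4/0.1, probabilities 0.15/0.25/0.60) are assigned independently of
the clusters, which is what makes the stratifier-comparison study a fair
race between a real and a random prognostic factor.

What the generator does **not** emulate: array chemistry and probe
cross-hybridisation, batch effects, bimodal genome-wide beta landscapes,
cell-type composition, correlated probes beyond shared gene means, and
non-proportional hazards. Passing tests therefore demonstrate that the
pipeline's logic and statistics behave correctly under the assumed model,
not that the thresholds are optimal for any particular real cohort.

## Numerical and degenerate-input choices

* Betas clipped at 1e−6 for the M transform; read validation tolerance
  1e−9 on the [0,1] bounds.
* Probes with > 20% missing betas are dropped (logged); remaining NAs are
  mean-imputed per probe (logged) so downstream fits keep a common df.
* p-values are floored at the smallest positive double and capped at 1.
* Ward clustering requires ≥ 2 features, ≥ 4 samples, errors on
  all-identical samples, and breaks the hyper/hypo label by strictly larger
  mean signature beta.
* `cascade_select` returning an empty list is a valid (warned) outcome;
  an empty combined signature is an error.
* Gene identity is case-sensitive symbol match; symbol harmonisation
  between platforms is out of scope. Annotation harmonisation intersects
  probe ids and keeps the second (reference platform) argument's records.

## Problem sizes used in validation

The operating-characteristic studies run at the scale of the targeted
design: 100 cascade replicates for signature recovery, 50 cohorts of 500
genes for fMET error rates, 1000/500 replicates for log-rank calibration
and power, 200,000 Monte-Carlo draws for the multi-set check, 100 fixtures
for the exhaustive clustering oracle, and 200 replicates for the
stratifier comparison. These sizes give binomial standard errors well below
the margins being asserted while keeping the whole suite fast enough to run
routinely.
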