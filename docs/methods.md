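# Methods

`alpzone` re-implements, as a tested library plus numbered analysis drivers,
the post-sequencing analysis chain of a soil-eDNA metabarcoding survey of
green algae (Chlorophyta) along Alpine elevational gradients: MOTU-table
quality control, Hill-number diversity along discretised gradients, community
turnover by constrained ordination, robust marker-vs-marker regression, and
Outlying-Mean-Index (OMI) niche inference with a dual permutation criterion
for specialization. Because no sequencing accessions accompany such surveys,
all analyses are exercised end-to-end on a synthetic study generator whose
design mirrors the field protocol.

## The synthetic study

**Design.** Five sites whose ~1,000 m elevational sub-ranges tile
1,250–2,940 m in 200 m steps; at every site × elevation level, two soil
horizons (litter, deep) are sampled and each sample is amplified in PCR
triplicate. Extraction blanks, PCR blanks and positive controls (each also in
triplicate) accompany the samples. The positive controls carry a 13-species
mock community whose concentrations halve from one species to the next
(c_i ∝ 0.5^(i−1)), giving the analytic diversity benchmark
¹D → exp(2 ln 2) = 4 in the infinite-series limit (3.9957 for 13 terms).

**Environment.** Elevation is fixed by the design; the other continuous
variables (pH, Nitrogen, Carbon, C/N ratio, organic matter, freezing degree
days FDD, climatic water stress CWD, diurnal temperature range DTR) are drawn
from a Gaussian copula conditioned on the standardised elevation, so any
positive semi-definite correlation matrix can be imposed. The default matrix
comes from a two-factor loading structure (an elevation/climate factor and a
soil-fertility factor); it makes the fertility block (Nitrogen, Carbon,
organic matter) collinear enough (r ≈ 0.8–0.9) that iterative VIF selection
has real work to do, typically removing Carbon and sometimes organic matter.
Litter rows get a +0.7 sd fertility shift; Environment is forest below
1,800 m, open-area above.

**Abundance model.** Each taxon is a generalist (flat response) or a
specialist with a Gaussian response curve over Elevation and pH. Relative
abundances are built from two fixed read budgets: generalists share
`1 − specialist_budget` (default 0.5) of the community in constant
proportions, and specialists split the rest proportionally to their responses
at the sample's environment. This constant-budget construction matters: if
raw response curves are simply normalised per sample, the pooled specialist
share varies along the gradients (it is depleted near the gradient ends,
where fewer optima fall) and compositional renormalisation then couples
*every* taxon — including flat generalists — to the environment. Generalists
would be genuinely environment-associated in relative-frequency space and any
honest niche test would flag them. With constant block budgets, generalist
relative frequencies are exchangeable across samples up to sequencing noise,
which is the null the specialization tests are calibrated against. For the
same reason, specialist optima are drawn from the gradient extended ±300 m
past the sampled range (the standard coenocline-simulation device against
boundary depletion), and the class-specific niche shifts (Chlorophyceae
+300 m / +0.6 pH vs Trebouxiophyceae −40 m / −0.08, giving the two dominant
classes distinct niche centres) are chosen mean-zero under the default class
mix so they do not tilt the pooled specialist share.

**Reads.** Per PCR, the total depth is lognormal around `depth_mean`
(default 20,000 reads, log-sd 0.3) and counts are Dirichlet-multinomial
around the expected proportions with concentration 1/`depth_dispersion`. The
default dispersion 0.005 (α₀ = 200) reflects the very high replicate
reproducibility such surveys report for their positive controls (mock ¹D
standard deviations of order 0.01 across dozens of replicates);
`depth_dispersion = 0` collapses to a plain multinomial. A `fail_rate`
fraction of sample PCRs is forced below 100 reads (ground truth recorded in
the PCR table). Contaminant MOTUs receive Poisson(`contaminant_intensity`)
reads in every blank and a small constant spillover share (10⁻³) in samples;
blanks carry nothing else by default (`blank_leak_mean` adds community
leakage if wanted). Positive controls contain only the mock MOTUs. Class
labels follow the read-share proportions reported for the four Chlorophyta
classes in alpine soil (82.3 / 11.1 / 1.6 / 0.02 %, renormalised), and an
`offtarget_fraction` of taxa are non-Chlorophyta (exercising the clade
filter).

**What the generator does not emulate.** Sequence-level error (chimeras, tag
jumps, point errors), taxonomic misassignment, spatial autocorrelation within
sites, horizon effects on *diversity* (only fertility covariates shift with
horizon), seasonal or temporal structure, and genuinely absent taxa
re-detected through database artefacts. Passing tests therefore show the
table-level pipeline recovers what this model encodes, not that it would be
equally well calibrated against every pathology of real metabarcoding data.

## Quality control

Filters run in a fixed order — length → rarity → clade → contaminants →
failed PCRs → replicate outliers — each returning a reconciled report:

* **Length**: inclusive bounds per marker, 65–200 bp (Chlo01, Euka03) and
  65–130 bp (Chlo02).
* **Rarity**: a MOTU must exceed 10 reads in at least one PCR (a peak of
  exactly 10 is discarded).
* **Clade**: the MOTU's taxonomic path must contain the marker's target clade
  (ancestor membership counts).
* **Contaminants**: a MOTU is removed when its maximum abundance across
  negative controls strictly exceeds its maximum across sample PCRs; the
  default metric is the within-PCR relative frequency, because blank depths
  are orders of magnitude below sample depths (raw-read mode available).
* **Failed PCRs**: a PCR must total at least 200 reads (Chlo01/Chlo02) or
  1,000 (Euka03), threshold inclusive. The source protocol's wording inverts
  this ("more than … considered unsuccessful"), which contradicts its purpose
  of discarding unreliable PCRs; the threshold is therefore interpreted as a
  minimum, with the direction configurable.
* **Replicate outliers**: per sample, each replicate profile is
  Hellinger-transformed (square roots of within-PCR relative frequencies) and
  its Euclidean distance to the unweighted barycenter of the sample's
  replicates is pooled across samples; replicates beyond Q3 + 1.5·IQR (Tukey
  fence, configurable; quantile rule available) are flagged.
* **Aggregation**: samples become the mean of their retained replicates'
  relative-frequency vectors, renormalised to sum 1.

## Diversity

Hill numbers ^qD = (Σ pᵢ^q)^(1/(1−q)), with q = 1 as exp(−Σ pᵢ ln pᵢ)
(0·ln 0 = 0); the implementation is continuous at q = 1 and invariant to
zero-padding. β = γ/α with α the mean per-unit ¹D and γ the ¹D of the pooled
community; pooling weighs units equally (mean of frequency vectors), matching
α's equal weighting. Diversity is computed per PCR by default (per-sample
mode available). Gradients are discretised into seven equal-width slices over
the observed range (equal-count mode available); the association is the
between-slice ANOVA R², significance is Kruskal–Wallis, and p-values are
Benjamini–Hochberg-adjusted across variables. Slice means carry normal 95%
CIs (±1.96·SE). Two-level contrasts (litter vs deep, forest vs open) use the
two-sided tie-corrected Mann–Whitney test.

## Ordination

* **VIF selection**: VIF = 1/(1−R²) of each variable on the others;
  iteratively remove the largest until all ≤ 5. Ties break deterministically
  (larger VIF, then alphabetical); perfect collinearity (VIF = ∞) is removed
  first.
* **Hellinger + PCoA**: Euclidean distances on the Hellinger-transformed
  community, embedded by classical scaling (via scikit-bio); negative
  eigenvalues are reported, their axes dropped.
* **Partial RDA**: predictors are centred/scaled; the community and predictor
  blocks are residualised on the conditioning block (Site by default;
  categoricals as treatment contrasts), the community is regressed on the
  predictors, and the fitted values eigendecomposed. Constrained R² is the
  fitted fraction of conditioned variance; adjusted R² uses Ezekiel's
  1 − (1−R²)(n−1)/(n−m−1). The permutation p permutes rows of the
  *residualised* community (reduced-model permutation) with the
  include-observed convention; the statistic is the constrained R², monotone
  in the pseudo-F at fixed degrees of freedom and hence equivalent.
  Predictors aliased by the conditioning block raise a named error.
* **Stepwise selection**: greedy forward addition of the candidate with the
  lowest marginal permutation p (< 0.05), then backward removal of any
  selected variable whose marginal p exceeds the threshold, until stable;
  deterministic under a fixed seed. With k independent noise candidates the
  family-wise forward addition rate is ≈ 1 − (1−α)^k; calibration tests use
  two candidates.
* **Variance partitioning**: each selected variable's partial adjusted R² is
  the full-model adjusted R² minus that of the model without it (conditioning
  fixed); negative partials are reported unclipped.
* **Marker regression**: Tukey-bisquare IRLS (c = 4.685, MAD scale, via
  statsmodels RLM) on log₁₀ frequencies, pairs with a zero in either marker
  excluded and counted; the weighted R² is reported. The paired-marker
  generator shares a per-sample lognormal clade-abundance factor between the
  two markers — without it the constant-budget design keeps the clade
  fraction near-constant across samples and the regression would have nothing
  to fit.

## Niche inference

Environmental variables are standardised (zero mean, unit variance,
population scaling) over samples. For a taxon with normalised abundance
weights w over samples at standardised positions zᵢ:

* niche centre c = Σ wᵢ zᵢ; **marginality** = ‖c‖²;
* total **inertia** = Σ wᵢ ‖zᵢ‖²;
* **marginal tolerance** = Σ wᵢ (zᵢ·u − ‖c‖)² with u = c/‖c‖ (variance along
  the marginality axis);
* **residual tolerance** = inertia − marginality − marginal tolerance.

The decomposition is exactly additive; when c = 0 the marginality axis is
undefined and the marginal tolerance is set to 0 (residual = inertia). A
taxon in a single sample has zero tolerances and is flagged degenerate.

**Dual specialization criterion.** Null distributions come from permuting the
taxon's weight vector across samples (n = 999 by default) — equivalent under
exchangeability to permuting sample rows, and simpler to vectorise.
p_marginality is the upper tail (marginality larger than expected),
p_tolerance the lower tail (marginal tolerance *smaller* than expected),
both with the include-observed convention (minimum attainable p =
1/(n_perm+1)). A taxon is specialized when either p ≤ α = 0.05. The two
rejections are nearly disjoint under the null, so the union fires at ≈ 2α on
null taxa — tests of this rate use binomial confidence intervals against the
[α, 2α] band rather than the raw Monte-Carlo realization. Note that a
concentrated weight vector inflates its own permutation null (a one-hot taxon
reaches only p ≈ (1 + n_perm/n)/(n_perm+1)), so point niches are *not*
automatically significant unless their sample is environmentally extreme.

**Optimal ranges.** Per taxon and variable, an abundance-weighted Gaussian
KDE (Silverman bandwidth by default) over the sampled values; the peak is the
density argmax, the range the smallest interval around the peak holding 50%
of the weighted density mass (configurable), the median the weighted median.
The Mann–Whitney p compares the taxon's read-weighted positions (weights
expanded to 200 pseudo-observations) against all sampled positions,
two-sided; comparing against all samples (rather than against other taxa) is
the default reading of an under-specified choice. Recovery precision scales
with niche breadth and with the ~200 m granularity of the elevational design:
a sharp specialist (breadth 150 m) is recovered within 100 m in ≥ 90% of
seeded studies, while broad specialists carry proportionally larger errors.
A taxon's realized elevational profile is also tilted by its other niche
axes (pH anticorrelates with elevation, shifting profiles by a few tens of
metres) — a property of the estimand, not an estimator bias.

**Niche PCA.** Specialized taxa are described by the midpoints of their
per-variable optimal ranges; the centred/scaled matrix is decomposed by PCA
(scikit-learn), constant columns dropped, and axis-1 scores compared between
the two designated classes by Mann–Whitney.

## Numerical and reproducibility choices

Every random stage derives its stream from the configuration seed
(`default_rng([seed, stage])`), so identical configurations give bit-identical
tables and every CLI command is byte-deterministic under a fixed `--seed`.
Permutation p-values always include the observed statistic. IRLS converges at
coefficient change < 1e-8 or 50 iterations; a perfect fit (zero scale) keeps
all weights at 1. Eigen-axes with eigenvalues ≤ 10⁻¹² of the leading one are
dropped. The OMI decomposition is asserted additive to 1e-9 in tests.

## Problem sizes

The test-suite simulations use the default study (60 samples, 60 taxa,
~200 PCRs) and scale Monte-Carlo layers as: 500 replicates for the
Kruskal–Wallis and RDA-permutation uniformity checks (KS at α = 0.01), 1,000
null taxa for the dual-criterion rate, and 50 seeded studies for the
recovery experiments; permutation counts are 199–999 depending on the layer.
These sizes put Monte-Carlo standard errors well below the tested margins.

## Known limitations

* The pipeline starts at the MOTU table: no read assembly, dereplication,
  denoising, or taxonomic assignment.
* The OMI tolerance test has modest power for specialists whose optima sit at
  the centre of the environmental space in *every* variable; the dual
  criterion mitigates but does not remove this.
* Adjusted R² uses the Ezekiel correction with m = number of predictors,
  ignoring degrees of freedom absorbed by the conditioning block; partials
  may be slightly conservative for many-level conditions.
* The contaminant rule compares maxima, so a true contaminant that amplifies
  more strongly in one sample than in any blank escapes removal; the
  generator's spillover is kept below that regime.
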