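# Methods

`hepatox` implements the computational arc of an in-vitro hepatotoxicity
study on stem-cell-derived hepatocyte-like cells: an LDH-release
cytotoxicity screen with dose-response modelling, targeted-RNA-seq
concentration-response differential expression, stress-pathway
overrepresentation, co-expression module analysis, candidate-gene
selection, and a cross-model fold-change concordance benchmark. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic data do and do not establish.

## Cytotoxicity and dose-response

Percent cytotoxicity is computed from 490-nm absorbances against untreated
(NC) and fully lysed (PC) control wells,

    cytotoxicity % = 100 * (A_sample - A_NC) / (A_PC - A_NC),

so the statistic is anchored at 0% and 100% at the controls, may leave
[0, 100] for wells beyond them, and is invariant to a common rescaling of
all absorbances (gain changes of the reader cancel).

Dose-response curves are four-parameter logistic (4PL) on natural
concentration scale,

    f(x) = c + (d - c) / (1 + (x/e)^(-b)),

with lower/upper asymptotes `c`, `d` (%), inflection `e` (uM) and hill
slope `b` (b > 0 rising). Keeping the dose axis natural (no log transform)
makes x = 0 well defined: the vehicle maps exactly to the lower asymptote.
Fitting is bounded trust-region least squares initialised at
c0 = min(y), d0 = max(y), b0 = 1, e0 = geometric mean of the positive
doses; all-identical responses short-circuit to a flagged flat fit. ICx is
the analytic inverse `e * ((d-c)/(x-c) - 1)^(-1/b)`, defined only for
converged fits and x strictly between the asymptotes.

A chemical is called *acutely cytotoxic* when (i) the 4PL fit beats a
constant-mean model in an extra-sum-of-squares F-test (3 vs n-4 df) at
p < 0.05 and (ii) the fitted maximal response reaches 10% cytotoxicity.
The paper-scale studies report this call only qualitatively, so both
thresholds are exposed (`f_alpha`, `min_response`); the 10% floor exists to
keep statistically detectable but biologically trivial slopes from being
called toxic.

## Differential expression

Counts are normalised with median-of-ratios size factors (reference: the
per-gene geometric mean over samples, computed on zero-free genes; fallback
to total-count ratios when no zero-free gene exists), scaled to geometric
mean 1. Expression for visualisation and networks is
log2(CPM + 1) with library size = column sum; the pseudocount of 1 pins
zero counts to exactly 0.

Per gene and chemical we fit a negative-binomial GLM with log link,

    log mu_s = b0 + beta * conc_s + log(sf_s),

i.e. expression modelled as a linear function of the micromolar treatment
concentration (a `log_conc` covariate option exists but is off by default,
matching the modelled form). The slope is reported in log2 units per uM.
Significance is a Wald test (normal reference) with Benjamini-Hochberg
step-up adjustment across genes; the DE set is `p_adj < 0.05` by default.

Dispersion is a per-gene method-of-moments estimate pooled across
concentration groups: with df-weighted within-group variance s^2 and grand
mean m of the size-factor-normalised counts, alpha = max(0,
(s^2 - m)/m^2); alpha = 0 degenerates to the Poisson family. There is no
cross-gene shrinkage — a deliberate simplification relative to
shrinkage-based DE tools, so gene-count-level agreement with such tools is
not promised. The plug-in dispersion makes the Wald statistic behave like a
t variable with roughly the pooled within-group degrees of freedom; with
the default calibration design (5 concentrations x 6 replicates, ~25 df)
the null rejection rate at p < 0.05 measures ~0.056, inside the accepted
[0.03, 0.07] band. Designs with very few replicates (e.g. 2 per
concentration) leave too few degrees of freedom for any plug-in dispersion
estimate and will be anti-conservative; that is a property of the method,
not a bug to patch silently.

Heatmap input is built by taking the k = 20 smallest adjusted p-values
(ties broken by larger |slope|, then gene id), averaging each gene's
log2CPM over replicates per concentration, and standardising each row to
mean 0, SD 1 (sample SD) across concentrations.

## Pathway overrepresentation

For a probe universe of size N with R differentially expressed probes
(unadjusted p < 0.05 — the overrepresentation statistic's own DE
definition; switchable to adjusted) and a pathway annotating n probes of
which r are DE,

    z = (r - nR/N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) ),

the observed overlap standardised by the exact hypergeometric mean and
variance. The implementation is guarded by an exhaustive equivalence test
against `scipy.stats.hypergeom` moments for every configuration with
N <= 60. Degenerate configurations (R = 0, R = N, n = 0) have zero null
variance and are returned flagged rather than infinite. |z| >= 1.96 is
treated as significant (two-sided 5%); a one-sided option exists because
the field sometimes thresholds on z alone. Enrichment profiles recompute
DE flags per vehicle-vs-concentration contrast so the z trajectory over
concentration is interpretable as a dose-dependent pathway response.

Note that depletion is informative too: when the DE set concentrates in
one planted pathway, unrelated pathways legitimately show strongly
negative z.

## Co-expression modules

The network is signed: a_ij = ((1 + cor_ij)/2)^power with Pearson
correlation across samples, so anticorrelated genes get adjacency ~0
rather than being conflated with correlated ones. The soft-threshold power
is the smallest candidate (1..12) whose connectivity distribution is
approximately scale-free (R^2 >= 0.8 with negative slope in the log-log
bin-frequency regression, 10 bins), falling back to 12. Gene similarity is
the topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

and modules come from average-linkage hierarchical clustering of 1 - TOM
with a fixed-height cut at 0.99 of the maximal merge height — deterministic
and testable, in place of dynamic tree-cut heuristics. Clusters below
`min_module_size` (default 20) are labelled `unassigned`. Detected modules
whose eigengenes correlate above 0.9 are merged in a single
connected-components pass, preventing trivially split blocks. Labels
M1, M2, ... are assigned by each module's lowest gene position, making the
labelling permutation-consistent.

The module eigengene is the first principal component of the
gene-standardised module submatrix (unit-norm per-sample scores,
sign-oriented so the mean correlation with module genes is positive); kME
is each gene's correlation with its module's eigengene.

Module activity is a rank statistic: per sample, all genes are ranked by
expression and the activity is the mean-rank gap between module and
non-module genes divided by its maximum attainable value (G/2), giving a
score in [-1, 1] that is invariant under any monotone transform of a
sample's expression. It is *not* a kernel-density enrichment score, so it
is validated property-wise (bounds, null centring, dose monotonicity of a
planted module), never by numeric equality with other packages' scores.

## Candidate-gene selection

A gene is selected when it (1) sits in a target module with kME strictly
above 0.65 (strict, because the criterion is "higher than"), (2) shows a
significantly increasing induction — operationalised as slope > 0 with
p_adj < 0.05 for at least one chemical, the only testable reading of
"significantly increasing" — and (3) appears on a curated evidence list.
The selection is exactly the intersection of the three filters (tested as
such) and is monotone in both thresholds. An optional second module
assignment (e.g. from an external reference dataset) imposes the
centrality filter in that dataset too.

## Benchmarking

Fold-change tables are harmonised by (a) translating non-human symbols
through a two-column ortholog table, dropping one-to-many rows in either
direction rather than resolving them arbitrarily, (b) intersecting gene
ids across all tables, and (c) restricting to the gold-standard DE set
(the `de_flag` column, or `p_adj < 0.05` when only statistics are given).
Per gene, the similarity is the signed ratio Si = log2FC_model /
log2FC_gold; the gold-DE restriction guarantees a nonzero denominator (a
zero reaching the ratio is flagged NaN, never silently dropped as 0).
Recovery curves count genes with Si >= t over a 0–2 grid in steps of 0.05;
negative Si never counts as recovered at t >= 0 (directional concordance
is required), and the count at t = 1 is the equal-or-higher-magnitude
summary.

## Synthetic data

The generator emulates the study's data shapes with known ground truth:

- **Plates** — absorbances `nc_abs + (pc_abs - nc_abs) * f4PL(conc)/100`
  plus Gaussian noise (default SD 0.02 AU against a 0.2→1.0 AU control
  span, i.e. ~2.5% cytotoxicity noise), six-point dose series, triplicate
  wells, NC/PC wells included. The default panel is 4 responsive chemicals
  (upper asymptote 70–100%, inflection 20–80 uM) and 10 flat ones,
  mirroring the screened panel of 14.
- **Counts** — negative binomial with variance mu + alpha*mu^2;
  mean = library factor x baseline x 2^(effect x conc) x module factor.
  Within-module correlation comes from a shared log-normal latent factor
  per (module, sample) with unit mean (`exp(sd*z - sd^2/2)`, default
  sd 0.3). Study-scale defaults: 600 genes in 6 modules, dispersions
  log-uniform in [0.01, 0.2], baselines log-uniform in [50, 2000], library
  sizes log-normal with CV 0.2, effects planted in two stress-pathway gene
  sets (ATF4- and XBP1-branch) at 0.05 log2FC/uM for the cytotoxic
  chemicals — 1 log2FC at the 20 uM top dose. The dispersion and
  library-size ranges are field-typical defaults, not measurements of any
  particular assay.
- **Benchmark tables** — model log2FC = scale x gold + N(0, noise), with
  optional foreign-symbol renaming plus the matching ortholog table, so
  the Si distribution and recovery behaviour are controlled exactly.

All generators take an explicit integer seed and are bit-reproducible;
the pipeline derives per-stage seeds from one root seed via
`numpy.random.SeedSequence`.

What passing on synthetic data does *not* show: the generator has no
probe-level hybridisation effects, no batch structure, no outlier samples,
and its module correlation is exchangeable within modules — real
TempO-Seq data violate all of these, so calibration and sensitivity
results here bound idealised, not field, performance.

## Problem sizes and runtime

Defaults are desk-scale by design: the demo pipeline uses 300 genes x 70
samples (7 chemicals x 5 concentrations x 2 replicates) and completes in
well under a minute on one CPU; null calibration uses 2000 genes; module
recovery uses two planted 50-gene blocks over 24 samples. All sizes are
constructor arguments and scale up linearly in genes x samples, with the
per-gene GLM (~2 ms/fit) dominating.

## Known limitations

- No dispersion shrinkage, independent filtering, or fold-change
  moderation; DE gene counts will differ from shrinkage-based tools,
  especially at 2 replicates.
- Fixed-height tree cut can split or lump modules that dynamic cutting
  would resolve; the eigengene-correlation merge mitigates but does not
  eliminate this.
- The rank-based activity score compresses extreme expression shifts
  (ranks saturate); it is a robust order statistic, not an effect-size
  estimate.
- Time is carried through the design but the GLM models concentration
  only, matching the modelled form; time-course inference is out of scope.
- Size factors inherit composition bias when a large planted fraction of
  the panel responds in one direction.
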