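# Methods

## Model and procedure

The object of analysis is a beta-value matrix `B` (probes × samples,
entries in [0, 1], missing allowed) with a donor age per sample.  The
pipeline asks, per CpG marker, whether its methylation level changes with
age by a large *relative* amount — without assuming the change is linear —
and then characterises the shape of the change.

**Age groups.**  For each integer year `y` from ⌊min age⌋ to ⌈max age⌉, the
group `G(y)` holds the `k = ⌈0.1·n⌉` samples nearest to `y` in age
(ties broken by ascending sample index, so results are platform-
independent).  Equal group sizes mean every year is represented by the same
amount of data regardless of the cohort's age density; the cost is that in
sparse age ranges a group can reach far from its nominal year.  Groups
whose median member age differs from `y` by more than the edge tolerance
(default 2.0 years) are discarded; the surviving years form the analysis
age range.  The tolerance is a package choice: the grouping rule only
determines which years are *trustworthy*, and 2 years keeps dense uniform
cohorts intact while discarding the sparse extremes.

**Running medians.**  The trajectory of marker `m` is
`m(y) = median{B[m, s] : s ∈ G(y)}` over retained years (median, not mean,
for robustness to single-sample outliers; even counts use the mean of the
two middle values).  Missing entries are excluded per marker-year and the
usable count recorded.

**Selection statistics.**  With `m⁻ = min_y m(y)` at year `y⁻` and
`m⁺ = max_y m(y)` at year `y⁺`:

- maximum fold change `FC = m⁺ / max(m⁻, ε)`, ε = 1e−6; tracks whose
  minimum falls below ε are flagged `epsilon_guarded` so the inflated
  ratio is auditable;
- maximum absolute change `Δβ = m⁺ − m⁻` (the same two years realise both
  extremes, so one test serves both selections);
- a two-sided Welch t-test between the raw betas of `G(y⁻)` and `G(y⁺)`
  (pooled-variance t available via `equal_var=True`);
- Benjamini–Hochberg adjusted `q` over all markers in the run;
- spread filter: mean over retained years of (group SD, ddof 1) / (group
  median); markers above 0.5 are excluded.  A zero median makes the ratio
  +∞ and the marker fails.  A `rel_sd_scope="extremes"` switch averages
  only the two extreme-year intervals instead of all retained years.

`fc_pass` requires `q < 0.05`, `FC > 2` (strict) and spread ≤ 0.5;
`abs_pass` requires `q < 0.05`, `Δβ ≥ 0.2` (inclusive) and the same spread
bound; the joint selection is their conjunction.  The differing strictness
of the two thresholds is deliberate and matched to the selection rules'
definitions.

**Pearson baseline.**  For contrast, each marker's raw betas are correlated
with age (r, p from the t transform with n−2 df, BH-adjusted).  Zero-
variance markers get r = 0, p = 1 by convention.  The baseline makes the
central point observable: a marker drifting 0.01% beta/year over a century
has r = 1.0 yet FC ≈ 1.1 and Δβ = 0.01 — far below either change
threshold.

**Gradients.**  Selected tracks are normalized by their own maximum (so
relative change rates are comparable), differentiated with plain central
differences on the retained-year grid (one-sided at the ends; the scheme is
exact on linear tracks and handles uneven grids after trimming), and
clustered with k-means (10 restarts, fixed seed).  The cluster count is a
run parameter; a t-SNE embedding of the gradients plus a silhouette-based
suggestion over k ∈ 2..6 (falling back to 1 for degenerate input) is
computed as an advisory diagnostic, never applied silently.  Clustering
uses the raw normalized gradients; Savitzky–Golay smoothing (window 21,
order 2, polynomial edge extension; the window shrinks to the largest valid
odd size on short tracks) is for reporting only.

**Overlap significance.**  For a selected set of size `n` sharing `x`
markers with a reference set of size `D` in a universe of `N` probes, the
tail `P(X ≥ x)`, `X ~ Hypergeometric(N, D, n)`, is summed in log-space
from log-gamma binomial terms (array universes of ~5·10⁵ overflow naive
factorials), truncating once terms fall below 1e−18 of the running total
past the mode.  When `p ± 2√(pq/n) > 0` (p = D/N) and `10·n < N`, a
continuity-corrected normal approximation is used instead:
`Z = |x − 0.5 − n·p| / √(npq)`, upper tail `(1 − erf(Z/√2))/2`.  The
universe `N` must always be supplied explicitly — the tool never infers it
from a matrix, because the appropriate universe (pre- or post-QC probe
count) is a scientific choice.

**Age prediction.**  A random-forest regressor (100 trees, unlimited
depth, bootstrap, squared-error criterion, all features per split — the
classic library defaults, deliberately untuned) is evaluated by shuffled
5-fold CV: per fold, missing features are imputed with the *training*
fold's per-marker median, the forest is fit on 80% and scored on the held-
out 20% (mean absolute error in years; fold-wise Pearson r).  The ± value
reported with the CV error is the SD across folds.  External linear clocks
are applied as `intercept + Σ coef·beta` with an optional piecewise
log-linear inverse age transform (`adult_age` 20).  The mean signed error
among samples above the 0.9 age quantile summarises old-age bias; with
saturating trajectories any linear-in-beta predictor underpredicts there,
while a forest on fold-change-selected markers is less biased — a property
the test suite reproduces over replicate synthetic cohorts.

## Quality control

Probe filters: user-supplied blacklists (SNP-overlapping, cross-reactive;
plain text, one id per line) and a missing-value rule that removes probes
with **more than** 10 missing entries (strictly greater).  Beta values are
never normalized across samples; the pipeline consumes them as deposited.

Sample outliers: each sample is scored by the mutual information between
its beta profile and the cohort mean profile, probes paired positionally,
both vectors binned into 10 equal-width bins on [0, 1] (plug-in estimator
on the 10×10 joint histogram, nats).  A sample is flagged iff its score is
below mean − 3·SD of the cohort's scores (one-sided: only *low* MI marks a
broken profile; ddof 1 SD; single pass, no re-iteration after removals).
The bin count is exposed as config; 10 bins on a [0, 1]-bounded variable
is the simplest defensible choice and only the cohort-relative comparison
matters.

## Synthetic cohorts

The generator emulates an age-heterogeneous methylation cohort: ages drawn
uniformly or from a truncated Gaussian mixture on [0, 102]; marker
trajectories from four families — constant, linear (`baseline + slope·age`),
logistic saturation (`baseline + amplitude/(1+e^{−steepness(age−midpoint)})`)
and step (`baseline` before the midpoint age, `baseline + amplitude` at and
after) — clipped to [0, 1]; additive Gaussian noise then clipping; missing
entries at random coordinates; outlier samples built by permuting a
sample's values across probes (the marginal distribution is preserved but
probe-wise correspondence is destroyed, which is precisely what the MI
screen detects).  Everything planted is recorded in a truth object.

The standard panel used in tests mixes 850 flat null markers, 100
weak-linear drifts (0.05% beta/year — near-perfect age correlation,
negligible total change) and 50 large-change non-linear markers
(sigmoid/step, baseline 0.1, amplitude 0.3, noise SD 0.03), on 400-sample
cohorts; the QC recovery experiments use 200-sample cohorts with 800
probes spanning baselines 0.05–0.95.  These sizes are small enough to run
the whole suite in minutes yet large enough that group sizes (k = 40 at
n = 400) make medians stable.

What the generator does *not* emulate: array chemistry and batch effects,
probe-probe correlation, beta-distributed (heteroscedastic) noise, sex
chromosomes, or covariates such as BMI.  Passing tests therefore show the
pipeline's statistical machinery behaves as specified on clean planted
signals, not that real cohorts are free of those confounders.

## Numerical choices and degenerate inputs

- k-nearest tie-break: ascending original sample order (determinism).
- Even-count medians: mean of the middle two.
- FC with a zero minimum: ε-guarded and flagged rather than infinite.
- t-test with <2 usable values per extreme group, or all medians missing:
  statistic recorded missing, marker excluded; both groups constant and
  equal gives p = 1.
- BH is applied once per run over all QC-surviving markers (a single
  significance gate reused by the FC and absolute selections); NaN p-values
  pass through as NaN.
- All-zero tracks cannot be normalized and raise, naming the marker.
- t-SNE requires ≥ 5 markers and perplexity < marker count; clustering of
  fewer markers than k raises.
- Identical config + seed reproduces every artifact byte-for-byte.

## Known limitations

- **The extreme-group t-test is anti-conservative under the null.**  The
  two groups being compared are chosen, per marker, *because* they have the
  extreme running medians, so even for a pure-noise marker their raw values
  differ more than two random groups would; the null distribution of the
  p-value is therefore far from uniform (in all-null simulations roughly
  half the markers reach q < 0.05).  The selection as a whole remains
  specific because null markers cannot clear the FC > 2 or Δβ ≥ 0.2 change
  thresholds — in the same simulations the end-to-end discovery rate is
  ≈ 0 — but the q-values should be read as ranking scores attached to this
  procedure, not as calibrated error rates.  Adjacent year-groups can also
  share up to 90% of members, and the test still treats the two extreme
  groups as independent samples.
- Group construction gives every year equal weight, so under-represented
  ages are described by samples borrowed from neighbouring ages; the edge
  trim bounds but does not eliminate this.
- The silhouette-based k suggestion is computed on a t-SNE embedding and
  inherits its seed- and perplexity-dependence; it is advisory only.
- The bundled clock support applies user-supplied coefficient tables; no
  published clock coefficients ship with the package.
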