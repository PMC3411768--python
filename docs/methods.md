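# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `trflpipe`, and what its synthetic benchmark does and
does not establish about real fingerprint data.

## Data model

A *peak table* is the long-form list of sized terminal restriction
fragments (TRFs): one row per (sample, enzyme, fragment) with a real-valued
size call in bp and a non-negative fluorescence peak height.  Sizes are
never pre-rounded: the binning step needs the raw sub-bp estimates.
Profiles are normalized per sample × enzyme (heights divided by their sum),
so all downstream abundances are relative.  Restriction to the 50–700 bp
size-standard range happens **before** normalization, so relative
abundances sum to one over the analyzable fragments; the alternative order
(normalize, then restrict) is not provided because it would leave profiles
summing to less than one by an amount that depends on unanalyzable signal.

Marker-range endpoints are inclusive: the size standard itself spans
50–700 bp, so boundary fragments are sized and kept.

## Recursive noise threshold

Each normalized profile is split into baseline noise and real peaks by a
recursive outlier rule: compute the center *m* (median by default; the
mean variant is available as `center="mean"`) and the sample standard
deviation *s* (n−1 denominator, as a sample statistic) of the current
working set; remove every value strictly greater than *m* + k·*s*
(k = 3 by default); repeat until no value is removed or *s* = 0.  The last
computed cutoff is the profile's threshold; the real peaks are the original
values strictly greater than it.

Conventions worth stating because they change edge-case behaviour:

- **Strict vs non-strict comparisons.**  Removing values "equal or larger"
  than the cutoff makes a perfectly uniform profile delete itself (every
  value equals *m* when *s* = 0), so iteration removes *strictly* greater
  values by default; the literal non-strict reading is available as
  `iteration_rule="ge"`.  Final retention is likewise strictly greater than
  the threshold by default (`retention="ge"` keeps boundary values); with
  the strict default the last working set — the estimated noise band — is
  never promoted to signal.
- **Degenerate inputs.**  Profiles with fewer than 5 peaks bypass filtering
  and are returned whole with a `bypass_small` flag (a median and standard
  deviation of so few points separate nothing).  Zero-variance profiles
  retain nothing and are flagged `degenerate`.  Empty profiles yield an
  undefined (NaN) threshold and an `empty` flag.
- The per-iteration cutoff sequence is non-increasing on generator-style
  data (removing the upper tail cannot raise the median or spread there);
  this is asserted on fixtures, not claimed as a theorem.

## Cross-gel binning

Between-gel migration differences give the same fragment slightly different
size calls in different profiles, so profiles are aligned by grouping
like-sized TRFs into OTU bins under three criteria: a size-dependent
maximum bin span, congruence (at most one TRF per profile per bin — a
second peak from the same profile forces a subdivision), and a peak-count
preference for larger bins.  The span allowance comes from a configurable
step table; the default is a single 2 bp window over the whole 50–700 bp
range, adopted from the window widths in common use for ARISA fragment
binning, and is deliberately user-replaceable since published workflows
differ here.

The scan is greedy: TRFs sorted by size, the current bin growing until the
span or congruence rule would break, then closing.  It runs once ascending
and once descending; the run placing more TRFs in multi-member bins (then
the higher mean occupancy; exact ties keep the ascending run) is selected.
Each OTU is labeled by the mean size of its members, formatted to 0.01 bp.

Greedy close-on-violation is not a global optimizer.  On generator-faithful
data — taxa at least 3 bp apart, size jitter ≤ half a bp — every jitter
cluster is an isolated, congruent run and the greedy result provably equals
the exhaustive optimum over order-contiguous partitions; the test suite
verifies this on randomized small instances against a brute-force
enumeration.  When a single profile contributes two peaks inside one
cluster (which the generator never produces, but real chimeric or shoulder
peaks might), the greedy scan can fall short of the optimum by a bounded
amount; a dedicated test documents that gap (≤ 2 TRFs on the adversarial
instances tested) rather than hiding it.

## Community statistics

- **Bray–Curtis** dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on
  square-root-transformed abundances (the transform damps dominant OTUs; a
  pair of all-zero samples is defined as distance 0 with a warning).
- **NMDS**: Kruskal's non-metric scaling (monotone regression), 110 random
  restarts by default, reporting the configuration and stress-1 of the best
  restart together with the seed of the winning restart.  The "110
  iterations" convention is read as 110 random restarts, since its stated
  purpose is initial-condition sensitivity, not gradient-step count.
  Stress is Kruskal stress-1; other stress variants are not provided.
- **ANOSIM**: R = (mean between-group rank − mean within-group rank)/(M/2),
  M = n(n−1)/2, midranks for ties.  **NPMANOVA**: one-way pseudo-F from the
  partition SS_T = (1/N)Σ_{i<j} d²ᵢⱼ, SS_W = Σ_g (1/n_g) Σ within-group d²,
  F = (SS_A/(a−1))/(SS_W/(N−a)).  Both use seeded label permutations and
  the (b+1)/(m+1) p-value estimator, which can never return exactly zero.
  With m chosen so that 0.05·(m+1) is an integer (e.g. m = 199 or 999) the
  α = 0.05 rejection rule has exactly nominal size under the null, which
  the calibration tests exploit.
- **SIMPER** decomposes the average between-group Bray–Curtis dissimilarity
  into additive per-OTU terms |xᵢ−yᵢ|/Σⱼ(xⱼ+yⱼ), averaged over between-group
  pairs, ranked, with rows flagged "reported" up to a cumulative 25% of the
  total by default.  Only the two-group (one-vs-one) case is defined.
- **Rényi profiles** are computed on raw (untransformed) relative
  abundances, zeros excluded; the default α grid is
  {0, 0.25, 0.5, 1, 2, 4, 8, ∞}.  Group-level profiles default to the
  *pooled* mode (profile of the group's mean abundance vector); a
  per-sample averaging mode is provided because fingerprint studies are
  rarely explicit about which they plot.  Profiles that cross are reported
  as non-comparable rather than force-ranked.
- The three per-enzyme OTU matrices are column-concatenated per sample
  before distance computation (per-enzyme analysis remains available);
  concatenation treats each enzyme's OTUs as independent features of the
  same community observation.

## Canonical correspondence analysis

CCA follows ter Braak: the chi-square-standardized matrix
Q̄ = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} is projected, with row-mass weighting,
onto the span of the standardized explanatory variables; canonical
eigenvalues are squared singular values of the fitted matrix, and the sum
of canonical eigenvalues cannot exceed the total inertia ‖Q̄‖²_F.  Site and
species scores use the scaling focused on inter-sample distances (sites
carry the singular values); biplot arrows are row-mass-weighted
correlations of each variable with the site axes.  Collinear explanatory
columns are dropped with an explicit aliasing report; more raw variables
than samples − 1 is an error.

Two deliberate departures from textbook usage: the response matrix holds
square-root-transformed relative abundances rather than raw counts
(fidelity to the fingerprint workflow takes precedence), and the
permutation test offers both unrestricted row permutation of the
explanatory matrix (default) and permutation of reduced-model residuals —
monitoring-study write-ups commonly name both, and with no covariables the
two coincide up to weighted centering.  The default test statistic is the
sum of canonical eigenvalues; the first eigenvalue alone is a flag away.
The share of total inertia on the first two canonical axes is exposed as
`fraction_first_two`.

## Performance statistics

Removal efficiency is 100·(in − out)/in (error for non-positive influent).
Influent/effluent regressions report Pearson r with a two-sided t-based p
and the OLS line of effluent on influent.  The between-plant slope
difference is tested as a Wald test (F form — exactly the squared t of the
interaction coefficient under normal errors, which makes its type-I rate
exact in the calibration tests) of the interaction term in
out ~ in + plant + in×plant.  The species-flow law S = cA^z is fitted by
least squares of log₁₀S on log₁₀A on per-sample points (a two-group-mean
fit cannot identify z usefully); z is scale-equivariant in A, c is not.
All tests are two-sided.  A helper labels fitted exponents against the
macro-organism ranges for continuous (0.12–0.19) and insular (0.2–0.4)
habitats; it is a labeling utility, not an inference.

## Synthetic-data generator

The generator defines the study conditions and is first-class, tested
code.  Defaults emulate the published plant summaries: two plants ("HC",
41.20 MLD average daily flow; "LC", 1.88 MLD), 12 monthly samples, three
enzymes (HaeIII, RsaI, MspI), operational series drawn at the published
monthly means/sds, influent→effluent BOD correlations of +0.4878 (HC) and
−0.6330 (LC), and per-plant richness tied to flow through S = c·A^0.359
with c set so the implied richness matches the reported study averages
(74 and 69 OTUs).

Modeling choices, each a deliberate default:

- **Abundances**: log-normal ranked abundances with σ = 2(1 − evenness),
  so evenness 1 is perfectly even; HC defaults to 0.7, LC to 0.5.
- **Temporal drift**: each month a fraction `turnover` of taxa is replaced
  (new sizes, new base abundances) and all abundances receive multiplicative
  log-normal noise (sd 0.25); HC defaults to 0.05 (stable), LC to 0.25
  (erratic) — one knob reproduces the stable-vs-dynamic contrast.
- **Noise floor**: uniform fragment positions with **half-normal** peak
  heights.  The median+3σ threshold rule presumes near-Gaussian baseline
  noise; measured on the generator's own output it removes ~98% of a
  half-normal floor but only ~92% of an exponential one (the recursion
  converges inside an exponential tail at about 2.4× its scale), so the
  half-normal floor is the model consistent with the filter being tested.
  An exponential floor remains available via `noise_model="exponential"`.
- **Signal-to-noise**: true-peak base heights are bounded below at 10× the
  noise scale, so "real" is well-defined in ground truth; 300 noise peaks
  per profile against ~70 real ones keeps the working set noise-dominated,
  as the threshold recursion assumes.
- **Size calls**: canonical fragment sizes at least 3 bp apart within a
  community; every observed size jittered by N(0, 0.15 bp) — a quarter of
  the 2 bp bin window, so alignment is recoverable but not trivial.
- **Effluent BOD** is a linear blend of the standardized influent draw and
  independent noise, which hits the target correlation exactly in
  population terms.  Influent concentrations are floored at a 1 mg/L
  detection limit; a plain normal emulation of a skewed quantity otherwise
  produces occasional non-physical zeros.
- `simulate_species_flow` generates per-sample (flow, richness) points with
  log₁₀-normal scatter (sd 0.05 ≈ the reported richness coefficient of
  variation) — exactly the sampling model under which the log-log OLS fit
  and its t-based confidence interval are correctly specified.

What passing tests on this generator do **not** show: real
electropherograms have correlated baseline structure, pull-up and shoulder
artifacts, partial digestion, and size-call error that grows with fragment
length; none of these are modeled.  Results here certify the algorithms'
contracts and statistical calibration, not field performance on any
particular instrument.

## Pipeline and reproducibility

`run_pipeline` executes the stages in order, writes every intermediate
artifact as TSV/CSV/JSON plus a SHA-256 manifest, and never mutates an
upstream artifact, so stages are re-entrant.  Every stochastic stage
(simulation, NMDS restarts, each permutation test) gets its own seed
derived from the master seed by CRC-32 of the stage name: toggling one
stage cannot shift another's randomness, and identical config + seed imply
an identical manifest.  Serialized run configs omit the output directory so
manifests are location-independent.

Default problem sizes — 24 samples, three enzymes, 110 NMDS restarts, 999
community permutations, 999 CCA permutations — complete in well under a
minute on one CPU; the bundled demo is simply these defaults under a fixed
master seed.  Calibration-style tests use 199 (ANOSIM/NPMANOVA) and 99
(CCA) permutations per replicate so the α = 0.05 rule is exact (see above)
across hundreds of replicates at small cost.

## Known limitations

- The binning width table's default (a flat 2 bp) is an adopted convention,
  not a recovered constant; workflows with size-dependent windows should
  supply their own table.
- ANOSIM/NPMANOVA assume exchangeability under the null; the monthly
  samples here are treated as exchangeable, ignoring temporal
  autocorrelation, as the fingerprint studies this mirrors also do.
- CCA on square-root-transformed relative abundances departs from the
  count-based chi-square model it was derived for; eigenvalue shares
  should be read comparatively, not as variance-explained in the strict CA
  sense.
- The per-sample species-flow fit inherits whatever richness inflation the
  upstream filter's false positives introduce; with default settings the
  surviving noise adds roughly 5–8 spurious OTUs per profile.
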