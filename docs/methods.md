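# Methods

This note documents the statistical model behind `trialscape`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real registry data.

## Registry model and ingestion

A trial record is (identifier, start year, primary sponsor, set of country
locations).  Start dates are reduced to calendar years — every analysis in
the package is annual.  The primary sponsor is classified as *industry* or
*non-industry* by case-insensitive keyword matching ("Inc.", "Ltd.",
"University", …); tokens of ≤ 4 characters require word boundaries so "inc"
does not fire inside "Provincial".  When industry and non-industry keywords
both match, the sponsor is *unknown* — the keyword lists carry no
precedence, so a conflict is treated like no evidence, and unknown-sponsor
trials are excluded from analysis (mirroring the few-percent exclusion such
keyword schemes typically produce).  The default keyword list is a small
editable YAML file; real deployments should extend it.

Country locations are resolved against a bundled 41-country table (2012
populations, World Bank income groups, regions, continents) plus an alias
file.  An unresolvable location drops that location, not the trial, unless
no location survives; both events are counted in the exclusion report.
Transcontinental countries carry the single continent assignment of the
bundled table (e.g. Russia → Europe, Turkey → Asia); the table is data, not
code, and can be edited.  Deduplication keys on the trial identifier only
and keeps the record with the largest country set (remaining ties broken on
sorted codes, year and sponsor fields, so results are order-independent);
cross-registry semantic duplicate detection is out of scope.

The study period filter keeps trials with start years in [2006, 2013],
inclusive on both ends.  The "at least 50 trials" reporting threshold for
shares is read as ≥ 50.

## Mapping metrics

Density is trials per million inhabitants; group medians treat countries as
equal units (no population weighting), computed only over countries above
250,000 inhabitants.  Each international trial contributes one count to
*every* one of its countries in all per-country and per-group tallies, so
annual group shares are shares of country *locations*, not of trials.

## Collaboration network and trimming

Only international trials (≥ 2 countries) enter the incidence matrix; a
single-country trial has row sum 1 and can contribute nothing to
co-occurrence.  A pair's weight counts each trial once, however many other
countries the trial includes.  Trimming removes, one at a time, the country
with the smallest current column sum (ties broken alphabetically by ISO
code; column sums re-evaluated over surviving rows after each removal) and
stops before the retained total pairwise weight Σ_t C(k_t, 2) would fall
below the retain fraction times the *original* total.  Rows left with fewer
than two countries are dropped.

One consequence of anchoring the stopping rule to the original total: the
operation is not idempotent in general.  Re-trimming an already-trimmed
matrix re-bases the reference total and may remove further countries.  On
matrices where the least-connected surviving country still carries more
than the allowed weight loss (such as the resolved test fixtures), a second
application is a no-op; the pipeline always trims exactly once.

Descriptive networks are computed untrimmed; trimming is applied only
before the null-model stage, matching the order of operations the analysis
is defined in.

## Fixed-margin null model

The null hypothesis is that countries collaborate at random *conditional on
the margins*: the number of international trials per country and the number
of countries per trial.  The sampler is the curveball algorithm: a trade
picks two random rows, pools the columns exclusive to each, shuffles the
pool and deals it back preserving both row sums.  Each trade preserves all
margins, and the induced Markov chain is uniform over the fill class (the
set of all binary matrices with those margins) at stationarity.

Defaults and numerical choices:

- **Replicates** come from one long chain: burn-in of 5 × n_rows trades,
  then one full sweep (n_rows trades) between successive samples.  An
  independent-chains mode (restart + 5 × n_rows trades per replicate) exists
  for uniformity testing; on enumerable fixtures both modes reproduce the
  exact fill-class distributions.
- **Percentile**: the empirical 99.9th percentile is the ⌈0.999·n⌉-th order
  statistic, no interpolation, so "99.9% of null observations fall below or
  at it" holds exactly on the sample.  With n = 90,000 the Monte-Carlo
  standard deviation of the percentile's coverage is
  √(0.999·0.001/90,000) ≈ 0.0105 percentage points — the ±0.01% precision
  quoted for the default replicate count.
- **Flagging** uses strict inequality (observed > q999); ties at the
  percentile are not flagged.  With a discrete null this makes the test
  conservative: the realized false-flag rate sits below the nominal 0.1%
  (calibration places it around 0.05% on large null matrices).
- **Degenerate pairs** (q999 = mean, e.g. margins forcing a constant
  co-occurrence) get no degree; they are reported as degenerate and are
  excluded from the co-occurrence network by default (configurable), since
  an edge width D would be undefined for them.
- **Memory**: per-pair null distributions are bounded integer histograms of
  width min(colsum_i, colsum_j) + 1, the exact co-occurrence bound, so
  memory is O(Σ_pairs min colsum) and no raw sample matrix is kept.  The
  hot loops (trades, accumulation) are numba-compiled.
- Replicate counts below 1,000 trigger a warning: the 99.9th percentile of
  so few samples is essentially the maximum.

## Map-equation clustering

Co-occurrence networks are undirected, so visit rates need no teleportation:
p_i = s_i / Σ_j s_j with s_i the node strength.  The two-level map equation
is evaluated as L = h(q) − 2Σ_m h(q_m) + Σ_m h(q_m + p_m) − Σ_i h(p_i) with
h(x) = x log₂ x, q_m the normalized inter-module edge weight of module m.
The optimizer greedily merges the connected module pair that most decreases
L (ties broken by the smallest sorted module-id pair), then runs single-node
refinement sweeps in seeded random order until no move helps, and keeps the
best of n_restarts runs.  Connected components are optimized independently
and never merged; zero-strength nodes become singletons.  On ≤ 5-node
graphs the result matches brute-force enumeration of all set partitions;
local optimality (no single-node move improves L) is asserted on every
output.  The two-level (flat) variant is implemented; hierarchical variants
are out of scope.

## Synthetic registry generator

The generator's defaults encode the study conditions the pipeline is meant
for: per-income-group expected densities over the whole 2006–2013 period of
116.0 / 13.8 / 1.8 / 1.1 trials per million (high / upper-middle /
lower-middle / low), industry sponsorship fractions 0.516 / 0.66 / 0.654 /
0.093, international probability 0.30 (industry) vs 0.03 (non-industry),
and countries-per-international-trial K = 1 + Geometric(p) with p = 0.55
(median 2, industry) and p = 0.18 (median 5, non-industry); p is chosen in
the interior of the interval that yields the target median so the sample
median is stable.  Trials are anchored in a country (Poisson volumes), and
international trials add K − 1 partner countries sampled without
replacement with probability ∝ √(population in millions) — a compromise
between pure population weighting (which would make the largest countries
ubiquitous) and uniform choice — multiplied by a block affinity when the
anchor and the partner share a planted block.  `rate_scale` scales volumes;
tests and examples run at a few percent of realistic volume purely to keep
suites fast, a problem-size choice documented per test.

What the generator does *not* emulate: geographic distance, language or
regulatory affinity outside planted blocks, temporal drift in collaboration
patterns, disease areas, phases, enrolment.  Passing tests therefore
establish the statistical machinery (calibration, sensitivity, exactness
against enumeration), not that any particular real-world cluster will be
reproduced — cluster memberships on real data depend on the data.

Fill classes of small matrices are enumerated by backtracking with
column-capacity pruning; enumeration is the exact oracle against which the
sampler's per-pair means and percentiles are validated.

## Validation experiment designs

- *Exactness*: a 5×5 fixture whose fill class has 198 members; sampled
  per-pair means must sit within 3 Monte-Carlo SEs of the exact values and
  sampled q999 within the exact distribution's quantile band
  0.999 ± 3·√(p(1−p)/n).
- *Type-I calibration*: 470 equal-scale synthetic countries (> 10⁵ pairs);
  the "observed" matrix is itself a curveball draw from its fill class, so
  every flag is a false positive; at 5,000 replicates the rate must lie in
  [0.02%, 0.3%] around the nominal, conservative 0.1% level.
- *Sensitivity*: four planted 6-country blocks at affinity 5 among 24
  equal-sized countries, each block with ≥ 200 international trials
  containing ≥ 2 members.  The symmetric layout matters: a single block
  distorts the margins of its complement and big-country blocks are partly
  absorbed by the null's conditioning, both of which weaken the planted
  signal.  Within-block sensitivity must reach 90% at 5,000 replicates;
  cross-block flags stay at zero and the map-equation clusters reproduce
  the blocks exactly (adjusted Rand index 1.0).

## Known limitations

- Sponsor classification from keywords is a coarse proxy; registries with a
  curated sponsor-type field should supply it directly (the reader uses a
  pre-classified `sponsor_type` column when present).
- The bundled country table covers 41 countries; analyses of fuller
  extracts need an extended table (same CSV schema).
- The null model conditions on margins only; it cannot distinguish
  mechanisms that produce the same co-occurrence excess.
- Degree-of-overrepresentation values are comparable within one analysis,
  not across matrices with different margins.
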