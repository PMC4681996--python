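# trialscape

Mapping and collaboration-network analysis of clinical-trial registries,
comparing industry- and non-industry–sponsored research.

Clinical trials are spread very unevenly across the world, and the sponsor
type is a major axis of that inequality: industry sponsors run a large share
of their trials internationally in preferentially selected countries, while
academic and public sponsors mostly stay within one country.  `trialscape`
implements the statistical machinery to quantify this from registry metadata
(one row per trial: identifier, start date, primary sponsor, country
locations), for epidemiologists and health-policy researchers analysing
ICTRP-style extracts — and ships a synthetic-registry generator so every
stage is testable without access to registry data.

## What it computes

**Mapping.** Trial density per country (trials per million inhabitants,
reported for countries above 250,000 inhabitants), sponsorship and
internationality shares (reported at ≥ 50 trials in the relevant
denominator), single-country / unicontinental / intercontinental scope, and
annual distributions of country trial locations over regions or World Bank
income groups (a trial in two countries of one region counts twice).

**Collaboration networks.** The binary incidence matrix *B* (international
trials × countries) projects onto a weighted country network with
w(i,j) = number of trials conducted simultaneously in at least countries i
and j.  Sparse countries are trimmed until 95% (industry) or 90%
(non-industry) of the total pairwise weight Σ_t C(k_t, 2) remains.

**Fixed-margin null model.** Is w(i,j) larger than expected if countries
collaborated at random, *given* how many trials each country hosts (column
sums) and how many countries each trial spans (row sums)?  Replicate
matrices with exactly these margins are sampled by curveball trades; each
pair's observed co-occurrence is compared with the empirical 99.9th
percentile of its null distribution (the ⌈0.999·n⌉-th order statistic of
n replicates, 90,000 by default).  Flagged pairs get an overrepresentation
degree

    D = (observed − null mean) / (null q999 − null mean),

so D = 0 at the null mean and D = 1 exactly at the percentile.

**Clustering.** The network of flagged pairs (edge weight D) is partitioned
by minimizing the two-level map equation

    L(M) = q H(Q) + Σ_m p_m^⟲ H(P_m),

the expected per-step description length of a random walk under a two-level
codebook — clusters are groups of countries whose collaboration flow stays
internal.

## Worked example

```python
import trialscape as ts
from trialscape.synthetic import Block

block = frozenset({"DK", "FI", "NO", "SE"})
config = ts.default_config(rate_scale=0.3, seed=4,
                           blocks=(Block(members=block, affinity=12.0),))
records = ts.generate_registry(config)
matrix = ts.trim(ts.build_incidence(records, ts.INDUSTRY), 0.95)
summaries = ts.null_distributions(matrix, n_reps=5_000, seed=11)
for s in sorted((s for s in summaries if s.flagged),
                key=lambda s: -(s.degree or 0))[:4]:
    print(s.pair, s.observed, round(s.null_mean, 1), s.null_q999, round(s.degree, 2))
```

prints

```
('DK', 'NO') 14 2.3 8.0 2.06
('NO', 'SE') 15 2.9 9.0 1.98
('DK', 'SE') 13 3.0 9.0 1.67
('DK', 'FI') 10 2.5 8.0 1.36
```

The four planted Scandinavian pairs top the list: they co-occur in 10–15
trials where the margins alone predict 2–3, far beyond the 99.9th percentile
of the fixed-margin null (D > 1).  The `examples/` directory walks through
every stage the same way: registry generation, mapping metrics, network
construction and trimming, the null model, clustering, and the orchestrated
pipeline (`trialscape run --config run.yaml` from the shell).

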