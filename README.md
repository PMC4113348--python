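# orchidemog

Hierarchical Bayesian estimation of stage-transition probabilities and
matrix demography for several small populations of the lithophytic
orchid *Lepanthes rupestris*, with a synthetic census generator that
makes the whole pipeline testable end to end.

## The problem

Rare plants live in small populations, so many vital rates are observed
rarely or never in any single population: a census of 6–135 juveniles may
record zero deaths over two years even though juvenile mortality is not
zero. `orchidemog` addresses this by estimating all populations jointly
in one hierarchical model, so each population's estimate borrows strength
from the others, and by propagating full posterior uncertainty into the
demographic quantities conservation planning needs: the asymptotic
growth rate, the stable stage distribution and the elasticities of a
stage-classified (Lefkovitch) projection matrix.

## The model

Individuals occupy five stages — seedling (S), juvenile (J),
non-reproducing adult (A0), small (A1) and large (A2) reproductive adult
— plus an absorbing dead state. For population *k*, month *j* and adult
stage *i*:

- monthly adult mortality is logit-linear,
  `logit m[k,j,i] = stage_i + month_{q(k),j} + pop_k`, where the month
  term is a random effect shared by populations in the same stream
  (`month ~ Normal(0, σ_q)`);
- conditional on survival an adult reproduces with probability `r[k,i]`
  and, conditional on reproducing, is large with probability `s[k,i]`,
  giving monthly fates `((1−m)(1−r), (1−m)r(1−s), (1−m)rs, m)` over
  (A0, A1, A2, dead);
- seedling and juvenile fates are modelled on a 13-month time scale as a
  conditional chain: survive (`logit s_y[k] = a_k`, juveniles offset by a
  shared `b`), progress (`g`), and which stage (`t` parameters shared
  across populations); seedlings cannot reach A2 within an interval;
- recruitment is Poisson with mean proportional to fruit-weighted adult
  exposure (an A2 month counts 7.8 A1 months), split between seedlings
  and juveniles by a shared fraction φ.

Priors are deliberately vague: Uniform(0,1) on probabilities,
Normal(0, 1000²) on regression coefficients, Uniform(0,10) on σ and on
the recruitment rates. The posterior is sampled with an adaptive
Metropolis-within-Gibbs sampler (10000 retained draws after 5000
burn-in by default; bit-reproducible under a fixed seed). Each draw is
turned into a 5×5 13-month matrix per population — the adult block is the
monthly kernel raised to the 13th power, fecundity is added once — and
λ, the stable stage vector and Caswell elasticities
(`e_ij = (a_ij/λ)·v_i w_j/⟨v,w⟩`) are summarized across draws with
means, standard deviations and 2.5–97.5% credible intervals.

## Worked example

```python
import orchidemog as od

census = od.simulate_census(od.default_sim_config(seed=1))   # 7 populations
counts = od.tabulate(census)                                  # sufficient stats
sample = od.sample_posterior(counts, n_keep=2000, n_burn=800, seed=1)
summary = od.summarize_demography(sample, max_draws=500)
print(summary.lambda_table().to_string(index=False))
```

prints (seed 1):

```
 population     mean       sd    lo2.5   hi97.5
          1 1.088728 0.031094 1.024277 1.148428
          2 1.083289 0.026633 1.031994 1.133945
          3 1.224314 0.027919 1.170234 1.282249
          4 1.081064 0.028822 1.024568 1.132234
          5 1.001256 0.034249 0.928066 1.068482
          6 0.797140 0.050589 0.702526 0.891158
          7 0.903713 0.037148 0.823222 0.972629
```

Each row is one population's asymptotic growth rate: the posterior mean,
its standard deviation, and the 95% credible interval. Values above 1
indicate growth (population 3's synthetic truth is strongly growing),
below 1 decline; where the interval straddles 1 the trajectory cannot be
distinguished from stability. `summary.stable` and `summary.elasticity`
hold the stage-distribution and elasticity summaries, and
`summary.chi_square` tests each observed initial stage structure against
the stable distribution.

The published summary tables for the real study (initial rosters,
fruit/recruit totals, mean 13-month matrices, elasticities, stable stage
distributions) ship as packaged CSVs under `orchidemog.tables`.

A `orchidemog` command-line tool exposes the same steps
(`simulate`, `tabulate`, `fit`, `project`, `summarize`, `report`,
`regression`).

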