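# nichefit

Niche-neutral modeling of microbial species-abundance distributions, for
microbial ecologists analyzing 16S OTU count tables — in particular gut
microbiota cohorts where biodiversity is compared across age, diet and
health status.

## The model

The relative species abundance (RSA) distribution of a community — the
number of OTUs with exactly *n* reads — is modeled as the stationary law
of a neutral birth–death–immigration process. With per-capita birth rate
*b*, death rate *d* (*b < d*) and immigration influx *s*, the abundance
of an observed species follows the zero-truncated Negative Binomial

```
P(n) = x^n Γ(n + r) / ( n! Γ(r) [(1 − x)^(−r) − 1] ),   x = b/d,  r = s/b
```

A hybrid niche-neutral community with K ∈ {1, 2, 3} non-interacting
niches has a K-component mixture of such laws. Each fitted niche yields
Hubbell's fundamental biodiversity number

```
θ = N_obs / ( [(1 − x)^(−r) − 1] Γ(r) )
```

and for K = 2 the niches split into "rare" and "abundant" by expected
abundance, giving **θ_rare** and **θ_abundant** as the community's
biodiversity summary, alongside the classical indices (Shannon, Pielou,
Simpson, Hill₁, Hill₂).

Fitting is by ABC rejection: propose parameters from priors, simulate a
community at the observed richness, accept when the simulated Preston
(log2-octave) plot reproduces the empirical one — every data octave
within ±30% and a Skellam-motivated χ² below its distribution's median.
A two-step hierarchy shares information across the samples of a dataset:
step-1 acceptances (≤ 5 per sample) are pooled into Gamma/Beta
hyperpriors that drive step 2. Model choice among 1/2/3-niche models
compares acceptance rates via log Bayes factors.

Downstream cohort statistics cover the accompanying epidemiology:
natural-cubic-spline age trends with per-dataset deviations, pairwise
Mann–Whitney group tests, a four-criterion elderly health classifier, a
PCA health score, and leave-one-out health prediction with AUC.

See `docs/methods.md` for assumptions, parameter meanings, numerical
choices and limitations.

## Worked example

```python
import nichefit as nf
from nichefit.experiments import run_recovery

# one gut-like community from the default two-niche model
model = nf.default_recovery_model()
table, truth = nf.make_community(model, n_obs=500, seed=11, sample_id="S0")
av = nf.abundance_vector(table, "S0")
print(f"generating theta_rare = {truth['theta_rare']:.1f}, "
      f"theta_abundant = {truth['theta_abundant']:.2f}")
prof = nf.diversity_profile(av)
print(f"S0: richness={prof.richness}  shannon={prof.shannon:.3f}  "
      f"pielou={prof.pielou:.3f}  hill1={prof.hill1:.1f}  hill2={prof.hill2:.1f}")
print("preston:", nf.preston_histogram(nf.rsa_histogram(av)).bin_counts)

# standard recovery experiment: 10 communities, two-step ABC fit,
# 2e5 proposals per sample and step
res = run_recovery(seed=2, n_sims=200_000)
print(f"median theta_rare = {res.theta_rare_median:.0f} "
      f"(truth 1000, rel. error {res.err_rare:.2f})")
print(f"median theta_abundant = {res.theta_abundant_median:.1f} "
      f"(truth 10.2, rel. error {res.err_abundant:.2f})")
```

prints

```
generating theta_rare = 1000.0, theta_abundant = 10.20
S0: richness=500  shannon=4.934  pielou=0.794  hill1=139.0  hill2=93.9
preston: [229 112  20  22  21  41  40  13   2]
median theta_rare = 873 (truth 1000, rel. error 0.13)
median theta_abundant = 15.2 (truth 10.2, rel. error 0.49)
```

The Preston plot shows the two niches: a rare mode concentrated in the
first octaves and an abundant mode around 2⁴–2⁷ reads. Point recovery of
θ is intrinsically limited at this sample size: several (x, r)
combinations reproduce the octave counts within the acceptance
tolerance while differing in θ, so replicate-to-replicate spread is
wide — across seeded replicates roughly half land within a factor of 2
of the generating values, and θ estimates are best read as
configuration-matched comparative indices across samples rather than
absolute biodiversity numbers (see the identifiability analysis in
`docs/methods.md`).

A thin CLI wraps the same functions: `nichefit diversity`, `nichefit
simulate`, `nichefit fit`, `nichefit cohort`, `nichefit make-fixtures`
(see `--help` on each).

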