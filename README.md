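# depauperon

Tools for asking a simple macroevolutionary question rigorously: **does a
clade have fewer (or more) species than a constant birth–death process
predicts for its age?**  Lineages far below expectation — *depauperons* —
and explosive radiations are both invisible to methods that only estimate
average rates; this package classifies each family against the *stochastic
spread* of clade sizes implied by the fitted process, then tests what
distinguishes the unusual families (genome duplications, traits, mating
systems, geography).

It is aimed at researchers working with family-level richness/age tables
from calibrated phylogenies (angiosperms being the motivating system), and
ships a synthetic-data generator so the entire pipeline is testable without
any downloads.

## The model

Under a birth–death process with speciation rate λ and extinction rate μ
(net diversification *r* = λ − μ, extinction fraction ε = μ/λ), the number
of extant species *n* in a surviving clade of crown age *t* is geometric:

    P(n) = (1 − β_t) β_t^(n−1),   β_t = (e^{rt} − 1) / (e^{rt} − ε)

Given families (n_i, t_i) that originated in the same geological interval,
the log-likelihood

    ℓ(r, λ) = Σ_i [ ln(1 − β_i) + (n_i − 1) ln β_i ]

is maximized by exhaustive grid search over (r, λ).  Two uncertainty
systems come out of the fit:

1. **Profile-likelihood region** — all grid points within 1 log-unit of the
   maximum; parameter intervals are the extremes of r, λ (and by deduction
   μ, ε) over that region.
2. **Stochastic clade-size bounds** — the 2.5% and 97.5% quantiles of the
   geometric clade-size law,

       k_upper(t) = ln(0.025)/ln(β_t) + 1,   k_lower(t) = ln(0.975)/ln(β_t) + 1.

A family is called **low** / **predicted** / **high** by comparing *n*
against the *widest* [min k_lower, max k_upper] obtained by sweeping the
parameters over the profile region at the family's age.  Calls are repeated
across five independently calibrated datasets; unanimous agreement gives a
strict-consensus label (*poor* / *expected* / *high*), agreement in ≥4 a
majority label, anything else *undefined*.

Downstream, the package provides Pearson χ² with Haberman adjusted
residuals (per-cell excess/deficit flags), Kruskal–Wallis + Dunn post-hoc
under a global Benjamini–Hochberg FDR for trait batteries, two-sample
Kolmogorov–Smirnov tests on median ages, mating-system categorization
(>80% / 20–80% thresholds), occurrence-record cleaning, per-family
diversification-rate estimators, 1° grid maps of mean family rates, and
rule-based range/pattern categorization.

## Worked example

Fit the young-interval families of one synthetic dataset generated at known
truth (r = 0.08, ε = 0.6), then classify an age-50-My family:

```python
from depauperon import GridSpec, grid_mle
from depauperon.synthetic_data import SimulationConfig, simulate_families

cfg = SimulationConfig(n_families=300, poor_fraction=0.0, rich_fraction=0.0, seed=42)
tables, key = simulate_families(cfg)
young = tables["ds1"].query("age <= 66")

fit = grid_mle(list(zip(young["richness"], young["age"])),
               GridSpec(1e-4, 0.2, 2e-4, 0.1, 5.0, 0.02))
print(fit.params_hat, fit.profile_ci["r"], fit.widest_bounds_at(50.0))
```

prints (reformatted):

```
r_hat=0.0793  lam_hat=0.22  eps_hat=0.640  loglik=-726.9  n=143
r CI: (0.0683, 0.0877)
widest bounds t=50: (4.14, 614.46)
```

The grid MLE recovers the generating rates (truth r = 0.08, ε = 0.6 sits
inside the profile interval), and a 50-My family in this regime is called
*predicted* if it holds between ~5 and ~614 species, *low* below, *high*
above.  The contingency layer, run on the published whole-genome-duplication
× richness-category counts for 248 angiosperm families:

```python
from depauperon.association_tests import chi2_haberman
from depauperon.study_tables import wgd_by_richness
res = chi2_haberman(wgd_by_richness())
print(f"chi2={res.chi2:.2f} df={res.df} p={res.p:.2e}")
print(res.flags)
```

```
chi2=73.65 df=4 p=3.85e-15
category     poor predicted     high
None       excess      none  deficit
One       deficit    excess   excess
>Two         none   deficit   excess
```

i.e. species-poor families are significantly enriched for *no* ancestral
genome duplication, and species-rich families for more than two.

The full pipeline (simulate → fit → classify → consensus → associations →
geography) runs from the shell:

```sh
depauperon all --seed 1 --out out/
```

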