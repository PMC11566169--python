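# agestrata

Intersectional analysis of family and social participation in older
adults: survey-item coding, latent-class composite indices, regression
and propensity-score-matching association analysis, and a Bayesian
MAIHDA variance decomposition — with a synthetic microdata generator so
the whole pipeline runs and is tested without access to restricted
survey data.

## The problem

Gerontologists and social epidemiologists studying *active aging* ask
how participation inside the family (caring for parents or
grandchildren, helping adult children with housework) relates to
participation in society (voting, community activities, volunteering,
exercise), and how both vary across jointly held social positions —
gender × health × socioeconomic status × family participation — rather
than along one dimension at a time. The package targets survey microdata
of the kind collected in large aging surveys of adults 60+: one row per
respondent with ten binary social-activity items, three
family-participation aspects, ordinal health measures (self-rated
health, a 9-item CES-D total, a 10-item IADL score) and socioeconomic
measures (hukou registration, education, income).

## What it computes

**Coding** (`agestrata.scoring`). The ten activity items sum to a 0–10
social-participation score; family participation is 0/1/2 (none / one /
two-or-more aspects); health and SES measures are recoded to ordinal
levels with configurable boundary conventions.

**Latent composites** (`agestrata.lca`). Two latent-class models — a
finite mixture of independent categorical indicators,
P(x) = Σₖ πₖ Πⱼ ρₖⱼ(xⱼ) — fitted by EM with seeded restarts, compared by
AIC/BIC across K, give each respondent a binary health class
(healthy/unhealthy) and SES class (high/low) from modal posterior
assignment.

**Association** (`agestrata.regression_psm`). OLS of the participation
score on family participation plus controls, and a robustness check by
propensity-score matching: logistic propensity model, 1-nearest-neighbour
and Epanechnikov-kernel matching, the average treatment effect on the
treated (ATT) with a record-level bootstrap SE, and balance diagnostics
(standardized bias, pseudo-R², LR χ²).

**MAIHDA** (`agestrata.maihda`). Multilevel analysis of individual
heterogeneity and discriminatory accuracy: individuals nested in the
24 = 2×2×2×3 intersectional strata,

    y_ij = γ₀ + x_j'β + u_j + e_ij,   u_j ~ N(0, σ²_u),  e_ij ~ N(0, σ²_e),

fitted as a null (intercept-only) and a main-effects model by a
collapsed Gibbs sampler under weakly informative priors (Normal(0, 10²)
on fixed effects, half-Cauchy(0, 1) on both SDs). General
intersectionality is summarized by the variance partition coefficient
VPC = σ²_u/(σ²_u + σ²_e) and the proportional change in variance
PCV = (σ²_u,null − σ²_u,main)/σ²_u,null, whose complement is the share
of between-stratum variation attributed to interactions; specific
intersectionality by per-stratum expected/predicted outcomes and random
effects with 95% credible intervals, flagging strata whose interval
excludes zero.

**Synthesis** (`agestrata.synthetic`). A generator producing raw survey
tables with known latent classes, stratum effects and injected
interaction offsets; the `paper_like` preset encodes study-scale
conditions (n = 10,625, realistic marginals, participation mean 2.68,
SD 1.74).

## Worked example

```bash
agestrata run --preset paper_like --n 2400 --seed 7 --outdir out
```

or, equivalently, from Python with scaled MCMC settings:

```python
import agestrata as ag

cfg = ag.PipelineConfig(preset="paper_like", n_override=2400, seed=7,
                        mcmc_warmup=1000, mcmc_total=2000,
                        lca_n_starts=5, psm_n_boot=100, outdir="out")
report = ag.run_pipeline(cfg)
ag.write_report(report, cfg.outdir)
```

`out/summary.txt` then reads:

```
agestrata run summary
=====================
records analyzed: 2400
participation score: mean 2.746 (sd 1.706)
regression: FP coefficient 0.3188 (p = 6.19e-06, n = 986)
psm[nn_k1]: ATT 0.5659 (se 0.0947), post-match mean bias 1.65%
psm[kernel]: ATT 0.5124 (se 0.0693), post-match mean bias 1.47%
maihda: VPC 8.05% -> adjusted 3.84%, PCV 54.43% (interaction share 45.57%)
flagged strata (1): [2]
```

Reading it: the 0–10 participation score averages 2.75; family
participation is positively associated with social participation (OLS
coefficient 0.32 per category, on the smaller income-complete sample
n = 986), and the matched comparisons agree (ATT ≈ 0.5 score points for
any-family-participation vs none, with post-matching covariate bias
under 2%). In the intersectional decomposition, 8% of outcome variance
lies between the 24 strata; additive main effects explain 54% of it,
and one stratum's interaction residual is credibly non-zero at this
reduced sample size. Alongside the summary, the run writes the full
parameter, stratum, balance and caterpillar-plot tables as CSV plus
`report.json`.

## Layout

```
src/agestrata/     scoring, lca, regression_psm, maihda, synthetic,
                   pipeline, cli
tests/             unit, property and end-to-end suites
scripts/           acceptance.py
docs/methods.md    models, priors, generator design, numerical choices
```
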