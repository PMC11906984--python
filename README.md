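# gwgtraj

Distributional-regression modelling of gestational weight gain (GWG)
trajectories, with personalised centile chart construction — exercised
entirely on synthetic cohorts.

The package implements the full workflow:

1. **Synthetic cohort generation** (`gwgtraj.synthetic`): cohorts with
   realistic marginals (maternal age, 13 country-of-birth regions,
   parity, delivery gestation, 1–21 routine visits per woman) and a
   configurable ground-truth Box-Cox *t* generating model with a
   nonlinear median curve, gestation-increasing variance, skewness and
   heavy tails, plus self-report/measurement error of SD 0.70 kg.
2. **Preprocessing** (`gwgtraj.preprocess`): gain scores (measured
   weight minus pre-pregnancy weight), week-0 Gaussian
   pseudo-observations with variance 0.70² + 0.70² = 0.98 kg², a
   windowed 4 SD credible-interval exclusion, WHO/Chinese/Korean BMI
   coding, and the first-visit re-baselining used for sensitivity
   analysis.
3. **Response families** (`gwgtraj.distributions`): normal, Box-Cox
   Cole–Green, Box-Cox power exponential and Box-Cox *t*, each with
   log-density, CDF, quantile, sampler and score functions. Negative
   gains are handled by a configurable positive shift (default 30 kg).
4. **Smoothers** (`gwgtraj.smoothers`): penalised B-splines (20 interior
   knots, degree 3, order-2 difference penalty), natural cubic smoothing
   splines with effective-df targeting, fractional polynomials and
   GAIC-based smoothing-parameter selection.
5. **Fitting engine** (`gwgtraj.engine`): cyclic backfitting over the
   four distribution parameters with squared-score working weights,
   step-halving and deviance-based convergence; linear and
   cubic-polynomial baselines; AIC/SBC/generalised-R² model comparison.
6. **Diagnostics** (`gwgtraj.diagnostics`): normalized quantile
   residuals, four-moment summaries with the Filliben correlation, worm
   plots, generalised R², and two-way mixed-effects ICC (absolute
   agreement and consistency) with F-based confidence intervals.
7. **Centiles + CLI** (`gwgtraj.centiles`, `gwgtraj.cli`): P2.3 / P16 /
   P50 / P84 / P97.7 trajectory tables for any covariate profile,
   per-BMI-category batch charts, empirical coverage checks, and a
   config-driven end-to-end pipeline.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed
analytic values, the property suites, Box-Cox-*t* parameter recovery on
the model's own simulation (n = 5000 women), the AIC ranking direction
over 10 seeded cohorts, held-out centile coverage, and the
re-baselining sensitivity comparison.

## CLI

```sh
# full demo pipeline (simulate -> preprocess -> fit 4 models -> report)
gwgtraj run --demo --out out/demo

# or stage by stage
gwgtraj simulate --seed 1 --n-women 2000 --out out/sim
gwgtraj preprocess --cohort out/sim/cohort.csv --visits out/sim/visits.csv \
    --seed 1 --out out/pre
gwgtraj fit --obs out/pre/observations.csv --model bct-pspline \
    --out out/model.json
gwgtraj diagnose --model out/model.json --obs out/pre/observations.csv \
    --out out/diag
gwgtraj centiles --model out/model.json --age 30 --bmi 27 \
    --ethnicity "Australian/European" --parity 0 --out out/centiles.csv
```

Exit codes: 0 success, 2 config error, 3 convergence failure.

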