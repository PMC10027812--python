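# qisipop

Small-area synthetic population generation from census-like data, for
researchers who need individual-level agent populations — epidemiological
and transport agent-based models, policy microsimulation — where only a
weighted microdata sample and confidentiality-protected aggregate counts
are published.

## The method

For each small area the synthesizer estimates a seven-way contingency
table over (age group, sex, highest degree, labour force status,
household-size category, income band, primary-maintainer flag) and draws an
integer population from it:

1. **Seed**: the province's weighted microdata records summed into the
   7-axis table (12 960 cells), with unobserved cells smoothed by a small ε.
2. **IPF**: iterative proportional fitting scales the seed until every
   published marginal of the area — total population *N*, households *H*
   (as the maintainer margin (N−H, H)), sex, age group, age × sex, household
   size, degree, labour status, income — is reproduced, preserving the
   seed's odds ratios where unconstrained. Published counts are randomly
   rounded, so marginal vectors are first adjusted to sum to *N* by
   largest-remainder increments along the province distribution.
3. **Quasirandom integer sampling without replacement**: individuals are
   drawn one at a time from the fitted table under integer quotas per
   marginal category, refitting after each draw. The sampled population
   matches **every** constrained marginal exactly — no integerisation step.

Around the synthesizer: projection to a future year by per-cell
(sex × age group) resampling against a provincial projection table
(duplicating or deleting uniformly, which preserves the within-cell
attribute law); grouping into households (one per maintainer, capacity
from the maintainer's household-size category, members drawn young-first
from a composition law estimated from hierarchical microdata); household
typing from member counts and age gaps; and validation metrics (Pearson r,
range-normalised RMSE, per-area relative absolute error

    RAE_i = |obs_i − sim_i| / obs_i

with five-number summaries). A fixture module generates a complete ground
truth world and emits all five inputs with the statistical defects of a
real release — 2.7 % / 1 % samples, counts randomly rounded to multiples
of 5, small areas suppressed — so every stage is testable offline. See
`docs/methods.md` for the full model description.

## Worked example

```sh
qisipop fixtures   --out inputs --seed 7 --areas 6 --mean-pop 400
qisipop synthesize --inputs inputs --out out --province 10 --seed 11
qisipop project    --inputs inputs \
                   --population out/province_10/syn_pop/synthetic_pop_2016_.csv \
                   --out out --province 10 --scenario LG --year 2023 --seed 11
qisipop households --inputs inputs \
                   --population out/province_10/syn_pop/LG/synthetic_pop_2023_.csv \
                   --out out/pop_hh.csv --seed 11
qisipop hhtypes    --population out/pop_hh.csv --out out/pop_final.csv
qisipop validate   --population out/province_10/syn_pop/synthetic_pop_2016_.csv \
                   --profile inputs/truth_profile.csv --out report.csv
```

The final file has one line per individual with the twelve columns
`index, HID, sex, prihm, agegrp, age, area, hdgree, lfact, hhsize, totinc,
hhtype`:

```
index,HID,sex,prihm,agegrp,age,area,hdgree,lfact,hhsize,totinc,hhtype
0,17,0,0,0,3,10010001,0,2,2,0,4
1,144,0,0,0,1,10010001,0,2,2,0,4
```

— individual 0 is a girl aged 3 living in area 10010001 in household 17, a
3-person household of the "other" type. The validation report compares the
base synthesis with the generator's exact pre-rounding counts per area:

```
Category                                         r   NRMSE %  RAE % min/q1/median/q3/max
0 to 4 years                                 0.993     4.167  1.96/2.40/2.82/3.09/3.70
1 person                                     0.935    22.822  3.70/4.41/11.52/20.31/27.69
15 to 19 years                               0.991     9.671  0.00/3.16/5.83/7.75/8.33
```

High r and single-digit median RAE for most categories; the residual error
is dominated by the confidentiality rounding of the published counts (a
rounded count carries an expected absolute error of 2.5, i.e. 25 % of a
count of 10 — see `qisipop.validation.rounding_error_model`).

Every command is a pure function of (inputs, config, seed); per-area random
substreams make chunked execution (`--chunk-start/--chunk-size` plus
`qisipop merge`) bit-identical to a single run.

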