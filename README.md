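# crvsddm

Death-registration completeness and adult mortality estimation for
civil registration and vital statistics (CRVS) assessment.

In many countries, deaths are under-registered, and the degree of
under-registration may differ between data sources, over time, and —
critically for health policy — between women and men. `crvsddm` is a
Python toolkit for demographers and epidemiologists who need to answer
questions like: *what fraction of adult deaths does a health-ministry
register actually capture, by sex?* and *after adjusting for that
completeness, how large is the female–male gap in adult survival?*

It implements, as tested reusable components:

* **Death distribution methods (DDM)** on two censuses and intercensal
  registered deaths:
  - **Generalized growth balance (GGB)**: in a population closed to
    migration, `N(x)/N(x+) − r(x+) = (1/C)·D*(x+)/N(x+) + δ`, so the
    slope of a fitted line estimates `1/C` (registration completeness)
    and the intercept `δ = ln(k1/k2)/t` the relative census coverage.
  - **Synthetic extinct generations (SEG, Bennett–Horiuchi)**:
    reconstructs the population from registered deaths cumulated up the
    age axis with growth-rate weights, `N̂(x) = ∫ₓ D*(y) exp(∫ₓʸ r) dy`,
    and estimates `C = N̂(x)/N(x)`.
  - **Combined GGB–SEG**: SEG after rescaling the second census by the
    GGB-estimated `k1/k2`, robust to differential census coverage.
  - An **age-trim sensitivity sweep** that re-estimates completeness on
    every contiguous window of ≥ 8 adjacent five-year age groups between
    15 and 80 and reports `mean (min–max)` sensitivity intervals.
* **Completeness-adjusted abridged life tables** giving the adult
  summary measures ₃₅q₁₅ (probability of dying between exact ages 15
  and 50) and e₁₅ (life expectancy at 15), plus the female−male e₁₅ gap.
* **Direct survey estimation**: DHS-style sibling histories (with the
  date-imputation and weight-screening rules such files require) and
  household-death modules, with respondent-level bootstrap uncertainty.
* **Two-source registry comparison** (`100·(B/A − 1)` by year and sex),
  shipped with the published annual totals of Peru's health-ministry
  (MINSA) and civil-registry (RENIEC) death records, 2005–2019.
* **Synthetic generators with known ground truth** for every stage, so
  each estimator is validated by parameter recovery.

## Worked example

Estimate registration completeness for a male population observed
through two censuses ten years apart, where the register truly captured
80% of deaths:

```python
from crvsddm import DDMModel, build_life_table, prob_15_50
from crvsddm.simulate import ScenarioTruth, make_ddm_scenario

truth = ScenarioTruth(r=0.01, alpha=3.8e-4, beta=0.066, c=0.80, sex="male")
data = make_ddm_scenario(truth)

model = DDMModel(data.census_pair, data.death_series)
res = model.fit(method="ggbseg")
print(res.summary())

lt = res.life_table("mean")
print(f"adjusted 35q15 = {prob_15_50(lt):.4f}")
print(f"adjusted e15   = {lt.e_at(15):.2f} years")
```

This prints:

```
Death distribution method results
==============================================
method:            GGBSEG
sex:               male
fit:               ols
windows swept:     21
completeness:      0.80 (0.80–0.80)

adjusted 35q15 = 0.1319
adjusted e15   = 55.50 years
```

The trim sweep enumerated all 21 admissible age windows, the combined
GGB–SEG method recovered the true completeness of 0.80 on every one of
them (hence the degenerate sensitivity interval on this noise-free
scenario), and dividing the registered death rates by that completeness
raises the adult mortality probability from the unadjusted 0.1070 to
0.1319 — the level implied by the true schedule.

The same objects are available from the shell:

```bash
crvsddm simulate ddm --out scenario/ --seed 1
crvsddm ddm --census scenario/census.csv --deaths scenario/deaths.csv \
        --sex female --method all
crvsddm compare --series-a minsa.csv --series-b reniec.csv
```

## Layout

- `crvsddm.grids`, `crvsddm.lifetable` — age-group arithmetic, abridged
  life tables, ₃₅q₁₅ / e₁₅ / sex gap
- `crvsddm.ddm` — GGB, SEG, GGB–SEG, trim sweep, rate adjustment, and
  the `DDMModel` / `DDMResults` front-end
- `crvsddm.survey` — sibling-history and household-death estimation
  (`SiblingSurveyModel`, `HouseholdSurveyModel`)
- `crvsddm.simulate` — ground-truth generators
- `crvsddm.pipeline`, `crvsddm.cli` — orchestration, registry
  comparison, reporting
- `docs/methods.md` — modelling assumptions, conventions and
  limitations
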