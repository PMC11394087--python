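# crocdiet

Quantitative stomach-content analysis for hatchling crocodiles (and other
gape-limited predators sampled by stomach-flushing). Given per-stomach
records — individual total length (TL, mm) plus prey category, count and
displaced volume (mL) per stomach — the package computes everything a diet
study of this kind reports:

- **Diet indices per TL size class.** With `N_i` prey of category *i*,
  `N_t = Σ N_i` prey in the class, `n` stomachs containing the category out
  of `N` examined, `vd` its displaced volume and `vTd` the total volume:

  ```
  %N  = 100·N_i/N_t        %V  = 100·vd/vTd
  %FO = 100·n/N            RII = %FO·%V/100
  ```

  RII (relative importance index, 0–100) is classed low [0, 10),
  secondary [10, 40), high [40, 100].
- **Diversity and overlap.** Simpson diversity `D = 1 − Σ p_i²` per class,
  pairwise class comparison by a stomach-resampling bootstrap *t* test, and
  Pianka niche overlap `O_jk = Σ p_i q_i / √(Σ p_i² Σ q_i²)` between classes
  on a numeric, volumetric or occurrence proportion basis.
- **Composition inference.** Bootstrap chi-square goodness-of-fit of pooled
  prey counts against uniform expected frequencies, with standardized
  residuals `(O−E)/√E` flagged beyond ±1.96; and per-item logistic
  regression of presence against TL (`logit P = β₀ + β₁·TL`, IRLS, 1-df
  likelihood-ratio test), restricted to items with RII ≥ 1.0 in some class.
- **Synthetic data.** A seedable generator of stomach-level datasets
  (uniform TL, constant or TL-logistic presence, zero-truncated Poisson
  counts, log-normal item volumes), plus a deterministic reconstruction of
  the reference survey: 31 wild Morelet's crocodile hatchlings (300–509 mm)
  in three equal-width size classes of 10/7/14 stomachs and 11 prey
  categories, rebuilt exactly from the published per-class summary table.

## Worked example

```python
import crocdiet as cd

fixture = cd.build_study_fixture()          # the reconstructed 31-stomach survey
diet = fixture.diet_table()
metrics = cd.summarize_diet(diet, vtd=fixture.vtd_ml)
print(metrics.query("size_class == 2 and category == 'Coleoptera'")
      [["pct_n", "pct_v", "pct_fo", "rii", "rii_class"]].round(1))
```

```
    pct_n  pct_v  pct_fo   rii rii_class
11   25.0   77.1    85.7  66.1      high
```

Coleoptera dominates the medium size class: it is 25% of prey individuals,
77% of displaced volume, occurs in 86% of stomachs, and its RII of 66 makes
it the only *high*-importance item in the survey. The analysis drivers
narrate the full pipeline and write tables under `results/`:

```
python analysis/01_build_fixture.py       # dataset audit, pooled %FO
python analysis/02_diet_metrics.py        # per-class index table
python analysis/03_diversity_overlap.py   # Simpson D, bootstrap t, Pianka O
python analysis/04_composition_tests.py   # bootstrap chi-square, logistic fits
python analysis/05_simulation_checks.py   # generator-based calibration
```

For example, `04_composition_tests.py` prints a pooled bootstrap chi-square
of X² = 87.96 (p = 0.001, 1000 iterations) with Coleoptera, Hemiptera and
Araneae over-consumed (standardized residuals +5.3, +4.0, +4.0), and the
logistic screen shows Hemiptera presence falling with body length
(β₁ = −0.029 per mm, p = 0.001) while fish presence rises.

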