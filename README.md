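# walkmet

Nonlinear estimation of submaximal effort tolerance (METs) from the
six-minute walk test, for pulmonary rehabilitation.

Submaximal treadmill exercise tests (e.g. the modified Bruce protocol)
grade a COPD patient's effort tolerance in METs, but they need equipment
and supervision.  The six-minute walk test (6MWT) — walk as far as you can
in six minutes along a corridor — needs neither.  `walkmet` models the
relationship between the 6MWT result and the treadmill MET score so the
cheap test can stand in for the expensive one, and turns the fitted model
into rehabilitation-class boundaries.

The 6MWT result is a distance D [m] or equivalently the velocity
v = D/100 [km/h].  Because oxygen uptake is nonlinear in power output above
the anaerobic threshold, `walkmet` fits two nonlinear model classes, both
pinned to the resting value of exactly 1 MET at v = 0:

* polynomial expansion:  M(v) = 1 + a₁v + … + a_K v^K, analytic least
  squares (default K = 3);
* continuous piecewise-linear: n segments with slopes a_j and change points
  V_i, intercepts fixed by continuity (b₁ = 1,
  b_j = (a_{j−1} − a_j)V_{j−1} + b_{j−1}); slopes are solved analytically
  via a hinge basis while a seeded genetic algorithm searches the change
  points (default n = 4, matching the four rehabilitation groups A–D).

Model selection uses leave-one-out cross-validation (RMSE_cv, Pearson R).
A synthetic-cohort generator emulating the study-sample structure
(159 men + 140 women, MET noise SD 0.55) makes the whole pipeline testable
without patient data.  See `docs/methods.md` for the full model and
algorithm description.

## Worked example

Converting a treadmill score to the common velocity scale — a patient who
walks T = 10.5 min on the modified Bruce protocol:

```python
>>> from walkmet import MBRUCE, convert
>>> convert(MBRUCE, 10.5)
TreadmillOutcome(walk_time=10.5, completed_stages=3, partial_stage_time=1.5,
distance=505.0000000000001, average_velocity=2.885714285714286,
six_minute_equivalent_velocity=5.050000000000001)
```

Three completed 3-minute stages plus 1.5 min of stage four give 505 m: an
average treadmill pace of 2.886 km/h, but a 6MWT-equivalent pace of
5.05 km/h — the 6MWT is the less exhausting test, so the same distance maps
to a faster sustained walk.

Fitting both model classes to a synthetic study-shaped cohort:

```python
>>> from walkmet import GAConfig, fit_piecewise, fit_polynomial, switch_points
>>> from walkmet.synthetic import SyntheticConfig, generate
>>> cohort = generate(SyntheticConfig(seed=7))          # 299 records
>>> poly = fit_polynomial(cohort, 3)
>>> [round(c, 4) for c in poly.model.coefficients], round(poly.rmse, 4)
([0.419, -0.018, 0.0286], 0.5762)
>>> pw = fit_piecewise(cohort, 4, GAConfig(population_size=40,
...                                        generations=100, restarts=1, seed=7))
>>> [round(v, 3) for v in pw.model.change_points], round(pw.rmse, 4)
([3.079, 5.345, 5.946], 0.5406)
>>> [round(m, 3) for m in switch_points(pw.model)]
[2.576, 6.935, 8.461]
```

Both fits land near the generator's noise floor (0.55 MET), the piecewise
model slightly ahead.  Its switch points — the fitted MET values at the
change points — are candidate rehabilitation-class boundaries; compare them
with the conventional 3/5/7 MET division via
`walkmet.classification.scheme_disagreement`.

The same pipeline is scriptable from the shell:

```bash
walkmet treadmill-convert --protocol mbruce --time 10.5
walkmet simulate --seed 7 --out cohort.txt
walkmet fit --model piecewise --segments 4 --input cohort.txt --seed 7
walkmet validate --model poly --order 3 --input cohort.txt
walkmet classify --met 6.2
```

Real cohort tables are two-column text files (6MWT distance in meters or
velocity in km/h, then the treadmill MET score); `walkmet.read_cohort`
sniffs the delimiter, header and column semantics.

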