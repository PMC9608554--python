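# chromaqbd

A design-of-experiments toolkit for **analytical quality-by-design (AQbD)
HPLC method development**. It implements the computational pipeline behind a
robust chromatographic optimization study: two-level fractional-factorial
screening with Lenth/half-normal significance analysis, Box–Behnken
response-surface modelling in coded factor units, Monte Carlo mapping of the
probabilistic *design space* of separation criteria, translation of the
chosen working point into a gradient program, and ICH-style validation
statistics (calibration, LOD/LOQ, recovery, %RSD with tiered acceptance
rules).

It is written for analytical chemists and chemometricians who develop
gradient LC methods for an active ingredient and its impurities and want the
statistics of the development study to be scripted, seeded, and reproducible
rather than locked in point-and-click DoE software.

## The model

Each measured response (a peak-begin or peak-end retention time, in minutes)
is fitted in coded units x ∈ [−1, +1] by ordinary least squares as

    linear:     y = b₀ + Σⱼ bⱼxⱼ
    quadratic:  y = b₀ + Σⱼ bⱼxⱼ + Σ_{j<l} b_{jl} xⱼxₗ + Σⱼ b_{jj} xⱼ²

Method performance is summarised by *separation criteria*
s = t_b(later peak) − t_e(earlier peak); the method is acceptable when every
s ≥ 0 (baseline separation). Each criterion is computed per run and fitted
as its own surface, and its predictive distribution at a factor setting x is
sampled from the standard posterior:

    σ*² ~ ν σ̂² / χ²(ν),   s* = x'b* + ε*,   b* ~ N(b̂, σ*² (X'X)⁻¹),  ε* ~ N(0, σ*²)

π(x) is the fraction of Monte Carlo iterations in which all criteria are
met; the **design space** is {x : π(x) ≥ 0.85} over the gridded knowledge
space. Screening uses Lenth's pseudo standard error over all alias-distinct
contrasts of the fraction, with a simulation-calibrated critical value.

## Worked example

The package ships the run tables of a chaotropic gradient HPLC study of an
antidepressant and five impurities: a 19-run 2^(6−2) screening study and a
16-run Box–Behnken study over (A) %acetonitrile at the gradient start
(37–41%), (B) chaotropic salt concentration (30–60 mM) and (C) gradient
start time (7–11 min).

```python
import chromaqbd as cq

table = cq.load_fixture("table2_bbd")
fit = cq.fit_ols(table, "t_e_bup", "quadratic")
print(cq.coefficient_inference(fit).round(4))
print(f"R2={fit.r2:.5f} adjR2={fit.adj_r2:.4f} predR2={fit.pred_r2:.4f}")
```

```
       coef      se         t       p stars
1    9.3450  0.0600  155.7725  0.0000   ***
A   -1.6712  0.0424  -39.3974  0.0000   ***
B    0.5850  0.0424   13.7906  0.0000   ***
C    0.0637  0.0424    1.5028  0.1836
...
R2=0.99662 adjR2=0.9916 predR2=0.9462
```

The end of the drug peak elutes 1.67 min earlier per coded unit of starting
organic ratio and 0.59 min later per coded unit of salt concentration — the
chaotropic agent increases the retention of the protonated analytes. The
design space for the two separation criteria:

```python
cmas = [cq.CMADefinition("s1", "t_b_imp2", "t_e_bup"),
        cq.CMADefinition("s2", "t_b_imp3", "t_e_imp2")]
fits = cq.fit_cma_surfaces(table, cmas)
result = cq.compute_design_space(
    fits, cmas, table.factors, threshold_pi=0.85,
    config=cq.MCConfig(iterations=5000, seed=1),
    working_point=[37.5, 45.0, 10.0],
)
print(result.summary())
```

```
{'n_grid': 4851, 'n_in_ds': 3348, 'fraction_in_ds': 0.690,
 'threshold_pi': 0.85,
 'bounding_box': {'A': [37.0, 40.6], 'B': [30.0, 60.0], 'C': [7.0, 11.0]},
 'working_point': [37.5, 45.0, 10.0], 'working_point_in_ds': True}
```

3348 of the 4851 grid points meet both separation criteria with probability
at least 85%; the chosen working point (37.5% ACN, 45 mM, gradient start at
10.0 min) lies inside the design space.
`cq.working_point_to_gradient_program([37.5, 45.0, 10.0])` turns it into the
runnable timetable (0, 37.5%) → (10, 37.5%) → (17, 70%) → (21, 37.5%) →
(23, 37.5%).

A `chromaqbd` command-line interface exposes the same stages
(`design`, `screen`, `fit`, `ds`, `gradient`, `validate`, `simulate`,
`pipeline`); see `chromaqbd --help`.

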