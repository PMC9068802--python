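# trackace

Twin-model machinery for asking whether **delaying school tracking changes
how much genes and family background matter for educational attainment**.

In the Dutch system, children are sorted into secondary-school ability
tracks around age 12.  Some schools assign the definitive track
immediately; others first place students in a heterogeneous class and
decide one to three years later.  The classical twin design turns this
institutional contrast into a test of equality of opportunity: comparing
monozygotic pairs (genetic relatedness r = 1) with dizygotic pairs
(r = 0.5) decomposes the variance of attainment into additive genetic
(A), shared environmental (C), and non-shared environmental (E) parts,

    V = a² + c² + e²,    Cov_MZ = a² + c²,    Cov_DZ = ½a² + c²,

where a larger shared-environment share is read as a larger imprint of
family background, and a larger genetic share as better realization of
individual potential.

`trackace` implements the full analysis pipeline for this design:

* **Bivariate Cholesky decomposition** ordering end-of-primary test
  performance (x, CITO-score scale 501–550) before secondary attainment
  (y, track levels 0–4): the A/C/E influences on attainment split into a
  part *common* with performance (paths `a_yx, c_yx, e_yx` — capturing
  family influence that works through test performance) and a part
  *unique* to attainment (`a_yy, c_yy, e_yy` — net of performance).
* **Path moderation** by each twin's own centered performance as a
  definition variable: any attainment path `b` may become `b + b′·X`,
  so heritability can vary with the student's performance level.
* **Multigroup FIML estimation**: tracking status (immediate, delayed,
  or unknown) selects each *twin's* parameter set — discordant pairs mix
  two sets inside one pair covariance — and every pair contributes the
  Gaussian likelihood of its observed subvector, so item missingness
  needs no imputation.  Three nested specifications mirror the analysis
  progression: one shared parameter set ("1a"), a set per tracking
  status ("1b"), and per-status sets with moderation ("2"), compared by
  likelihood-ratio tests.
* **Synthetic twin data** from exactly this generative model, with known
  parameters, for recovery and calibration testing; plus descriptives
  (double-entry twin correlations, decomposition tables, moderation
  curves, and Rao–Scott pair-cluster-corrected crosstabs).

It is written for quantitative social scientists and behavior
geneticists who want a reproducible, testable version of this analysis
for simulated or suitably formatted twin-register data.

## Worked example

```python
from trackace import (GenerativeConfig, simulate_pairs, fit_model,
                      likelihood_ratio_test, twin_correlations,
                      variance_components, standardize_components)

cfg = GenerativeConfig.default(n_mz=1650, n_dz=1350, seed=7)
table = simulate_pairs(cfg)

for pheno in ("attainment", "performance"):
    r = twin_correlations(table, pheno)
    print(f"{pheno:12s} rho_MZ = {r.rho_mz:.2f}  rho_DZ = {r.rho_dz:.2f}")

shared = fit_model("1a", table, n_restarts=1, compute_se=False)
warm = dict(shared.estimates)
warm.update({f"{k}@{s}": v for k, v in shared.estimates.items()
             for s in ("immediate", "delayed", "missing")})
split = fit_model("1b", table, starts=warm, n_restarts=1)

for status in ("immediate", "delayed"):
    std = standardize_components(variance_components(split.path_set(status)))
    print(f"{status:10s} A = {100*std['a_y']:.0f}%  C = {100*std['c_y']:.0f}%  "
          f"E = {100*std['e_y']:.0f}%  "
          f"(V_T = {variance_components(split.path_set(status)).vt_y:.2f})")

lrt = likelihood_ratio_test(shared, split)
print(f"LRT shared vs split: Chi2({lrt.df}) = {lrt.statistic:.1f}, "
      f"p = {lrt.p_value:.2g}")
```

prints

```
attainment   rho_MZ = 0.80  rho_DZ = 0.47
performance  rho_MZ = 0.78  rho_DZ = 0.47
immediate  A = 54%  C = 24%  E = 22%  (V_T = 1.26)
delayed    A = 69%  C = 8%  E = 23%  (V_T = 0.91)
LRT shared vs split: Chi2(22) = 242.9, p = 3.8e-39
```

Read: identical twins resemble each other far more than fraternal twins
(0.80 vs 0.47), consistent with substantial genetic influence.  Under
the tracking-split model, the shared environment accounts for a sizable
share of attainment variance when tracking is immediate (24%) but little
when it is delayed (8%), while the genetic share rises from 54% to 69% —
the generating contrast, recovered from 3000 simulated pairs.  The
22-degree-of-freedom likelihood-ratio test rejects the hypothesis that
one parameter set fits both tracking regimes.

The same pipeline is scriptable from the shell:

```bash
trackace all --seed 7 --out results/demo          # bundled demo config
trackace simulate --seed 1 --out pairs.csv
trackace fit --data pairs.csv --model 1b --out fit1b.json
```

`CholeskyACE` in `trackace.fiml_engine` is a scikit-learn-style
estimator (`fit`, `get_params`, fitted attributes `params_`, `se_`,
`neg2_loglik_`, `aic_`) over wide pair tables, so it composes with
sklearn tooling; `fit_model` and the other module-level functions are
thin wrappers over it.

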