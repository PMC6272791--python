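# plsvip

A toolkit for building and rigorously validating PLS-based QSAR models with
iterative VIP variable selection, developed around the problem of predicting
human placental barrier permeability — the clearance index (CI), a drug's
ex vivo placental clearance relative to antipyrine — from large pools of
numeric molecular descriptors.

QSAR practitioners routinely face a descriptor table that is far wider than
it is tall (hundreds of DRAGON-style descriptors for fewer than a hundred
compounds). `plsvip` implements the complete workflow for that regime:

- **Pretreatment** — remove constant columns, columns with SD < 0.001, and
  one of every descriptor pair with |r| > 0.90 (deterministic greedy scan).
- **PLS regression (NIPALS)** — single-response partial least squares on
  autoscaled data; the number of latent variables *A* is chosen by
  maximising leave-one-out q².
- **VIP selection** — the variable importance in projection of descriptor
  *j*,

  VIP_j = √( m · Σ_a w²_ja · r²(y, t_a) / Σ_a r²(y, t_a) ),

  with w_a the unit-norm weight vectors and r²(y, t_a) each component's
  explained y-variance (Σ_j VIP²_j = m by construction). Descriptors with
  VIP > 1 are kept and the model is refitted, iteratively; the final subset
  is the smallest m that is a local maximum of q² along the trace.
- **Validation battery** — LOO and leave-many-out q² (M = 2…6, repeated,
  with Student-t 95% CIs), y-randomization with the four chance-correlation
  categories, external r_p²/RMSP, the Golbraikh–Tropsha through-origin
  criteria (k, k′, R²₀, ratios), and the |residual| > 3·RMSE outlier rule.
- **Applicability domain** — leverage h_i = x_i′(X′X)⁻¹x_i against the
  autoscaled training matrix, control leverage h\* = 3k/n, standardized
  LOO/prediction residuals: the Williams-plot data.

The package ships the 88-compound placental CI dataset (observed and
calculated values, 65 train / 22 test / 1 excluded outlier) and a synthetic
descriptor-matrix generator with full ground truth (latent structure,
planted noise, correlated blocks, constants), so every stage is exercisable
without commercial descriptor software.

## Worked example

```sh
python examples/06_placenta_dataset_stats.py
```

prints

```
training (n=65): r2 = 0.9070, RMSE = 0.09, F = 79.4
test (n=22): r_p2 = 0.4164, RMSP = 0.23
|residual| > 3*RMSE outliers: compounds [53, 68, 75]
test without outliers (n=19): r_p2 = 0.7633, RMSP = 0.14
Golbraikh-Tropsha slopes: k = 0.9267, k' = 1.0091
control leverage h* = 3*48/65 = 2.22
selection rule on the published trace chooses m = 48 descriptors
```

Reading these numbers: the 48-descriptor model fits its 65 training
compounds tightly (r² ≈ 0.91, RMSE ≈ 0.09 CI units). Raw external
prediction over all 22 test compounds looks weak (r_p² ≈ 0.42) but is
dominated by three compounds whose residuals exceed three training RMSEs;
with those flagged and removed the remaining 19 show genuine predictive
power (r_p² ≈ 0.76, RMSP ≈ 0.14) and pass the Golbraikh–Tropsha checks
(through-origin slopes within 0.85–1.15). Compounds with leverage above
h\* = 2.22 would be extrapolations outside the model's domain.

The other examples (`examples/01…05`) walk through pretreatment, fitting
and VIP ranking, the selection loop, the validation battery, and the
applicability domain on synthetic data. The same pipeline is scriptable via
the `qsar` command (`qsar run --synthetic default --seed 7`,
`qsar validate-fixture`, `qsar pretreat|select|fit|validate|ad|synth`).

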