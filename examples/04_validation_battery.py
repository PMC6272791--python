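"""Run the full internal/external validation battery on a fitted model.

LOO and LMO cross-validation measure robustness (q² > 0.5 is the working
bound), y-randomization measures chance correlation, and the held-out test
set measures true predictive power (r_p², RMSP, Golbraikh–Tropsha).
"""
import numpy as np

from plsvip import (
    external_validation,
    fit_pls_nipals,
    generate_synthetic_qsar,
    golbraikh_tropsha,
    lmo_cv,
    loo_cv,
    predict,
    pretreat_pipeline,
    run_vip_selection,
    select_n_components,
    y_randomization,
)

X, y, _ = generate_synthetic_qsar(seed=5)
Xp, _ = pretreat_pipeline(X)

rng = np.random.default_rng(5)
test = np.sort(rng.choice(len(y), size=22, replace=False))
is_test = np.zeros(len(y), dtype=bool)
is_test[test] = True
Xtr, ytr, Xte, yte = Xp[~is_test], y[~is_test], Xp[is_test], y[is_test]

trace = run_vip_selection(Xtr, ytr)
names = trace.final_step.retained_names
A = select_n_components(Xtr[names], ytr)
fit = fit_pls_nipals(Xtr[names], ytr, A)

loo = loo_cv(Xtr[names], ytr, A)
print(f"m = {len(names)}, A = {A}, q2(LOO) = {loo.q2:.4f}, RMSV = {loo.rmsv:.2f}")
for M in (2, 3, 4, 5, 6):
    r = lmo_cv(Xtr[names], ytr, A, M=M, repeats=10, seed=100 + M)
    print(f"q2(L{M}O) = {r.mean_q2:.4f} (+/-{r.ci95_halfwidth:.4f})")
yr = y_randomization(Xtr[names], ytr, A, repeats=10, seed=999)
print(f"y-randomization: r2 = {yr.mean_r2:.4f} (+/-{yr.r2_ci95:.4f}), "
      f"q2 = {yr.mean_q2:.4f} -> {yr.category} chance correlation")

ext = external_validation(yte, predict(fit, Xte[names]))
gt = golbraikh_tropsha(yte, predict(fit, Xte[names]), q2=loo.q2)
print(f"external: r_p2 = {ext.r_p2:.4f}, RMSP = {ext.rmsp:.2f} (n_p = {ext.n_p})")
print(f"Golbraikh-Tropsha: k = {gt.k:.4f}, k' = {gt.k_prime:.4f}, passes = {gt.passes}")
# A robust model shows all LMO means > 0.5 and near-zero shuffled-y r²/q²;
# slopes near 1 with both ratios < 0.1 mean predictions track observations.
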