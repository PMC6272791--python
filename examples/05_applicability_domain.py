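"""Leverage applicability domain: the Williams-plot data.

Leverage h = x'(X'X)⁻¹x measures how far a compound sits from the training
cloud in descriptor space (control limit h* = 3k/n); standardized residuals
(> 3 in magnitude) flag response outliers.
"""
import numpy as np

from plsvip import fit_pls_nipals, generate_synthetic_qsar, williams_report

rng = np.random.default_rng(2)
Z = rng.standard_normal((40, 2))
X = np.column_stack([Z @ rng.standard_normal(2) + 0.2 * rng.standard_normal(40)
                     for _ in range(5)])
y = Z @ np.array([1.0, -0.6]) + 0.1 * rng.standard_normal(40)
fit = fit_pls_nipals(X, y, 2)

# one test compound inside the cloud, one far outside it
X_test = np.vstack([X[:1] * 1.05, X.max(axis=0) * 8])
y_test = np.array([y[0], 0.0])

rep = williams_report(fit, X, y, X_test, y_test, test_ids=["near", "far"])
print(f"h* = {rep.h_star:.3f}")
print(rep.rows.tail(4).to_string(index=False,
      formatters={"leverage": "{:.3f}".format, "std_residual": "{:.2f}".format}))
print(f"out of domain: {rep.out_of_domain}")
print(f"response outliers: {rep.outliers}")
# Compounds with leverage > h* are extrapolations — their predictions can
# only be used with care; |standardized residual| > 3 marks poorly predicted
# compounds regardless of leverage.
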