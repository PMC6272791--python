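"""Iterative VIP selection: shrink the descriptor set until q² peaks.

Each round refits the model, drops descriptors with VIP <= 1, and records
(m, A, r², RMSE, q², RMSV).  The final subset is the smallest descriptor
count that is a local q² maximum along the trace.
"""
from plsvip import generate_synthetic_qsar, pretreat_pipeline, run_vip_selection, trace_to_frame

X, y, truth = generate_synthetic_qsar(seed=3)
Xp, _ = pretreat_pipeline(X)

trace = run_vip_selection(Xp, y)
print(trace_to_frame(trace).to_string(index=False,
      formatters={"r2": "{:.4f}".format, "q2": "{:.4f}".format,
                  "RMSE": "{:.2f}".format, "RMSV": "{:.2f}".format}))
print(f"\nchosen subset: m = {trace.final_m} (rule = {trace.rule_used})")
final = set(trace.final_step.retained_names)
hits = len(final & set(truth.informative_names))
print(f"{hits} of the {len(truth.informative_names)} truly informative "
      f"descriptors survive among the final {len(final)}")
# q² (cross-validated) rises as noise descriptors are shed and falls once
# informative ones start being removed; the peak marks the working subset.
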