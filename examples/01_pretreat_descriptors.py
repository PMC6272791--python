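"""Reduce a raw descriptor pool to an informative, non-redundant set.

Generates a synthetic DRAGON-like table (constant columns, near-duplicate
blocks, noise) and applies the three pretreatment filters in order:
constant removal, SD < 0.001 removal, pairwise |r| > 0.90 removal.
"""
from plsvip import generate_synthetic_qsar, pretreat_pipeline

X, y, truth = generate_synthetic_qsar(seed=42)
Xp, log = pretreat_pipeline(X)

print(f"input descriptors:     {log.n_in}")
print(f"removed constant:      {len(log.removed_constant)}")
print(f"removed low-SD:        {len(log.removed_low_sd)}")
print(f"removed correlated:    {len(log.removed_correlated)}")
print(f"surviving descriptors: {log.n_out}")
print(f"example correlated removal: {log.removed_correlated[0]}")
# Each correlated removal records (dropped, kept partner, r); the surviving
# table has every pairwise |r| <= 0.90 and no degenerate columns, which is
# what the PLS autoscaling step downstream requires.
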