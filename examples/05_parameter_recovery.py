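"""Verify that the fitter recovers a known protective diet effect.

Generates mechanistic cohorts in which high adherence truly reduces
disease odds by a factor 0.74 within matched pairs, refits the model on
each, and compares the mean estimate with the planted truth.
"""

from meddiet import simstudy

res = simstudy.recovery_study(
    true_or_high=0.74, n_pairs=750, n_replicates=8, seeds=tuple(range(1, 9))
)
print(f"planted high-vs-low OR: {res.true_or}")
print(f"fitted ORs per replicate: {[round(float(v), 3) for v in res.ors]}")
print(f"mean fitted OR {res.mean_or:.3f} +/- {res.mc_se:.3f} (MC SE)")
print("\nThe mean estimate should sit within ~2 Monte-Carlo standard errors"
      "\nof the planted truth; larger cohorts tighten the replicate spread.")
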