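"""Rank the 103 features by information gain with MDL discretization.

Each continuous feature is discretized by supervised entropy-based binary
splitting under the Fayyad-Irani MDL stopping rule; features whose first
split is rejected score zero.  The 'optimized profile' is the non-zero-gain
subset.
"""

import fxscreen as fx
from fxscreen.selection import optimized_profile

cohort = fx.generate_cohort(fx.default_cohort_spec(n_per_group=50, seed=5))
lin = fx.profiles_to_frame([fx.profile_transcript(t) for t in cohort.transcripts])
table = fx.build_feature_table(lin, cohort.cognitive, cohort.labels)

X = table.drop(columns="label")
y = (table["label"] == "carrier").astype(int).to_numpy()

ranking = fx.rank_features(X, y)
print("top 10 features by information gain (bits):")
for r in ranking[:10]:
    print(f"  {r.feature:35s} {r.gain:.3f}  cuts={[round(c, 2) for c in r.cut_points]}")

chosen = optimized_profile(ranking)
print(f"\noptimized profile: {len(chosen)} of {len(ranking)} features "
      "carry non-zero gain")
# Dysfluency counts/rates dominate the ranking; the injected cognitive-scale
# shifts appear with smaller but non-zero gain, mirroring how linguistic
# features outrank cognitive ones in this screening setting.
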