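"""Cohort-level dissociation: group cluster test plus 2x2 within-subject ANOVA.

Twelve phantom subjects are analysed end to end (design -> BOLD -> GLM ->
z-scored betas -> searchlights -> smoothed accuracy maps -> sign-flip
cluster test against 50% chance), and region-mean accuracies enter a
repeated-measures ANOVA over region x classifier.
"""

from hubspoke.studies import dissociation_study

result = dissociation_study(seed=1, n_subjects=12, n_perm=400)

print("fraction of each planted region covered by significant clusters:")
for scheme, cov in result.coverage.items():
    print(f"  {scheme:17s} hub {cov['semantic_hub']:.2f}   "
          f"modality {cov['modality_region']:.2f}")

print("\nANOVA (region x classifier), F(1, 11):")
print(result.anova.effects.round(4).to_string())
print("\npost-hoc paired t (modality_region - semantic_hub):")
print(result.anova.posthoc.round(4).to_string(index=False))
print(f"\nfull dissociation recovered: {result.dissociated()}")
# A significant interaction with opposite-signed simple effects means each
# region is read out best by its own classifier — the hub-and-spoke
# signature the phantom plants.
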