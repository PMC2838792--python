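"""Test whether a clade's symptom distribution differs from a diagnosis.

The four-group likelihood-ratio test splits the cohort into: the diagnostic
category outside the clade (group 2), the clade outside the category
(group 3), their intersection (group 4), and everyone else (group 1, which
cancels). H0 pools groups 2-4; HA frees group 2. Significance comes from
permuting clade membership.
"""

from cladelink import simulate_symptom_cohort
from cladelink.symptoms import (four_group_counts, lrt_symptom, permutation_p)

probs = {
    "depression_sleep": {"insomnia": 0.9, "low_mood": 0.8, "anhedonia": 0.6},
    "depression_other": {"insomnia": 0.2, "low_mood": 0.8, "anhedonia": 0.6},
}
matrix, labels = simulate_symptom_cohort(
    {"depression_sleep": 60, "depression_other": 80}, probs, seed=5)

# the "clade" recovers the sleep-disturbance subgroup; the diagnostic
# category is everyone with the depression label (here: the whole cohort)
clade = {u for u, g in labels.items() if g == "depression_sleep"}
category = set(labels)

counts = four_group_counts("insomnia", matrix, clade, category)
print(f"groups: x2/n2 = {counts.x2}/{counts.n2} (category only), "
      f"x4/n4 = {counts.x4}/{counts.n4} (clade within category)")

res = lrt_symptom(counts)
print(f"LRT statistic 2(lnL_A - lnL_0) = {res.statistic:.2f} "
      f"(p-hat null {res.p_null:.2f}, alternative {res.p_alt})")

res = permutation_p("insomnia", matrix, clade, category,
                    n_perm=10_000, seed=1)
print(f"permutation p = {res.perm_p:.5f} over 10,000 label shuffles")
print("a small p says insomnia is enriched in the clade beyond what its "
      "share of the diagnostic category explains")

null = permutation_p("low_mood", matrix, clade, category, n_perm=2000, seed=2)
print(f"control trait 'low_mood' (same rate everywhere): p = {null.perm_p:.3f}")
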