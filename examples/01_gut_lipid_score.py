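"""Gut layer: pathway comparison and the composite lipid-catabolism score.

Simulates a 8-vs-8 shotgun-metagenomics cohort with the three lipid
pathways (ko00071 fatty acid degradation, ko00561 glycerolipid metabolism,
ko00564 glycerophospholipid metabolism) shifted down in the psoriasis
group, then tests every pathway and summarizes the lipid set as a
per-sample sum of cohort z-scores.
"""

from triplehit import gut, synthdata

table, truth = synthdata.gen_pathway_table(
    planted=synthdata.default_lipid_shifts(), seed=42
)
tests = gut.compare_pathways(table)
print("Per-pathway Wilcoxon results for the planted lipid set:")
print(tests.loc[list(gut.DEFAULT_LIPID_SET), ["p_value", "q_value", "direction"]])

score = gut.lipid_score(table)
print("\nLipid degradation functional score (z-units per sample):")
print(score.per_sample_score.round(2).to_string())
print(f"\nGroup Wilcoxon p on the composite score: {score.group_p:.4g}")
print(
    "A negative median in the PsO group with a small p indicates the planted "
    "coordinated loss of microbial lipid catabolic potential was detected; "
    "direction = -1 rows show each lipid pathway individually shifted down."
)
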