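"""Regulatory network layer: TF activity inference and marker cell scores.

Simulates a logCPM matrix in which one transcription factor's regulon is
coherently activated in the case group and one cell population's markers
are shifted up, then scores TF activity with a permutation-normalized
weighted mean and cell abundance with marker means plus Wilcoxon tests.
"""

import warnings

import numpy as np
import pandas as pd

from triplehit import regnet

warnings.simplefilter("ignore")
rng = np.random.default_rng(0)

genes = [f"G{i:04d}" for i in range(800)]
samples = [f"HC{i:02d}" for i in range(12)] + [f"PsO{i:02d}" for i in range(13)]
expr = pd.DataFrame(rng.normal(5, 1, size=(800, 25)), index=genes, columns=samples)
group = pd.Series(["HC"] * 12 + ["PsO"] * 13, index=samples)

active_targets = genes[:12]
expr.loc[active_targets, group == "PsO"] += 1.5  # activated regulon
neutro_markers = genes[100:105]
expr.loc[neutro_markers, group == "PsO"] += 2.0  # infiltrating population

regulons = [
    regnet.Regulon("RELA_like", active_targets, np.ones(12)),
    regnet.Regulon(
        "NULL_TF", [genes[i] for i in rng.choice(800, 15, replace=False)],
        rng.choice([-1.0, 1.0], 15),
    ),
]
act = regnet.tf_activity(expr, regulons, n_perm=500, seed=1)
diff = regnet.differential_activity(act, group, ("HC", "PsO"))
print("Differential TF activity (permutation z-score scale):")
print(diff.round(3))

markers = {"Neutrophils": neutro_markers, "B_lineage": genes[200:205]}
scores, tests = regnet.cell_scores(expr, markers, group, ("HC", "PsO"))
print("\nCell-score group tests (Wilcoxon, BH):")
print(tests[["effect", "p_value", "q_value"]].round(4))
print(
    "The activated regulon shows a positive differential effect with a tiny "
    "q-value while the random regulon stays null; the shifted marker set is "
    "flagged with a positive median difference, the untouched one is not."
)
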