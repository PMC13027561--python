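"""Skin transcriptome: TMM + logCPM, DEG calling, pre-ranked GSEA and
keyword-axis aggregation.

Simulates a 12-vs-13 bulk RNA-seq cohort with a planted up-regulated
inflammatory gene set and a down-regulated lipid set, normalizes with TMM,
calls DEGs (|log2FC| >= 1, FDR <= 0.05), runs pre-ranked GSEA on the
log2FC ranking and aggregates set results into the three biological axes.
"""

import warnings

import numpy as np

from triplehit import synthdata, transcriptome as tr

warnings.simplefilter("ignore")

inflam = [f"G{i:04d}" for i in range(0, 30)]
lipid = [f"G{i:04d}" for i in range(30, 60)]
planted = [(g, 2.0) for g in inflam] + [(g, -2.0) for g in lipid]
cm, _ = synthdata.gen_counts(n_gene=1500, planted_de=planted, seed=5)

factors, logcpm = tr.tmm_normalize(cm)
print(f"TMM factors (geometric mean {np.exp(np.mean(np.log(factors))):.3f}):")
print(factors.round(3).head().to_string())

deg = tr.de_genes(logcpm, cm.group, cm.levels)
print(f"\nDEGs at |log2FC| >= 1 and FDR <= 0.05: {int(deg['is_deg'].sum())}")

gene_sets = {
    "HALLMARK_TNFA_SIGNALING_VIA_NFKB": inflam,
    "HALLMARK_FATTY_ACID_METABOLISM": lipid,
    "HALLMARK_MYOGENESIS": [f"G{i:04d}" for i in range(200, 240)],
}
gsea = tr.preranked_gsea(deg["log2fc"], gene_sets, n_perm=500, seed=1)
print("\nPre-ranked GSEA:")
print(gsea[["es", "nes", "p_value", "padj"]].round(3))

axes = tr.aggregate_axes(gsea)
print("\nAxis aggregation (median member NES; significant if median padj < 0.05):")
print(axes[["n_members", "axis_nes", "median_padj", "significant"]])
print(
    "The planted inflammatory set scores a large positive NES (enriched in "
    "lesional samples), the lipid set a negative NES, and the axis table "
    "mirrors that: inflammation up, lipid down, the unmatched set in no axis."
)
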