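"""Evidence-tiered, directionality-constrained miRNA-mRNA bridge.

miRNA-target interactions arrive as an evidence edge list naming which
validated databases (miRTarBase, TarBase) and which prediction resources
(TargetScan, DIANA, miRDB) support each pair.  Edges are tiered:

* tier 2 -- any experimentally validated source;
* tier 1 -- no validation but at least two independent prediction resources;
* tier 0 -- a single prediction resource; excluded.

Retained edges are then filtered by canonical repression logic against the
paired differential-expression tables: the miRNA must be a bridge driver
(DE at FDR < 0.05 with |log2FC| > 1) and its target a DEG of the opposite
sign.  Surviving edges are labeled with a pathological effector module
(AMP core, barrier-lipid, keratinocyte differentiation, auxiliary lipid)
from user-editable gene lists, and summarized as Sankey-style edge counts
per (miRNA, module, target direction) flow.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "VALIDATED_SOURCES",
    "PREDICTION_SOURCES",
    "MODULE_PRIORITY",
    "tier_edges",
    "constrain_directionality",
    "assign_modules",
    "sankey_counts",
]

VALIDATED_SOURCES = frozenset({"miRTarBase", "TarBase"})
PREDICTION_SOURCES = frozenset({"TargetScan", "DIANA", "miRDB"})

#: module label precedence when curated lists overlap
MODULE_PRIORITY = ("AMP_core", "barrier_lipid", "keratinocyte_diff", "aux_lipid")


def _parse_sources(field) -> frozenset[str]:
    if isinstance(field, frozenset):
        return field
    if isinstance(field, (set, list, tuple)):
        return frozenset(field)
    if not isinstance(field, str) or not field:
        return frozenset()
    return frozenset(s for s in field.split(";") if s)


def tier_edges(edges: pd.DataFrame, drop_tier0: bool = True) -> pd.DataFrame:
    """Assign evidence tiers to a miRNA-target edge list.

    ``edges`` needs columns ``mirna_id``, ``gene_symbol``,
    ``validated_sources`` and ``prediction_sources`` (';'-joined strings or
    sets).  Unknown resource names raise with the allowed vocabulary.
    """
    out = edges.copy()
    validated = edges["validated_sources"].map(_parse_sources)
    predicted = edges["prediction_sources"].map(_parse_sources)
    for col, vocab in ((validated, VALIDATED_SOURCES), (predicted, PREDICTION_SOURCES)):
        unknown = set().union(*col) - vocab
        if unknown:
            raise ValueError(
                f"unknown resource names {sorted(unknown)}; "
                f"validated sources: {sorted(VALIDATED_SOURCES)}, "
                f"prediction sources: {sorted(PREDICTION_SOURCES)}"
            )
    if ((validated.map(len) == 0) & (predicted.map(len) == 0)).any():
        raise ValueError("every edge needs at least one supporting source")
    tier = pd.Series(0, index=edges.index)
    tier[predicted.map(len) >= 2] = 1
    tier[validated.map(len) >= 1] = 2
    out["tier"] = tier
    if drop_tier0:
        out = out[out["tier"] >= 1]
    return out


def constrain_directionality(
    edges: pd.DataFrame,
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    id_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only canonical-repression edges between paired DE tables.

    An edge survives iff its miRNA is a bridge driver (``is_bridge_driver``
    in ``mirna_de``) and its target is a DEG (``is_deg`` in ``mrna_de``)
    with the opposite log2FC sign.  ``id_map`` optionally maps the mRNA
    table's gene ids to symbols (columns ``gene_id``, ``gene_symbol``)
    before matching.  Returns the retained edges (with direction columns and
    ``inverse=True``) and per-reason drop counts.
    """
    mrna = mrna_de
    if id_map is not None:
        mapping = id_map.set_index("gene_id")["gene_symbol"]
        mrna = mrna_de.copy()
        mrna.index = mrna.index.map(lambda g: mapping.get(g, g))
        mrna = mrna[~mrna.index.duplicated()]
    drops = dict(mirna_absent=0, gene_absent=0, mirna_not_driver=0,
                 gene_not_deg=0, same_direction=0)
    rows = []
    for _, edge in edges.iterrows():
        mi, gene = edge["mirna_id"], edge["gene_symbol"]
        if mi not in mirna_de.index:
            drops["mirna_absent"] += 1
            continue
        if gene not in mrna.index:
            drops["gene_absent"] += 1
            continue
        if not bool(mirna_de.loc[mi, "is_bridge_driver"]):
            drops["mirna_not_driver"] += 1
            continue
        if not bool(mrna.loc[gene, "is_deg"]):
            drops["gene_not_deg"] += 1
            continue
        mi_fc = float(mirna_de.loc[mi, "log2fc"])
        g_fc = float(mrna.loc[gene, "log2fc"])
        if mi_fc * g_fc >= 0:
            drops["same_direction"] += 1
            continue
        rec = edge.to_dict()
        rec.update(
            mirna_direction="up" if mi_fc > 0 else "down",
            gene_direction="up" if g_fc > 0 else "down",
            inverse=True,
        )
        rows.append(rec)
    retained = pd.DataFrame(rows, columns=[*edges.columns, "mirna_direction",
                                           "gene_direction", "inverse"])
    return retained, drops


def assign_modules(
    edges: pd.DataFrame,
    modules: dict[str, list[str]],
    priority: tuple[str, ...] = MODULE_PRIORITY,
) -> pd.DataFrame:
    """Label each retained edge with its target's pathological module.

    Overlapping module lists are resolved by the declared priority order; a
    target in no list gets module ``none`` (excluded from module-filtered
    summaries).
    """
    if not modules:
        warnings.warn("empty module collection; all edges labeled 'none'", stacklevel=2)
    ordered = [m for m in priority if m in modules] + [
        m for m in modules if m not in priority
    ]
    lookup: dict[str, str] = {}
    for name in reversed(ordered):  # earlier (higher-priority) names overwrite
        for gene in modules[name]:
            lookup[gene] = name
    out = edges.copy()
    out["module"] = out["gene_symbol"].map(lambda g: lookup.get(g, "none"))
    return out


def sankey_counts(labeled_edges: pd.DataFrame, include_none: bool = False) -> pd.DataFrame:
    """Edge counts per (miRNA, module, target-direction) flow.

    Flow widths of an alluvial plot; counts sum to the number of
    module-labeled retained edges.
    """
    df = labeled_edges if include_none else labeled_edges[labeled_edges["module"] != "none"]
    return (
        df.groupby(["mirna_id", "module", "gene_direction"], sort=True)
        .size()
        .rename("n_edges")
        .reset_index()
    )
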