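"""Promoter-aware over-representation analysis (ORA) for DMR genes.

EPIC-style arrays over-sample promoters, so testing DMR-associated genes
against a whole-genome background inflates promoter-heavy categories.  The
background universe here is restricted to genes carrying at least one probe
in a promoter category (TSS1500, TSS200, 5'UTR, 1st Exon); enrichment is
the hypergeometric upper tail within that universe, BH-adjusted across the
sets of a collection.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from . import stats
from .methylome import PROMOTER_CATEGORIES

__all__ = ["build_promoter_universe", "ora"]


def split_genes(field: str) -> list[str]:
    """Split a probe's (possibly multi-gene) annotation on ';'."""
    if not isinstance(field, str) or not field:
        return []
    return [g for g in field.split(";") if g]


def build_promoter_universe(probes: pd.DataFrame) -> set[str]:
    """Unique genes with >=1 probe in any promoter category."""
    if len(probes) == 0:
        raise ValueError("empty probe annotation")
    mask = probes["promoter_category"].isin(PROMOTER_CATEGORIES)
    universe: set[str] = set()
    for field in probes.loc[mask, "genes"]:
        universe.update(split_genes(field))
    if not universe:
        raise ValueError("no promoter-category probes with gene annotations")
    return universe


def ora(
    query: set[str],
    universe: set[str],
    gene_sets: dict[str, list[str]],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set collection.

    Query genes outside the universe are dropped with a warning; each gene
    set is intersected with the universe and skipped when fewer than
    ``min_set_size`` genes remain.  p = P(X >= n_hits) under sampling
    n_query genes from the universe; BH q across the tested sets.
    """
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped", stacklevel=2
        )
    q = query & universe
    if not q:
        warnings.warn("query empty after intersecting with universe", stacklevel=2)
        return pd.DataFrame(
            columns=["set_size_in_universe", "n_hits", "n_query", "n_universe", "p_value", "q_value"]
        )
    n_universe = len(universe)
    n_query = len(q)
    rows = []
    for set_id, genes in gene_sets.items():
        in_uni = set(genes) & universe
        if len(in_uni) < min_set_size:
            continue
        hits = len(q & in_uni)
        p = float(hypergeom.sf(hits - 1, n_universe, len(in_uni), n_query))
        rows.append(
            dict(
                set_id=set_id,
                set_size_in_universe=len(in_uni),
                n_hits=hits,
                n_query=n_query,
                n_universe=n_universe,
                p_value=min(1.0, p),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("set_id")
        out["q_value"] = stats.bh_adjust(out["p_value"].to_numpy())
    return out
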