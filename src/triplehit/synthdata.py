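"""Synthetic multi-omics cohorts with planted, fully known ground truth.

Each generator emulates one input layer of the analysis at the study's
cohort sizes and returns both the data container and a
:class:`SyntheticTruth` recording exactly what was planted, so every
downstream stage (pathway tests, DMR calling, miRNA DE, bridge filtering,
DEG/GSEA) can be scored for recovery without any external download.

Models
------
* Pathway tables: per-group expected compositions differ by planted
  relative shifts; samples are Dirichlet draws around the group
  composition, so columns close to 1 exactly.
* Methylation: beta is generated on the logit scale (baseline mixture of
  low/intermediate/high methylation states plus Gaussian noise) and
  inverse-logit transformed, keeping beta strictly inside (0,1).  Planted
  DMRs are contiguous CpG runs whose case-group logit is shifted to move
  mean beta by the requested delta.
* RNA-seq counts: negative binomial with log-normal gene means, gene-wise
  dispersion and per-sample library-size factors; planted genes change
  their expected mean by the requested log2 fold-change.
* Paired regulome: a miRNA array matrix (log2-normal noise, n = 4 vs 4)
  and an mRNA count matrix with planted inverse-direction regulatory edges
  carrying evidence-tier flags, plus decoy edges over all tier/direction
  combinations, and module gene lists seeded with canonical psoriasis
  effector genes.

A fixed seed plus fixed parameters reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gut import PathwayAbundanceTable
from .methylome import MethylationData
from .transcriptome import CountMatrix

__all__ = [
    "SyntheticTruth",
    "PlantedShift",
    "default_lipid_shifts",
    "gen_pathway_table",
    "DmrSpec",
    "CovariateSpec",
    "gen_methylation",
    "gen_counts",
    "RegulomeSpec",
    "gen_paired_regulome",
    "DEFAULT_MODULES",
    "write_truth",
]


@dataclass
class SyntheticTruth:
    """Record of everything planted into a synthetic cohort."""

    seed: int
    planted_pathways: list[tuple[str, str, float]] = field(default_factory=list)
    planted_dmrs: list[tuple[str, int, int, float]] = field(default_factory=list)
    planted_de_features: list[tuple[str, float]] = field(default_factory=list)
    planted_edges: list[tuple[str, str, int, bool, str]] = field(default_factory=list)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)


# ---------------------------------------------------------------------------
# pathway layer

_KEGG_L3 = [
    "ko00071",  # fatty acid degradation
    "ko00561",  # glycerolipid metabolism
    "ko00564",  # glycerophospholipid metabolism
    "ko00600",  # sphingolipid metabolism
    "ko00650",  # butanoate metabolism
    "ko00640",  # propanoate metabolism
    "ko00010",  # glycolysis / gluconeogenesis
    "ko00620",  # pyruvate metabolism
    "ko00500",  # starch and sucrose metabolism
    "ko00520",  # amino and nucleotide sugar metabolism
    "ko00250",  # alanine, aspartate and glutamate metabolism
    "ko00270",  # cysteine and methionine metabolism
]


@dataclass(frozen=True)
class PlantedShift:
    """A planted between-group shift for one pathway.

    ``effect`` is the relative change of the pathway's expected relative
    abundance in the case group (0.5 means a 50% change in the stated
    direction).
    """

    pathway_id: str
    direction: str  # "up" or "down"
    effect: float = 0.5


def default_lipid_shifts(effect: float = 0.5) -> list[PlantedShift]:
    """Downward shifts of the three lipid-catabolism pathways."""
    return [PlantedShift(p, "down", effect) for p in ("ko00071", "ko00561", "ko00564")]


def gen_pathway_table(
    n_per_group: int = 8,
    n_pathways: int = 40,
    planted: list[PlantedShift] | None = None,
    concentration: float = 300.0,
    seed: int = 0,
) -> tuple[PathwayAbundanceTable, SyntheticTruth]:
    """Compositional pathway x sample table with planted group shifts.

    Samples are Dirichlet draws (precision ``concentration``) around their
    group's expected composition, so each column sums to one.  A planted
    shift multiplies the case group's expected abundance by (1 +/- effect)
    before renormalization; a shift that would drive an expected abundance
    negative is rejected.
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    rng = np.random.default_rng(seed)
    ids = _KEGG_L3[:n_pathways] + [f"ko9{i:04d}" for i in range(max(0, n_pathways - len(_KEGG_L3)))]
    planted = list(planted or [])
    unknown = [s.pathway_id for s in planted if s.pathway_id not in ids]
    if unknown:
        raise ValueError(f"planted pathways absent from table: {unknown}")
    base = rng.lognormal(mean=0.0, sigma=0.8, size=n_pathways)
    base = base / base.sum()
    shifted = base.copy()
    for s in planted:
        if s.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {s.direction!r}")
        mult = 1.0 + s.effect if s.direction == "up" else 1.0 - s.effect
        i = ids.index(s.pathway_id)
        new = base[i] * mult
        if new < 0:
            raise ValueError(
                f"effect {s.effect} drives {s.pathway_id} abundance negative "
                "before renormalization"
            )
        shifted[i] = new
    shifted = shifted / shifted.sum()

    hc = rng.dirichlet(concentration * base, size=n_per_group).T
    pso = rng.dirichlet(concentration * shifted, size=n_per_group).T
    cols = [f"HC{i+1:02d}" for i in range(n_per_group)] + [
        f"PsO{i+1:02d}" for i in range(n_per_group)
    ]
    abund = pd.DataFrame(np.hstack([hc, pso]), index=ids, columns=cols)
    group = pd.Series(["HC"] * n_per_group + ["PsO"] * n_per_group, index=cols, name="group")
    truth = SyntheticTruth(
        seed=seed,
        planted_pathways=[(s.pathway_id, s.direction, s.effect) for s in planted],
    )
    return PathwayAbundanceTable(abund, group), truth


# ---------------------------------------------------------------------------
# methylation layer


@dataclass(frozen=True)
class DmrSpec:
    """A planted contiguous differentially methylated region."""

    n_cpgs: int = 10
    delta_beta: float = 0.10
    chrom: str | None = None


@dataclass(frozen=True)
class CovariateSpec:
    """Sample covariate model: independent by default, optionally confounded.

    ``confounded=True`` ties age to group (cases older on average) and
    ``age_effect`` adds a logit-scale methylation slope per year of
    (centered) age to a random ``age_effect_fraction`` of CpGs, so covariate
    adjustment is exercised.
    """

    confounded: bool = False
    age_effect: float = 0.0
    age_effect_fraction: float = 0.1


_PROMOTER_CHOICES = ["TSS1500", "TSS200", "5UTR", "1stExon", "other"]
_PROMOTER_PROBS = [0.15, 0.12, 0.10, 0.08, 0.55]


def _logit(b: np.ndarray) -> np.ndarray:
    return np.log(b / (1 - b))


def gen_methylation(
    n_cpg: int = 1000,
    n_per_group: int = 10,
    planted_dmrs: list[DmrSpec] | tuple[DmrSpec, ...] = (),
    noise_sd: float = 0.3,
    covariates: CovariateSpec = CovariateSpec(),
    seed: int = 0,
    sex_chrom_fraction: float = 0.02,
    flag_fraction: float = 0.02,
    detection_fail_fraction: float = 0.01,
) -> tuple[MethylationData, SyntheticTruth]:
    """Logit-normal beta matrix with planted contiguous DMRs.

    CpGs are laid out on two autosomes (plus a small chrX block to exercise
    probe QC) with inter-CpG gaps of 150-600 bp, so neighbors are always
    within the 1 kb smoothing bandwidth.  Planted regions are runs of
    consecutive CpGs (at least 2; defaults give 10) with a mid-range
    baseline whose case-group logit is shifted to move mean beta by
    ``delta_beta``; planted regions never overlap and never receive QC
    flags.
    """
    for spec in planted_dmrs:
        if spec.n_cpgs < 2:
            raise ValueError("a planted region needs at least 2 CpGs")
    rng = np.random.default_rng(seed)
    n_sex = int(round(n_cpg * sex_chrom_fraction))
    n_auto = n_cpg - n_sex
    half = n_auto // 2
    chroms = np.array(["chr1"] * half + ["chr2"] * (n_auto - half) + ["chrX"] * n_sex)
    pos = np.empty(n_cpg, dtype=int)
    for chrom in ("chr1", "chr2", "chrX"):
        idx = np.where(chroms == chrom)[0]
        gaps = rng.integers(150, 601, size=idx.size)
        pos[idx] = 10_000 + np.cumsum(gaps)

    # baseline methylation states: mixture of low / intermediate / high
    state = rng.choice(3, size=n_cpg, p=[0.4, 0.2, 0.4])
    centers = np.array([-2.5, 0.0, 2.5])
    base_logit = rng.normal(centers[state], 0.8)

    # place planted regions on autosomes, separated by > lambda from each other
    total_needed = sum(s.n_cpgs for s in planted_dmrs)
    if total_needed > n_auto // 2:
        raise ValueError("too many planted CpGs for the requested matrix size")
    used: set[int] = set()
    planted_records: list[tuple[str, int, int, float]] = []
    planted_shift = np.zeros(n_cpg)
    for spec in planted_dmrs:
        chrom = spec.chrom or str(rng.choice(["chr1", "chr2"]))
        cand = np.where(chroms == chrom)[0]
        for _ in range(200):
            start_i = int(rng.integers(0, cand.size - spec.n_cpgs))
            block = cand[start_i : start_i + spec.n_cpgs]
            guard = set(range(block[0] - 5, block[-1] + 6))
            if guard.isdisjoint(used):
                break
        else:
            raise ValueError("could not place planted regions without overlap")
        used.update(guard)
        base_logit[block] = rng.normal(0.0, 0.25, size=spec.n_cpgs)
        b0 = 1.0 / (1.0 + np.exp(-base_logit[block]))
        b1 = np.clip(b0 + spec.delta_beta, 0.01, 0.99)
        planted_shift[block] = _logit(b1) - _logit(b0)
        planted_records.append(
            (chrom, int(pos[block].min()), int(pos[block].max()) + 1, spec.delta_beta)
        )

    n_samples = 2 * n_per_group
    group = np.array([0] * n_per_group + [1] * n_per_group)
    sex = rng.choice(["F", "M"], size=n_samples)
    if covariates.confounded:
        age = np.where(group == 0, rng.normal(40, 8, n_samples), rng.normal(52, 8, n_samples))
    else:
        age = rng.normal(45, 12, n_samples)
    age = np.round(np.clip(age, 20, 80))

    age_slope = np.zeros(n_cpg)
    if covariates.age_effect != 0.0:
        affected = rng.random(n_cpg) < covariates.age_effect_fraction
        age_slope[affected] = covariates.age_effect

    logit = (
        base_logit[:, None]
        + planted_shift[:, None] * group[None, :]
        + age_slope[:, None] * (age - age.mean())[None, :]
        + rng.normal(0.0, noise_sd, size=(n_cpg, n_samples))
    )
    beta = 1.0 / (1.0 + np.exp(-logit))
    beta = np.clip(beta, 1e-12, 1 - 1e-12)

    cpg_ids = [f"cg{i:08d}" for i in range(n_cpg)]
    cols = [f"HC{i+1:02d}" for i in range(n_per_group)] + [
        f"PsO{i+1:02d}" for i in range(n_per_group)
    ]
    detp = rng.uniform(0.0, 0.008, size=(n_cpg, n_samples))
    plantable = np.array([i not in used for i in range(n_cpg)])
    fail = np.where(plantable & (rng.random(n_cpg) < detection_fail_fraction))[0]
    for i in fail:
        detp[i, rng.integers(0, n_samples)] = rng.uniform(0.02, 0.05)
    snp = plantable & (chroms != "chrX") & (rng.random(n_cpg) < flag_fraction)
    cross = plantable & (chroms != "chrX") & (rng.random(n_cpg) < flag_fraction)

    gene_no = np.arange(n_cpg) // 8
    probes = pd.DataFrame(
        dict(
            chrom=chroms,
            pos=pos,
            sex_chrom=(chroms == "chrX"),
            snp_overlap=snp,
            cross_reactive=cross,
            promoter_category=rng.choice(_PROMOTER_CHOICES, size=n_cpg, p=_PROMOTER_PROBS),
            genes=[f"GENE{g:04d}" for g in gene_no],
        ),
        index=cpg_ids,
    )
    samples = pd.DataFrame(
        dict(group=np.where(group == 0, "HC", "PsO"), sex=sex, age=age), index=cols
    )
    data = MethylationData(
        beta=pd.DataFrame(beta, index=cpg_ids, columns=cols),
        detection_p=pd.DataFrame(detp, index=cpg_ids, columns=cols),
        probes=probes,
        samples=samples,
    )
    truth = SyntheticTruth(seed=seed, planted_dmrs=planted_records)
    return data, truth


# ---------------------------------------------------------------------------
# RNA-seq counts


def gen_counts(
    n_gene: int = 2000,
    n_per_group: int | tuple[int, int] = (12, 13),
    dispersion: float = 0.1,
    planted_de: list[tuple[str, float]] | None = None,
    libsize_factors: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    mean_log2: float = 5.0,
    mean_log2_sd: float = 1.5,
    base_libsize_scale: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial count matrix with planted log2 fold-changes.

    Gene means are log-normal; variance follows mu + dispersion * mu^2.
    ``libsize_factors`` (one per sample, all positive) multiplicatively
    scale every gene's expected count in that sample.  Planted genes change
    the case group's expected mean by 2**log2fc.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if isinstance(n_per_group, int):
        n_ref, n_case = n_per_group, n_per_group
    else:
        n_ref, n_case = n_per_group
    n_samples = n_ref + n_case
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_gene)]
    if len(gene_ids) != n_gene:
        raise ValueError("gene_ids length must equal n_gene")
    planted_de = list(planted_de or [])
    absent = [g for g, _ in planted_de if g not in gene_ids]
    if absent:
        raise ValueError(f"planted DE genes absent from gene ids: {absent}")
    if libsize_factors is None:
        libsize_factors = np.ones(n_samples)
    libsize_factors = np.asarray(libsize_factors, dtype=float)
    if libsize_factors.size != n_samples or (libsize_factors <= 0).any():
        raise ValueError("libsize_factors must be positive, one per sample")

    mu_g = base_libsize_scale * 2.0 ** rng.normal(mean_log2, mean_log2_sd, size=n_gene)
    lfc = np.zeros(n_gene)
    pos_of = {g: i for i, g in enumerate(gene_ids)}
    for g, f in planted_de:
        lfc[pos_of[g]] = f
    group = np.array([0] * n_ref + [1] * n_case)
    mu = mu_g[:, None] * libsize_factors[None, :] * 2.0 ** (lfc[:, None] * group[None, :])
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    cols = [f"HC{i+1:02d}" for i in range(n_ref)] + [f"PsO{i+1:02d}" for i in range(n_case)]
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=cols),
        group=pd.Series(np.where(group == 0, "HC", "PsO"), index=cols, name="group"),
    )
    truth = SyntheticTruth(seed=seed, planted_de_features=planted_de)
    return cm, truth


# ---------------------------------------------------------------------------
# paired miRNA / mRNA regulome

#: curated effector-module seeds; AMP core carries the canonical psoriasis
#: antimicrobial-peptide genes, the others hold barrier/lipid and
#: differentiation markers.  Contents are configuration, not ground truth.
DEFAULT_MODULES: dict[str, list[str]] = {
    "AMP_core": ["DEFB4A", "S100A7", "S100A8", "S100A9", "IL36G", "LCN2", "PI3", "CAMP"],
    "barrier_lipid": ["FLG", "LOR", "CERS3", "ELOVL4", "ABCA12", "SPINK5"],
    "keratinocyte_diff": ["KRT6A", "KRT16", "KRT17", "IVL", "TGM1", "SBSN"],
    "aux_lipid": ["FABP5", "SCD", "FADS1", "FADS2"],
}


@dataclass(frozen=True)
class RegulomeSpec:
    """Sizes and effect sizes for the paired miRNA/mRNA cohort."""

    n_mirna: int = 150
    n_gene: int = 1200
    n_per_group_mirna: int = 4
    mirna_noise_sd: float = 0.5
    mirna_log2fc: float = 3.0
    gene_log2fc: float = 2.5
    n_inverse_per_module: int = 3
    n_decoys: int = 60


def gen_paired_regulome(
    spec: RegulomeSpec = RegulomeSpec(),
    modules: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> dict:
    """Paired miRNA matrix, mRNA counts, evidence edges and module lists.

    Planted inverse edges connect a DE miRNA to a DE module gene of the
    opposite sign, alternating between validated (tier-2) and
    two-prediction (tier-1) evidence.  Decoys cover every remaining filter
    branch: same-direction DE pairs at every tier, non-DE pairs, and
    single-resource (tier-0) support.  Returns a dict with keys ``mirna``
    (:class:`~triplehit.mirna.MirnaMatrix`-ready DataFrame + group),
    ``mrna`` (:class:`~triplehit.transcriptome.CountMatrix`), ``edges``,
    ``modules`` and ``truth``.
    """
    rng = np.random.default_rng(seed)
    modules = {k: list(v) for k, v in (modules or DEFAULT_MODULES).items()}
    module_genes = [g for gl in modules.values() for g in gl]
    n_fill = spec.n_gene - len(module_genes)
    if n_fill <= 0:
        raise ValueError("n_gene must exceed the module gene count")
    gene_ids = module_genes + [f"G{i:04d}" for i in range(n_fill)]

    # plant DE on module genes with alternating signs and on some background genes
    planted_gene_de: list[tuple[str, float]] = []
    for m, genes in modules.items():
        for k, g in enumerate(genes):
            sign = 1.0 if (k % 2 == 0) else -1.0
            planted_gene_de.append((g, sign * spec.gene_log2fc))
    n_bg_de = 20
    bg_de = [f"G{i:04d}" for i in range(n_bg_de)]
    for k, g in enumerate(bg_de):
        planted_gene_de.append((g, (1.0 if k % 2 == 0 else -1.0) * spec.gene_log2fc))
    gene_lfc = dict(planted_gene_de)

    mrna, _ = gen_counts(
        n_gene=spec.n_gene,
        n_per_group=(12, 13),
        planted_de=planted_gene_de,
        gene_ids=gene_ids,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # miRNA layer: planted drivers opposite in sign to their bridge target
    mirna_ids = [f"miR-{i:03d}-5p" for i in range(spec.n_mirna)]
    planted_edges: list[tuple[str, str, int, bool, str]] = []
    mirna_lfc: dict[str, float] = {}
    edge_rows: list[dict] = []
    mi_iter = iter(mirna_ids)
    tier_toggle = 0
    for m, genes in modules.items():
        for g in genes[: spec.n_inverse_per_module]:
            mi = next(mi_iter)
            mirna_lfc[mi] = -np.sign(gene_lfc[g]) * spec.mirna_log2fc
            tier = 2 if tier_toggle % 2 == 0 else 1
            tier_toggle += 1
            edge_rows.append(
                dict(
                    mirna_id=mi,
                    gene_symbol=g,
                    validated_sources="miRTarBase" if tier == 2 else "",
                    prediction_sources="TargetScan;miRDB" if tier == 1 else "",
                )
            )
            planted_edges.append((mi, g, tier, True, m))

    # decoys: same-direction DE pairs (all tiers) and non-DE pairs
    de_up = [g for g, f in gene_lfc.items() if f > 0]
    de_down = [g for g, f in gene_lfc.items() if f < 0]
    tier_sources = {
        2: ("TarBase", ""),
        1: ("", "TargetScan;DIANA"),
        0: ("", "TargetScan"),
    }
    decoy_records: list[tuple[str, str, int, bool, str]] = []
    for _ in range(spec.n_decoys):
        mi = next(mi_iter)
        tier = int(rng.integers(0, 3))
        same_dir = bool(rng.random() < 0.6)
        if same_dir:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mirna_lfc[mi] = sign * spec.mirna_log2fc
            pool = de_up if sign > 0 else de_down
            g = str(rng.choice(pool))
        else:
            # non-DE decoy: neither side planted
            mirna_lfc[mi] = 0.0
            g = f"G{int(rng.integers(n_bg_de, n_fill)):04d}"
        val, pred = tier_sources[tier]
        edge_rows.append(
            dict(mirna_id=mi, gene_symbol=g, validated_sources=val, prediction_sources=pred)
        )
        decoy_records.append((mi, g, tier, False, "decoy"))

    for mi, g, *_ in planted_edges + decoy_records:
        if mi not in mirna_ids or g not in gene_ids:
            raise ValueError(f"edge references absent feature: {mi} -> {g}")

    n = spec.n_per_group_mirna
    grp = np.array([0] * n + [1] * n)
    base = rng.normal(8.0, 1.5, size=spec.n_mirna)
    lfc_vec = np.array([mirna_lfc.get(m, 0.0) for m in mirna_ids])
    expr = (
        base[:, None]
        + lfc_vec[:, None] * grp[None, :]
        + rng.normal(0.0, spec.mirna_noise_sd, size=(spec.n_mirna, 2 * n))
    )
    cols = [f"HC{i+1:02d}" for i in range(n)] + [f"PsO{i+1:02d}" for i in range(n)]
    mirna_expr = pd.DataFrame(expr, index=mirna_ids, columns=cols)
    mirna_group = pd.Series(np.where(grp == 0, "HC", "PsO"), index=cols, name="group")

    truth = SyntheticTruth(
        seed=seed,
        planted_de_features=planted_gene_de
        + [(m, f) for m, f in mirna_lfc.items() if f != 0.0],
        planted_edges=planted_edges + decoy_records,
    )
    return dict(
        mirna_expr=mirna_expr,
        mirna_group=mirna_group,
        mrna=mrna,
        edges=pd.DataFrame(edge_rows),
        modules=modules,
        truth=truth,
    )
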