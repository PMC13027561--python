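"""Probe QC, beta/M conversion, DMP fitting and kernel-smoothed DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from triplehit import methylome, synthdata


class TestFilterProbes:
    def test_single_failing_sample_removes_probe(self, methylation_planted):
        data, _ = methylation_planted
        data = data.subset_probes(data.beta.index[:10])
        detp = data.detection_p.copy()
        detp.iloc[0, 3] = 0.02
        bad = methylome.MethylationData(data.beta, detp, data.probes, data.samples)
        filt, counts = methylome.filter_probes(bad)
        assert data.beta.index[0] not in filt.beta.index
        assert counts["detection"] >= 1

    def test_sex_chromosome_probe_removed_despite_perfect_detection(self, methylation_planted):
        data, _ = methylation_planted
        filt, counts = methylome.filter_probes(data)
        assert not filt.probes["sex_chrom"].any()
        assert counts["sex_chrom"] == int(data.probes["sex_chrom"].sum())

    def test_clean_autosomal_probe_retained(self, methylation_planted):
        data, _ = methylation_planted
        filt, _ = methylome.filter_probes(data)
        clean = (
            ~data.probes["sex_chrom"]
            & ~data.probes["snp_overlap"]
            & ~data.probes["cross_reactive"]
            & (data.detection_p <= 0.01).all(axis=1)
        )
        assert set(data.beta.index[clean]) == set(filt.beta.index)

    def test_all_removed_names_dominating_rule(self, methylation_planted):
        data, _ = methylation_planted
        sub = data.subset_probes(data.beta.index[:5])
        detp = sub.detection_p.copy()
        detp.iloc[:, 0] = 0.5
        bad = methylome.MethylationData(sub.beta, detp, sub.probes, sub.samples)
        with pytest.raises(ValueError, match="detection"):
            methylome.filter_probes(bad)


class TestBetaM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert methylome.beta_to_m(np.array([beta]))[0] == pytest.approx(m)

    def test_roundtrip_identity_inside_clip_range(self):
        b = np.linspace(0.01, 0.99, 50)
        assert methylome.m_to_beta(methylome.beta_to_m(b)) == pytest.approx(b)

    def test_antisymmetry(self):
        b = np.array([0.1, 0.3, 0.45])
        assert methylome.beta_to_m(b) == pytest.approx(-methylome.beta_to_m(1 - b))

    def test_epsilon_validation(self):
        with pytest.raises(ValueError):
            methylome.beta_to_m(np.array([0.5]), epsilon=0.7)


class TestFitDmps:
    def test_matches_pooled_two_sample_t_without_covariates(self, methylation_planted):
        data, _ = methylation_planted
        sub = data.subset_probes(data.beta.index[:30])
        dmps = methylome.fit_dmps(sub, covariates=())
        m = methylome.beta_to_m(sub.beta)
        case = sub.samples["group"] == "PsO"
        for cpg in sub.beta.index[:10]:
            t, p = sps.ttest_ind(m.loc[cpg, case], m.loc[cpg, ~case], equal_var=True)
            assert dmps.loc[cpg, "t_statistic"] == pytest.approx(t)
            assert dmps.loc[cpg, "p_value"] == pytest.approx(p)

    def test_delta_beta_on_beta_scale(self, methylation_planted):
        data, truth = methylation_planted
        dmps = methylome.fit_dmps(data)
        chrom, start, end, delta = truth.planted_dmrs[0]
        in_region = (
            (data.probes["chrom"] == chrom)
            & (data.probes["pos"] >= start)
            & (data.probes["pos"] < end)
        )
        assert dmps.loc[in_region, "delta_beta"].mean() == pytest.approx(delta, abs=0.05)

    def test_covariate_adjustment_attenuates_confounded_signal(self):
        spec = synthdata.CovariateSpec(confounded=True, age_effect=0.03, age_effect_fraction=1.0)
        data, _ = synthdata.gen_methylation(n_cpg=200, covariates=spec, seed=21)
        unadj = methylome.fit_dmps(data, covariates=())
        adj = methylome.fit_dmps(data, covariates=("age",))
        # age drives methylation and is tied to group: adjusting weakens the
        # spurious group signal on average
        assert np.nanmedian(np.abs(adj["t_statistic"])) < np.nanmedian(
            np.abs(unadj["t_statistic"])
        )


class TestCallDmrs:
    def test_planted_region_recovered(self, methylation_planted):
        data, truth = methylation_planted
        filt, _ = methylome.filter_probes(data)
        dmps = methylome.fit_dmps(filt)
        dmrs = methylome.call_dmrs(dmps, filt.probes)
        chrom, start, end, delta = truth.planted_dmrs[0]
        overlapping = [
            d for d in dmrs if d.chrom == chrom and d.start < end and d.end > start
        ]
        assert overlapping
        assert overlapping[0].direction == "increase"
        assert overlapping[0].n_cpgs >= 2

    def test_distant_significant_cpgs_never_merge(self):
        # two isolated strong CpGs separated by far more than lambda
        probes = pd.DataFrame(
            dict(chrom=["chr1"] * 4, pos=[1000, 1300, 50_000, 50_300],
                 sex_chrom=False, snp_overlap=False, cross_reactive=False,
                 promoter_category="other", genes=""),
            index=[f"cg{i}" for i in range(4)],
        )
        dmps = pd.DataFrame(
            dict(t_statistic=[8.0, 8.0, 8.0, 8.0], p_value=[1e-10] * 4,
                 q_value=[1e-9] * 4, delta_beta=[0.1] * 4, df=[20.0] * 4),
            index=probes.index,
        )
        dmrs = methylome.call_dmrs(dmps, probes)
        assert len(dmrs) == 2
        assert all(d.n_cpgs == 2 for d in dmrs)

    def test_translation_and_relabel_invariance(self, methylation_planted):
        data, _ = methylation_planted
        filt, _ = methylome.filter_probes(data)
        dmps = methylome.fit_dmps(filt)
        base = methylome.call_dmrs(dmps, filt.probes)
        shifted = filt.probes.copy()
        shifted["pos"] = shifted["pos"] + 10_000
        shifted["chrom"] = shifted["chrom"].map({"chr1": "chrA", "chr2": "chrB"})
        moved = methylome.call_dmrs(dmps, shifted)
        assert len(base) == len(moved)
        for a, b in zip(base, moved):
            assert b.start == a.start + 10_000 and b.end == a.end + 10_000
            assert b.stouffer_fdr == pytest.approx(a.stouffer_fdr)

    def test_unsorted_positions_rejected(self):
        probes = pd.DataFrame(
            dict(chrom=["chr1", "chr1"], pos=[500, 100], sex_chrom=False,
                 snp_overlap=False, cross_reactive=False,
                 promoter_category="other", genes=""),
            index=["a", "b"],
        )
        dmps = pd.DataFrame(
            dict(t_statistic=[1.0, 1.0], p_value=[0.5, 0.5], q_value=[0.5, 0.5],
                 delta_beta=[0.0, 0.0], df=[10.0, 10.0]),
            index=probes.index,
        )
        with pytest.raises(ValueError, match="unsorted"):
            methylome.call_dmrs(dmps, probes)

    def test_vanishing_bandwidth_degenerates_to_per_cpg_p(self):
        rng = np.random.default_rng(31)
        t = rng.normal(size=200)
        pos = np.cumsum(rng.integers(200, 500, 200)).astype(float)
        _, p = methylome._smooth_chromosome(pos, t**2, sd=1e-6)
        expected = 2 * sps.norm.sf(np.abs(t))
        assert p == pytest.approx(expected, rel=1e-4)

    def test_cd8_style_effect_floor_filters_small_regions(self, methylation_planted):
        data, _ = methylation_planted
        filt, _ = methylome.filter_probes(data)
        dmps = methylome.fit_dmps(filt)
        relaxed = methylome.call_dmrs(
            dmps, filt.probes, methylome.DmrParams(fdr_threshold=0.10, min_delta_beta=0.0)
        )
        floored = methylome.call_dmrs(dmps, filt.probes, methylome.CD8_PARAMS)
        assert {(d.chrom, d.start) for d in floored} <= {(d.chrom, d.start) for d in relaxed}
        assert all(abs(d.region_delta_beta) >= 0.02 for d in floored)


class TestSummaries:
    def test_printed_count_percentages(self):
        s = methylome.direction_summary_from_counts(26_572, 18_824)
        assert (s["pct_increase"], s["pct_decrease"]) == (58.5, 41.5)
        s2 = methylome.direction_summary_from_counts(52, 123)
        assert (s2["pct_decrease"], s2["pct_increase"]) == (70.3, 29.7)

    def test_single_dmr_is_hundred_percent(self):
        rec = methylome.DmrRecord("chr1", 0, 100, 3, 0.01, 0.01, 0.05, "increase")
        s = methylome.summarize_direction([rec])
        assert s["pct_increase"] == 100.0 and s["n_decrease"] == 0

    def test_empty_list_gives_zero_counts(self):
        s = methylome.summarize_direction([])
        assert s["total"] == 0 and s["n_increase"] == 0

    def test_delta_beta_median_and_iqr_reported(self):
        recs = [
            methylome.DmrRecord("chr1", i, i + 10, 2, 0.01, 0.01, d, "increase")
            for i, d in enumerate([0.01, 0.02, 0.03])
        ]
        s = methylome.summarize_direction(recs)
        assert s["increase_median_delta_beta"] == pytest.approx(0.02)


class TestRegionMedianBeta:
    def test_single_cpg_region_equals_that_row(self, methylation_planted):
        data, _ = methylation_planted
        cpg = data.beta.index[0]
        region = methylome.DmrRecord(
            data.probes.loc[cpg, "chrom"],
            int(data.probes.loc[cpg, "pos"]),
            int(data.probes.loc[cpg, "pos"]) + 1,
            1, 0.01, 0.01, 0.0, "increase",
        )
        medians, _ = methylome.region_median_beta(data, region)
        assert np.allclose(medians.to_numpy(), data.beta.loc[cpg].to_numpy())

    def test_constant_region_p_one(self, methylation_planted):
        data, _ = methylation_planted
        const = data.beta.copy()
        const.iloc[:5] = 0.4
        flat = methylome.MethylationData(
            const, data.detection_p, data.probes, data.samples
        )
        cpgs = data.beta.index[:5]
        region = methylome.DmrRecord(
            data.probes.loc[cpgs[0], "chrom"],
            int(data.probes.loc[cpgs, "pos"].min()),
            int(data.probes.loc[cpgs, "pos"].max()) + 1,
            5, 0.01, 0.01, 0.0, "increase",
        )
        _, p = methylome.region_median_beta(flat, region)
        assert p == 1.0

    def test_group_p_matches_exact_enumeration_9v10(self, methylation_planted, mwu_oracle):
        data, truth = methylation_planted
        # drop one reference sample to get the 9 vs 10 design
        cols = [c for c in data.beta.columns if c != "HC10"]
        trimmed = methylome.MethylationData(
            data.beta[cols], data.detection_p[cols], data.probes,
            data.samples.loc[cols],
        )
        chrom, start, end, _ = truth.planted_dmrs[0]
        region = methylome.DmrRecord(chrom, start, end, 10, 0.01, 0.01, 0.1, "increase")
        medians, p = methylome.region_median_beta(trimmed, region)
        case = medians[trimmed.samples["group"] == "PsO"].to_numpy()
        ref = medians[trimmed.samples["group"] == "HC"].to_numpy()
        assert p == pytest.approx(mwu_oracle(case, ref), abs=1e-9)

    def test_region_without_cpgs_rejected(self, methylation_planted):
        data, _ = methylation_planted
        region = methylome.DmrRecord("chr9", 0, 10, 0, 1.0, 1.0, 0.0, "increase")
        with pytest.raises(ValueError, match="no retained"):
            methylome.region_median_beta(data, region)
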