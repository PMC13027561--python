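"""Evidence tiering, directionality constraint and module assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triplehit import bridge


def edge_frame(rows):
    return pd.DataFrame(
        rows, columns=["mirna_id", "gene_symbol", "validated_sources", "prediction_sources"]
    )


def de_frame(entries, driver_col):
    df = pd.DataFrame(entries).set_index("id")
    df[driver_col] = df["flag"]
    return df


class TestTierRules:
    def test_full_truth_table_over_source_combinations(self):
        validated_opts = ["", "miRTarBase", "TarBase", "miRTarBase;TarBase"]
        pred_opts = ["", "TargetScan", "TargetScan;miRDB", "TargetScan;DIANA;miRDB"]
        rows, expected = [], []
        for i, (v, p) in enumerate(itertools.product(validated_opts, pred_opts)):
            if not v and not p:
                continue
            rows.append((f"m{i}", f"g{i}", v, p))
            n_pred = 0 if not p else len(p.split(";"))
            expected.append(2 if v else (1 if n_pred >= 2 else 0))
        tiered = bridge.tier_edges(edge_frame(rows), drop_tier0=False)
        assert list(tiered["tier"]) == expected
        retained = bridge.tier_edges(edge_frame(rows))
        assert (retained["tier"] >= 1).all()
        assert len(retained) == sum(1 for e in expected if e >= 1)

    def test_validated_single_source_is_tier2(self):
        t = bridge.tier_edges(edge_frame([("m", "g", "miRTarBase", "")]))
        assert t["tier"].iloc[0] == 2

    def test_two_predictions_no_validation_is_tier1(self):
        t = bridge.tier_edges(edge_frame([("m", "g", "", "TargetScan;miRDB")]))
        assert t["tier"].iloc[0] == 1

    def test_single_prediction_excluded(self):
        t = bridge.tier_edges(edge_frame([("m", "g", "", "TargetScan")]))
        assert t.empty

    def test_unknown_resource_name_rejected_with_vocabulary(self):
        with pytest.raises(ValueError, match="TargetScan"):
            bridge.tier_edges(edge_frame([("m", "g", "", "FooBase;TargetScan")]))

    def test_unsupported_edge_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            bridge.tier_edges(edge_frame([("m", "g", "", "")]))


def _de_tables():
    mirna_de = pd.DataFrame(
        dict(log2fc=[2.0, -2.0, 2.0, 0.5], is_bridge_driver=[True, True, True, False]),
        index=["miR-up", "miR-down", "miR-up2", "miR-weak"],
    )
    mrna_de = pd.DataFrame(
        dict(log2fc=[-1.5, 1.5, 1.5, 0.2], is_deg=[True, True, True, False]),
        index=["GDOWN", "GUP", "GUP2", "GFLAT"],
    )
    return mirna_de, mrna_de


class TestDirectionality:
    def test_inverse_pairs_retained_same_direction_dropped(self):
        mirna_de, mrna_de = _de_tables()
        edges = edge_frame(
            [
                ("miR-up", "GDOWN", "miRTarBase", ""),   # up vs down: keep
                ("miR-up", "GUP", "miRTarBase", ""),     # same direction: drop
                ("miR-down", "GUP", "", "TargetScan;miRDB"),  # down vs up: keep
                ("miR-weak", "GDOWN", "miRTarBase", ""),  # not a driver: drop
                ("miR-up2", "GFLAT", "miRTarBase", ""),  # target not DEG: drop
                ("miR-up", "ABSENT", "miRTarBase", ""),  # unmapped target: drop
            ]
        )
        tiered = bridge.tier_edges(edges)
        kept, drops = bridge.constrain_directionality(tiered, mirna_de, mrna_de)
        assert set(zip(kept["mirna_id"], kept["gene_symbol"])) == {
            ("miR-up", "GDOWN"),
            ("miR-down", "GUP"),
        }
        assert kept["inverse"].all()
        assert drops == dict(
            mirna_absent=0, gene_absent=1, mirna_not_driver=1, gene_not_deg=1,
            same_direction=1,
        )

    def test_id_mapping_applied_before_matching(self):
        mirna_de, mrna_de = _de_tables()
        ens = mrna_de.rename(index={"GDOWN": "ENSG0001"})
        id_map = pd.DataFrame(dict(gene_id=["ENSG0001"], gene_symbol=["GDOWN"]))
        edges = bridge.tier_edges(edge_frame([("miR-up", "GDOWN", "miRTarBase", "")]))
        kept, _ = bridge.constrain_directionality(edges, mirna_de, ens, id_map)
        assert len(kept) == 1

    def test_filter_order_invariance(self, regulome):
        from triplehit import mirna as mirna_mod, transcriptome as tr

        mm = mirna_mod.qc_filter_impute(regulome["mirna_expr"], regulome["mirna_group"])
        mde = mirna_mod.de_mirnas(mm)
        _, lc = tr.tmm_normalize(regulome["mrna"])
        gde = tr.de_genes(lc, regulome["mrna"].group, regulome["mrna"].levels)
        edges = regulome["edges"]
        a, _ = bridge.constrain_directionality(bridge.tier_edges(edges), mde, gde)
        b_all, _ = bridge.constrain_directionality(
            bridge.tier_edges(edges, drop_tier0=False), mde, gde
        )
        b = b_all[b_all["tier"] >= 1]
        assert set(zip(a["mirna_id"], a["gene_symbol"])) == set(
            zip(b["mirna_id"], b["gene_symbol"])
        )

    def test_random_directions_retain_half_of_eligible_edges(self):
        # Monte-Carlo oracle: with independent random up/down on both layers,
        # the inverse-direction constraint keeps ~50% of direction-eligible edges
        rng = np.random.default_rng(3)
        n = 10_000
        mirnas = [f"m{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(n)]
        mirna_de = pd.DataFrame(
            dict(log2fc=rng.choice([-2.0, 2.0], n), is_bridge_driver=True), index=mirnas
        )
        mrna_de = pd.DataFrame(
            dict(log2fc=rng.choice([-2.0, 2.0], n), is_deg=True), index=genes
        )
        edges = edge_frame([(m, g, "miRTarBase", "") for m, g in zip(mirnas, genes)])
        kept, _ = bridge.constrain_directionality(bridge.tier_edges(edges), mirna_de, mrna_de)
        assert len(kept) / n == pytest.approx(0.5, abs=0.02)

    def test_removing_constraint_only_enlarges_edge_set(self):
        mirna_de, mrna_de = _de_tables()
        edges = bridge.tier_edges(
            edge_frame(
                [("miR-up", "GDOWN", "miRTarBase", ""), ("miR-up", "GUP", "miRTarBase", "")]
            )
        )
        kept, _ = bridge.constrain_directionality(edges, mirna_de, mrna_de)
        assert len(kept) <= len(edges)


class TestModules:
    MODS = dict(
        AMP_core=["DEFB4A", "S100A7"],
        barrier_lipid=["FLG", "DEFB4A"],  # overlap resolved by priority
        keratinocyte_diff=["KRT16"],
        aux_lipid=["SCD"],
    )

    def edges(self):
        return pd.DataFrame(
            dict(
                mirna_id=["m1", "m2", "m3"],
                gene_symbol=["DEFB4A", "FLG", "NOMOD"],
                gene_direction=["up", "down", "up"],
                mirna_direction=["down", "up", "down"],
                inverse=[True, True, True],
            )
        )

    def test_lookup_and_priority(self):
        labeled = bridge.assign_modules(self.edges(), self.MODS)
        by_gene = labeled.set_index("gene_symbol")["module"]
        assert by_gene["DEFB4A"] == "AMP_core"  # AMP wins the overlap
        assert by_gene["FLG"] == "barrier_lipid"
        assert by_gene["NOMOD"] == "none"

    def test_sankey_counts_conserve_labeled_edges(self):
        labeled = bridge.assign_modules(self.edges(), self.MODS)
        counts = bridge.sankey_counts(labeled)
        assert counts["n_edges"].sum() == (labeled["module"] != "none").sum()

    def test_empty_module_file_warns_and_labels_none(self):
        with pytest.warns(UserWarning, match="empty"):
            labeled = bridge.assign_modules(self.edges(), {})
        assert (labeled["module"] == "none").all()


class TestEndToEndRecovery:
    def test_planted_inverse_edges_recovered_and_decoys_rejected(self, regulome):
        from triplehit import mirna as mirna_mod, transcriptome as tr

        mm = mirna_mod.qc_filter_impute(regulome["mirna_expr"], regulome["mirna_group"])
        mde = mirna_mod.de_mirnas(mm)
        _, lc = tr.tmm_normalize(regulome["mrna"])
        gde = tr.de_genes(lc, regulome["mrna"].group, regulome["mrna"].levels)
        kept, _ = bridge.constrain_directionality(
            bridge.tier_edges(regulome["edges"]), mde, gde
        )
        got = set(zip(kept["mirna_id"], kept["gene_symbol"]))
        planted = {
            (m, g) for m, g, t, inv, mod in regulome["truth"].planted_edges if inv
        }
        decoys = {
            (m, g) for m, g, t, inv, mod in regulome["truth"].planted_edges if not inv
        }
        assert planted <= got
        assert not (decoys & got)
        labeled = bridge.assign_modules(kept, regulome["modules"])
        planted_modules = {
            (m, g): mod for m, g, t, inv, mod in regulome["truth"].planted_edges if inv
        }
        for (m, g), mod in planted_modules.items():
            assert labeled.set_index(["mirna_id", "gene_symbol"]).loc[(m, g), "module"] == mod
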