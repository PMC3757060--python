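"""TF target mapping, FFL pair tests, record materialization, coexpression."""

import numpy as np
import pandas as pd
import pytest

from conftest import hypergeom_tail_by_enumeration
from fflnet.datatypes import ExpressionMatrix, PPINetwork
from fflnet.enrichment import TargetMap
from fflnet.motifs import (TFTargetMap, coexpression_eval, ffl3_test,
                           ffl4_test, map_tf_targets, neighbor_network,
                           significant_pairs, summarize_pairs,
                           validate_records)


def _expr(features, high_vals, low_vals):
    vals = pd.DataFrame(
        [[h] * 2 + [l] * 2 for h, l in zip(high_vals, low_vals)],
        index=features, columns=["h1", "h2", "l1", "l2"])
    groups = pd.Series(["high", "high", "low", "low"], index=vals.columns)
    return ExpressionMatrix(vals, groups)


# ---------------------------------------------------------------------------
# promoter mapping

class TestMapTFTargets:
    tss = pd.DataFrame({"feature": ["g1", "m1"], "kind": ["gene", "mirna"],
                        "chrom": ["chr1", "chr1"], "tss": [2000, 50000],
                        "strand": ["+", "-"]})

    def _run(self, tfbs_rows, expr=None):
        tfbs = pd.DataFrame(tfbs_rows, columns=["tf", "chrom", "start", "end"])
        expr = expr or _expr(["TF1"], [9.0], [9.0])
        return map_tf_targets(tfbs, self.tss, expr, w=2000, tf_expr_min=8.0)

    def test_site_fully_inside_promoter_is_a_hit(self):
        tm = self._run([("TF1", "chr1", 100, 110)])
        assert tm.gene_targets["TF1"] == {"g1"}

    def test_partially_overlapping_site_is_not_a_hit(self):
        tm = self._run([("TF1", "chr1", 3995, 4005)])
        assert tm.gene_targets["TF1"] == set()

    def test_boundary_site_touching_the_promoter_end_is_a_hit(self):
        tm = self._run([("TF1", "chr1", 3990, 4000)])
        assert tm.gene_targets["TF1"] == {"g1"}

    def test_mirna_promoters_are_mapped_separately(self):
        tm = self._run([("TF1", "chr1", 49000, 49010)])
        assert tm.mirna_targets["TF1"] == {"m1"}
        assert tm.gene_targets["TF1"] == set()

    def test_tf_expressed_in_one_group_is_retained(self):
        expr = _expr(["TF1"], [7.9], [8.0])
        tm = self._run([("TF1", "chr1", 100, 110)], expr=expr)
        assert "TF1" in tm.expressed_tfs

    def test_tf_below_threshold_everywhere_is_dropped(self):
        expr = _expr(["TF1"], [7.9], [7.5])
        tm = self._run([("TF1", "chr1", 100, 110)], expr=expr)
        assert tm.expressed_tfs == set()

    def test_tf_absent_from_expression_matrix_is_dropped(self):
        expr = _expr(["OTHER"], [9.0], [9.0])
        tm = self._run([("TF1", "chr1", 100, 110)], expr=expr)
        assert tm.expressed_tfs == set()

    def test_invalid_halfwidth_rejected(self):
        empty = pd.DataFrame(columns=["tf", "chrom", "start", "end"])
        with pytest.raises(ValueError, match="halfwidth"):
            map_tf_targets(empty, self.tss, _expr(["TF1"], [9], [9]), w=0)


# ---------------------------------------------------------------------------
# pair tests against the enumeration oracle

def test_ffl3_test_matches_enumeration_oracle():
    # predicted = 10 genes, 4 carry the TFBS, 5 functional, 3 of them bound
    predicted = {f"g{i}" for i in range(10)}
    functional = {"g0", "g1", "g2", "g8", "g9"}
    bound = {"g0", "g1", "g2", "g3"}
    tmap = TargetMap({"m": predicted}, {"m": functional})
    tf_map = TFTargetMap({"tf": bound}, {"tf": set()}, {"tf"})
    p = ffl3_test("m", "tf", tmap, tf_map)
    assert p == pytest.approx(hypergeom_tail_by_enumeration(10, 4, 5, 3))
    assert p == pytest.approx(66 / 252)


def test_ffl3_no_bound_predicted_targets_gives_p_one():
    tmap = TargetMap({"m": {"a", "b"}}, {"m": {"a"}})
    tf_map = TFTargetMap({"tf": {"zzz"}}, {"tf": set()}, {"tf"})
    assert ffl3_test("m", "tf", tmap, tf_map) == 1.0


def test_ffl4_test_matches_enumeration_oracle():
    neighbors = {"m": {f"n{i}" for i in range(12)}}
    bound = {f"n{i}" for i in range(5)}
    de = {f"n{i}" for i in range(3, 9)}     # 6 DE neighbors, 2 of them bound
    tf_map = TFTargetMap({"tf": bound}, {"tf": set()}, {"tf"})
    p = ffl4_test("m", "tf", neighbors, tf_map, de)
    assert p == pytest.approx(hypergeom_tail_by_enumeration(12, 5, 6, 2))


def test_ffl4_forced_outcome_and_degenerate_cases():
    tf_map = TFTargetMap({"tf": {"a", "b", "c"}}, {"tf": set()}, {"tf"})
    # TF binds every neighbor: k = n is certain, p = 1
    assert ffl4_test("m", "tf", {"m": {"a", "b", "c"}}, tf_map,
                     {"a", "b"}) == 1.0
    assert ffl4_test("m", "tf", {"m": set()}, tf_map, set()) == 1.0
    assert ffl4_test("m", "other", {"m": {"a"}},
                     TFTargetMap({}, {}, {"other"}), {"a"}) == 1.0


# ---------------------------------------------------------------------------
# neighbor network

def test_neighbors_include_targets_and_their_partners():
    tmap = TargetMap({"m": {"A"}}, {"m": {"A"}})
    ppi = PPINetwork.from_pairs([("A", "B"), ("A", "C"), ("D", "E")])
    nb = neighbor_network(tmap, ppi)
    assert nb["m"] == {"A", "B", "C"}


def test_target_absent_from_ppi_contributes_nothing_beyond_itself():
    tmap = TargetMap({"m": {"X"}}, {"m": {"X"}})
    ppi = PPINetwork.from_pairs([("A", "B")])
    assert neighbor_network(tmap, ppi)["m"] == {"X"}


def test_cluster_restriction_limits_the_seed_targets():
    tmap = TargetMap({"m": {"A", "B"}}, {"m": {"A", "B"}})
    ppi = PPINetwork.from_pairs([("A", "C"), ("B", "D")])
    nb = neighbor_network(tmap, ppi, cluster_genes={"A"})
    assert nb["m"] == {"A", "C"}


# ---------------------------------------------------------------------------
# family-wise testing and records

def _toy_study():
    """One miRNA, two TFs; TF 'tf_hit' binds all functional targets."""
    predicted = {f"g{i}" for i in range(12)}
    functional = {"g0", "g1", "g2", "g3"}
    tmap = TargetMap({"m": predicted}, {"m": functional})
    tf_map = TFTargetMap({"tf_hit": functional, "tf_miss": {"g11"}},
                         {"tf_hit": {"m"}, "tf_miss": set()},
                         {"tf_hit", "tf_miss"})
    ppi = PPINetwork.from_pairs([("g0", "s0"), ("g1", "s1")])
    de = functional | {"s0", "s1"}
    clusters = {"C1": functional}
    return tmap, tf_map, ppi, de, clusters


def test_significant_pairs_materializes_valid_ffl3_records():
    tmap, tf_map, ppi, de, clusters = _toy_study()
    records, pairs = significant_pairs(tmap, tf_map, ppi, de, clusters,
                                       fdr_max=0.2)
    f3 = records[records.motif_type == "ffl3"]
    assert set(f3["tf"]) == {"tf_hit"}
    assert set(f3["primary_target"]) == {"g0", "g1", "g2", "g3"}
    validate_records(records, tmap, tf_map, ppi, de)


def test_all_p_one_yields_no_records():
    tmap = TargetMap({"m": {"a", "b"}}, {"m": set()})
    tf_map = TFTargetMap({"tf": {"a"}}, {"tf": set()}, {"tf"})
    ppi = PPINetwork.from_pairs([])
    records, pairs = significant_pairs(tmap, tf_map, ppi, set(),
                                       {"C1": set()}, fdr_max=0.2)
    assert records.empty
    assert (pairs["p"] == 1.0).all()


def test_bh_families_are_independent_per_cluster_and_motif():
    """FDRs inside one family equal a standalone BH on that family alone."""
    from fflnet.diffexpr import bh_fdr
    tmap, tf_map, ppi, de, _ = _toy_study()
    clusters = {"C1": {"g0", "g1"}, "C2": {"g2", "g3"}}
    _, pairs = significant_pairs(tmap, tf_map, ppi, de, clusters, fdr_max=0.2)
    for (c, mt), fam in pairs.groupby(["cluster", "motif_type"]):
        np.testing.assert_allclose(fam["fdr"], bh_fdr(fam["p"].to_numpy()))


def test_summary_table_has_the_expected_columns():
    tmap, tf_map, ppi, de, clusters = _toy_study()
    records, _ = significant_pairs(tmap, tf_map, ppi, de, clusters, 0.2)
    summary = summarize_pairs(records)
    assert {"cluster", "motif", "n_mirnas", "n_tfs", "n_primary_targets",
            "n_secondary_targets", "n_pairs"} <= set(summary.columns)
    assert "total" in set(summary["motif"])


def test_validate_records_catches_corrupted_rows():
    tmap, tf_map, ppi, de, clusters = _toy_study()
    records, _ = significant_pairs(tmap, tf_map, ppi, de, clusters, 0.2)
    bad = records.copy()
    bad.loc[bad.index[0], "primary_target"] = "not_a_target"
    with pytest.raises(AssertionError, match="functional"):
        validate_records(bad, tmap, tf_map, ppi, de)


def test_every_study_record_revalidates_against_raw_inputs(study_bundle,
                                                           study_result):
    bundle, _ = study_bundle
    from fflnet.motifs import map_tf_targets
    tf_map = map_tf_targets(bundle.tfbs, bundle.tss, bundle.mrna_expr,
                            w=2000, tf_expr_min=8.0)
    tmap = study_result.target_map.restrict(study_result.retained_mirnas)
    validate_records(study_result.records, tmap, tf_map, bundle.ppi,
                     study_result.de_genes.index)


# ---------------------------------------------------------------------------
# coexpression

def _records_for(genes, cluster="C1", motif="ffl3"):
    return pd.DataFrame({
        "cluster": cluster, "motif_type": motif, "mirna": "m", "tf": "tf",
        "primary_target": list(genes), "secondary_target": "",
        "p": 0.01, "fdr": 0.01,
    })


def _expr_from_matrix(x, features):
    cols = [f"s{i}" for i in range(x.shape[1])]
    groups = pd.Series(["high"] * (x.shape[1] // 2) +
                       ["low"] * (x.shape[1] - x.shape[1] // 2), index=cols)
    return ExpressionMatrix(pd.DataFrame(x, index=features, columns=cols), groups)


def test_identical_profiles_give_minimal_ks_p():
    rng = np.random.default_rng(0)
    base = rng.normal(size=7)
    x = np.vstack([base + rng.normal(0, 1e-6, size=7) for _ in range(6)] +
                  [rng.normal(size=7) for _ in range(40)])
    expr = _expr_from_matrix(x, [f"g{i}" for i in range(46)])
    res = coexpression_eval(_records_for([f"g{i}" for i in range(6)]),
                            expr, B=200, seed=0)
    assert res["p"].iloc[0] < 1e-6
    assert res["mean_obs"].iloc[0] > 0.99


def test_anticorrelated_profiles_are_not_called_coexpressed():
    """The one-sided test looks for a shift toward HIGH correlation only."""
    rng = np.random.default_rng(1)
    base = rng.normal(size=8)
    x = np.vstack([base, -base, base, -base] +
                  [rng.normal(size=8) for _ in range(40)])
    expr = _expr_from_matrix(x, [f"g{i}" for i in range(44)])
    res = coexpression_eval(_records_for(["g0", "g1", "g2", "g3"]),
                            expr, B=200, seed=0)
    assert res["p"].iloc[0] > 0.2


def test_random_observed_pairs_are_calibrated():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(60, 7))
    expr = _expr_from_matrix(x, [f"g{i}" for i in range(60)])
    ps = [coexpression_eval(_records_for(list(rng.choice(
        [f"g{i}" for i in range(60)], size=5, replace=False))),
        expr, B=100, seed=s)["p"].iloc[0] for s in range(20)]
    assert np.mean(ps) > 0.2       # no systematic rejection under the null


def test_zero_variance_genes_are_skipped():
    x = np.vstack([np.ones(6), np.random.default_rng(0).normal(size=(10, 6))])
    expr = _expr_from_matrix(x, [f"g{i}" for i in range(11)])
    res = coexpression_eval(_records_for(["g0", "g1", "g2"]), expr,
                            B=50, seed=0)
    # only the (g1, g2) pair survives
    assert res["n_pairs"].iloc[0] == 1
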