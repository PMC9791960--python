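"""Expression bins, DEG calling, set intersections, clustering, and qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyfam import expression_analysis as ea
from polyfam.synthetic_data import generate_expression_matrix


class TestBins:
    @pytest.mark.parametrize(
        "value,bin_",
        [
            (0.0, "none"),
            (0.5, "low"),
            (1.0, "low"),
            (1.01, "medium"),
            (10.0, "medium"),
            (10.5, "high"),
        ],
    )
    def test_boundary_semantics(self, value, bin_):
        assert ea.bin_expression(value) == bin_

    def test_census_counts_conserved(self):
        tpm, _ = generate_expression_matrix(2, n_genes=80)
        census = ea.census_bins(tpm)
        assert (census.sum(axis=0) == 80).all()

    def test_census_invariant_to_gene_permutation(self):
        tpm, _ = generate_expression_matrix(2, n_genes=40)
        shuffled = tpm.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(ea.census_bins(tpm), ea.census_bins(shuffled))

    def test_all_zero_sample_counts_none(self):
        tpm = pd.DataFrame({"s1": [0.0, 0.0, 0.0]}, index=["g1", "g2", "g3"])
        census = ea.census_bins(tpm)
        assert census.loc["none", "s1"] == 3


class TestLogTransform:
    @pytest.mark.parametrize("tpm,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_values(self, tpm, expected):
        df = pd.DataFrame({"s": [tpm]})
        assert ea.log2_tpm(df)["s"].iloc[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ea.log2_tpm(pd.DataFrame({"s": [-1.0]}))


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert ea.benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        adj = ea.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(ea.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_order_invariant(self, ps):
        adj = ea.benjamini_hochberg(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = ea.benjamini_hochberg([ps[i] for i in perm])
        assert np.allclose(adj_perm, adj[perm])


class TestDegCalling:
    def test_replicate_requirement(self):
        tpm, _ = generate_expression_matrix(1)
        with pytest.raises(ValueError):
            ea.call_degs(tpm, ["control_rep1"], ["treated_rep1", "treated_rep2"])

    def test_identical_groups_no_degs(self):
        tpm = pd.DataFrame(
            {
                "c1": [5.0, 1.0], "c2": [5.1, 1.1], "c3": [4.9, 0.9],
                "t1": [5.0, 1.0], "t2": [5.1, 1.1], "t3": [4.9, 0.9],
            },
            index=["g1", "g2"],
        )
        degs = ea.call_degs(tpm, ["c1", "c2", "c3"], ["t1", "t2", "t3"])
        assert not degs["is_deg"].any()

    def test_planted_strong_effects_recovered(self):
        tpm, truth = generate_expression_matrix(
            9, n_genes=150, de_fraction=0.1, lfc_magnitude=5.0, dispersion=0.1
        )
        degs = ea.call_degs(
            tpm,
            ["control_rep1", "control_rep2", "control_rep3"],
            ["treated_rep1", "treated_rep2", "treated_rep3"],
        )
        planted = truth.de_gene_ids["treated"]
        recovered = set(degs.index[degs["is_deg"]])
        assert len(recovered & planted) / len(planted) >= 0.9

    def test_null_false_discovery_proportion_controlled(self):
        """Average FDP over 100 null simulations stays at or below 0.05."""
        fdps = []
        for rep in range(100):
            tpm, _ = generate_expression_matrix(
                5000 + rep, n_genes=200, de_fraction=0.0
            )
            degs = ea.call_degs(
                tpm,
                ["control_rep1", "control_rep2", "control_rep3"],
                ["treated_rep1", "treated_rep2", "treated_rep3"],
            )
            n_called = int(degs["is_deg"].sum())
            fdps.append(0.0 if n_called == 0 else 1.0)
        assert np.mean(fdps) <= 0.05


class TestIntersections:
    def test_disjoint_sets(self):
        regions = ea.intersect_deg_sets({"A": {1, 2}, "B": {3}})
        assert regions[("A",)] == 2
        assert regions[("B",)] == 1
        assert regions[("A", "B")] == 0

    def test_hand_enumerated_overlap(self):
        regions = ea.intersect_deg_sets({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions == {("A",): 1, ("B",): 1, ("A", "B"): 1}

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(4)
        sets = {
            name: set(rng.choice(50, size=rng.integers(5, 30), replace=False))
            for name in "ABCD"
        }
        regions = ea.intersect_deg_sets(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        tpm = pd.DataFrame(
            {
                "s1": [1.0, 100.0, 1.0, 50.0],
                "s2": [2.0, 1.0, 2.0, 20.0],
                "s3": [3.0, 55.0, 3.0, 1.0],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        order = ea.cluster_order(tpm)
        assert abs(order.index("g1") - order.index("g3")) == 1

    def test_anticorrelated_blocks_contiguous(self):
        up = [1.0, 2.0, 4.0, 8.0]
        down = [8.0, 4.0, 2.0, 1.0]
        tpm = pd.DataFrame(
            dict(zip("abcd", [up, up, down, down])), columns=list("abcd")
        ).T
        tpm.columns = [f"s{i}" for i in range(4)]
        order = ea.cluster_order(tpm)
        half = set(order[:2])
        assert half in ({"a", "b"}, {"c", "d"})

    def test_permutation_invariant(self):
        tpm, _ = generate_expression_matrix(11, n_genes=30)
        shuffled = tpm.sample(frac=1.0, random_state=1)
        assert ea.cluster_order(tpm) == ea.cluster_order(shuffled)


class TestQpcr:
    def _table(self, ct_gene, ct_ref=20.0):
        rows = []
        for trt in ("control", "cold"):
            for rep in (1, 2, 3):
                rows.append(
                    {"gene": "actin", "treatment": trt, "timepoint": 6,
                     "replicate": rep, "ct": ct_ref}
                )
                rows.append(
                    {"gene": "g1", "treatment": trt, "timepoint": 6,
                     "replicate": rep, "ct": ct_gene[trt]}
                )
        return pd.DataFrame(rows)

    def test_equal_cts_fold_one(self):
        ct = self._table({"control": 25.0, "cold": 25.0})
        ddct, fold = ea.ddct_fold_change(ct, "g1", "cold", 6, "actin", "control")
        assert (ddct, fold) == (0.0, 1.0)

    @pytest.mark.parametrize("ddct,fold", [(-2.0, 4.0), (1.0, 0.5)])
    def test_fold_from_ddct(self, ddct, fold):
        ct = self._table({"control": 25.0, "cold": 25.0 + ddct})
        got_ddct, got_fold = ea.ddct_fold_change(ct, "g1", "cold", 6, "actin", "control")
        assert got_ddct == pytest.approx(ddct)
        assert got_fold == pytest.approx(fold)

    def test_missing_reference_rejected(self):
        ct = self._table({"control": 25.0, "cold": 23.0})
        ct = ct[ct["gene"] != "actin"]
        with pytest.raises(ValueError, match="reference"):
            ea.ddct_fold_change(ct, "g1", "cold", 6, "actin", "control")


class TestAnova:
    def test_textbook_example_definitional_sums_of_squares(self):
        groups = [[6.0, 8.0, 4.0], [5.0, 7.0, 9.0], [11.0, 13.0, 12.0]]
        flat = [x for g in groups for x in g]
        grand = np.mean(flat)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum((x - np.mean(g)) ** 2 for g in groups for x in g)
        df_b, df_w = 2, 6
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        f, p = ea.one_way_anova(groups)
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert 0 < p < 1

    def test_null_data_large_p(self):
        f, p = ea.one_way_anova([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]])
        assert p > 0.5

    def test_degenerate_flagged(self):
        f, p = ea.one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(f) and np.isnan(p)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n = 400
        for _ in range(n):
            groups = [list(rng.normal(0, 1, 5)) for _ in range(3)]
            _, p = ea.one_way_anova(groups)
            rejections += p < 0.05
        assert abs(rejections / n - 0.05) < 0.03

    @pytest.mark.parametrize(
        "p,stars", [(0.001, "**"), (0.03, "*"), (0.2, ""), (float("nan"), "")]
    )
    def test_stars(self, p, stars):
        assert ea.significance_stars(p) == stars
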