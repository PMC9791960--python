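"""Collinearity chaining (vs brute force), duplication typing, triad census."""

import itertools

import pytest

from polyfam import comparative_genomics as cg
from polyfam.formats_io import GeneFeature, packaged_domain_table


def _anchor(ra, rb, ca="1A", cb="1B", name=None):
    name = name or f"a{ra}_{rb}"
    return cg.AnchorPair(f"{name}_x", f"{name}_y", ca, cb, ra, rb)


def _feat(gene_id, chrom, start):
    return GeneFeature(gene_id, chrom, start, start + 100, "+")


class TestAnchors:
    def test_no_homologs_no_anchors(self):
        assert cg.build_anchors([], [], []) == []

    def test_self_pairs_excluded(self):
        feats = [_feat("g1", "1A", 100)]
        assert cg.build_anchors([("g1", "g1")], feats, feats) == []

    def test_ranks_over_full_gene_order(self):
        feats_a = [_feat("a1", "1A", 100), _feat("bg", "1A", 200), _feat("a2", "1A", 300)]
        feats_b = [_feat("b1", "1B", 50), _feat("b2", "1B", 500)]
        anchors = cg.build_anchors([("a2", "b2")], feats_a, feats_b)
        assert anchors == [cg.AnchorPair("a2", "b2", "1A", "1B", 2, 1)]


class TestChaining:
    def test_six_consecutive_anchors_one_block(self):
        anchors = [_anchor(i, i) for i in range(6)]
        blocks = cg.chain_collinear_blocks(anchors, min_anchors=5, max_gap=25)
        assert len(blocks) == 1
        assert blocks[0].score == 6
        assert blocks[0].orientation == "same"

    def test_below_min_anchors_no_block(self):
        anchors = [_anchor(i, i) for i in range(4)]
        assert cg.chain_collinear_blocks(anchors, min_anchors=5) == []

    def test_reversed_order_inverted_block(self):
        anchors = [_anchor(i, 10 - i) for i in range(6)]
        blocks = cg.chain_collinear_blocks(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_gap_constraint_splits_chains(self):
        anchors = [_anchor(i, i) for i in range(5)] + [
            _anchor(100 + i, 100 + i) for i in range(5)
        ]
        blocks = cg.chain_collinear_blocks(anchors, min_anchors=5, max_gap=25)
        assert sorted(b.score for b in blocks) == [5, 5]

    def test_matches_brute_force_on_small_instances(self):
        """Best extracted chain length equals the exhaustive-subset optimum."""
        import numpy as np

        rng = np.random.default_rng(12)
        for trial in range(8):
            n = int(rng.integers(5, 12))
            ranks_b = rng.permutation(30)[:n]
            anchors = [_anchor(i, int(ranks_b[i]), name=f"t{trial}_{i}") for i in range(n)]
            max_gap = 10

            def chain_ok(subset, inverted):
                s = sorted(subset, key=lambda a: a.rank_a)
                for x, y in zip(s, s[1:]):
                    da = y.rank_a - x.rank_a
                    db = (x.rank_b - y.rank_b) if inverted else (y.rank_b - x.rank_b)
                    if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                        return False
                return True

            best = 1
            for r in range(2, n + 1):
                for combo in itertools.combinations(anchors, r):
                    if chain_ok(combo, False) or chain_ok(combo, True):
                        best = max(best, r)
            blocks = cg.chain_collinear_blocks(anchors, min_anchors=1, max_gap=max_gap)
            assert blocks[0].score == best


class TestDuplicationTyping:
    def test_adjacent_homologs_tandem(self):
        pair = _anchor(3, 4, ca="1A", cb="1A")
        assert cg.classify_duplication(pair, [], tandem_window=5) == "tandem"

    def test_pair_inside_block_segmental(self):
        anchors = [_anchor(i, i) for i in range(6)]
        blocks = cg.chain_collinear_blocks(anchors, min_anchors=5)
        assert cg.classify_duplication(anchors[2], blocks) == "segmental"

    def test_isolated_pair_dispersed(self):
        pair = _anchor(3, 50, ca="1A", cb="3B")
        assert cg.classify_duplication(pair, []) == "dispersed"

    def test_tandem_takes_precedence(self):
        anchors = [_anchor(i, i + 1, ca="1A", cb="1A") for i in range(6)]
        blocks = cg.chain_collinear_blocks(anchors, min_anchors=5)
        assert cg.classify_duplication(anchors[0], blocks) == "tandem"


class TestHomoeologGrouping:
    def test_planted_triad_grouped(self):
        feats = {
            "a": _feat("a", "3A", 10),
            "b": _feat("b", "3B", 10),
            "d": _feat("d", "3D", 10),
        }
        groups = cg.group_homoeologs(
            ["a", "b", "d"], feats, [("a", "b"), ("b", "d")]
        )
        assert len(groups) == 1
        assert groups[0].counts == (1, 1, 1, 0)
        assert groups[0].category == "1:1:1"

    def test_singleton_is_orphan(self):
        feats = {"a": _feat("a", "3A", 10)}
        groups = cg.group_homoeologs(["a"], feats, [])
        assert groups[0].category == "orphan"

    def test_different_chromosome_numbers_not_grouped(self):
        feats = {"a": _feat("a", "3A", 10), "b": _feat("b", "5B", 10)}
        groups = cg.group_homoeologs(["a", "b"], feats, [("a", "b")])
        assert len(groups) == 2

    def test_truth_driven_census_matches_planted_mixture(self, genome):
        """Noise-free homology reproduces the planted ratio categories exactly."""
        feats = {f.gene_id: f for f in genome.features}
        truth = genome.truth
        by_group = {}
        for gene, grp in truth.group_assignments.items():
            by_group.setdefault(grp, []).append(gene)
        hits = [
            (a, b)
            for members in by_group.values()
            for a, b in itertools.combinations(sorted(members), 2)
        ]
        groups = cg.group_homoeologs(
            sorted(truth.family_gene_ids), feats, hits
        )
        recovered = {}
        for g in groups:
            planted_group = truth.group_assignments[g.members[0]]
            recovered[planted_group] = g.category
        # map generator labels onto census labels
        label_map = {
            "1:1:1": "1:1:1", "n:1:1": "n:1:1-type", "1:1:0": "loss-of-one",
            "other": "other", "orphan": "orphan",
        }
        for grp, planted in truth.group_ratio_category.items():
            assert recovered[grp] == label_map[planted]

    def test_every_gene_in_exactly_one_group(self, genome):
        feats = {f.gene_id: f for f in genome.features}
        ids = sorted(genome.truth.family_gene_ids)
        groups = cg.group_homoeologs(ids, feats, [])
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == ids


class TestClassifyRatio:
    @pytest.mark.parametrize(
        "counts,category",
        [
            ((1, 1, 1, 0), "1:1:1"),
            ((2, 1, 1, 0), "n:1:1-type"),
            ((1, 3, 1, 0), "n:1:1-type"),
            ((1, 1, 0, 0), "loss-of-one"),
            ((0, 1, 2, 0), "other"),
            ((1, 0, 0, 0), "orphan"),
            ((0, 0, 0, 1), "orphan"),
            ((1, 0, 2, 2), "other"),
            ((1, 1, 0, 1), "other"),
            ((2, 0, 0, 0), "uncategorized"),
        ],
    )
    def test_category_rules(self, counts, category):
        assert cg.classify_ratio(counts) == category

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cg.classify_ratio((-1, 1, 1, 0))


class TestTriadCensus:
    def test_packaged_table_reproduces_published_census(self):
        summary = cg.census_from_domain_table(packaged_domain_table())
        assert summary.total_genes == 244
        assert summary.percents["1:1:1"] == 84.8
        assert summary.percents["loss-of-one"] == 6.6
        assert summary.percents["n:1:1-type"] == 1.6
        assert summary.percents["other"] == 4.5
        assert summary.gene_counts["orphan"] == 4
        assert summary.group_counts["1:1:1"] == 69
        assert summary.gene_counts["1:1:1"] == 207
        assert summary.gene_counts["uncategorized"] == 2

    def test_all_triad_config_is_hundred_percent(self):
        groups = [
            cg.HomoeologGroup(i, (f"a{i}", f"b{i}", f"d{i}"), (1, 1, 1, 0))
            for i in range(5)
        ]
        summary = cg.summarize_triads(groups)
        assert summary.percents["1:1:1"] == 100.0

    def test_gene_counts_conserved(self):
        summary = cg.census_from_domain_table(packaged_domain_table())
        assert sum(summary.gene_counts.values()) == 244
        assert abs(sum(summary.percents.values()) - 100.0) <= 0.2
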