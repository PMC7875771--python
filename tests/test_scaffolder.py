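"""Hi-C scaffolding: seeding, assignment, merge/split, ordering, AGP."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_contact_matrix
from gigasm import fixtures, scaffolder
from gigasm.scaffolder import (Cluster, ScaffoldConfig, assign_contigs,
                               bottleneck_linkage, build_agp,
                               build_scaffold_fasta, evict_misfits,
                               merge_split, n50, order_orient, pair_linkage,
                               seed_clusters, write_agp)


def _three_chromosome_matrix(strong=200.0, weak=1.0):
    """Six contigs (2 per chromosome), 2 bins each, block-structured."""
    names = ["a1", "a2", "b1", "b2", "c1", "c2"]
    n = 12
    dense = np.full((n, n), weak)
    for blk in range(3):  # strong within-chromosome contacts
        s = blk * 4
        dense[s:s + 4, s:s + 4] = strong
    np.fill_diagonal(dense, 0.0)
    return make_contact_matrix({c: 2 for c in names}, dense)


class TestLinkage:
    def test_pair_linkage_normalizes_by_length_product(self):
        counts = np.array([[0.0, 12.0], [12.0, 0.0]])
        lens = np.array([3.0, 4.0])
        assert pair_linkage(counts, lens)[0, 1] == 1.0

    def test_bottleneck_is_min_edge_on_chain(self):
        # chain a-b-c with direct a-c linkage zero
        link = np.array([[0.0, 5.0, 0.0],
                         [5.0, 0.0, 2.0],
                         [0.0, 2.0, 0.0]])
        bn = bottleneck_linkage(link)
        assert bn[0, 2] == 2.0
        assert bn[0, 1] == 5.0
        assert np.allclose(bn, bn.T)

    def test_bottleneck_never_below_direct_linkage(self):
        rng = np.random.default_rng(0)
        link = rng.random((8, 8))
        link = (link + link.T) / 2
        np.fill_diagonal(link, 0.0)
        bn = bottleneck_linkage(link)
        off = ~np.eye(8, dtype=bool)
        assert (bn[off] >= link[off] - 1e-12).all()


class TestSeedClusters:
    def test_single_seed_is_longest_contig(self):
        dense = np.zeros((6, 6))
        m = make_contact_matrix({"short": 1, "long": 3, "mid": 2}, dense)
        (cl,) = seed_clusters(m, 1)
        assert cl.members == ["long"]

    def test_one_seed_per_chromosome(self):
        m = _three_chromosome_matrix()
        clusters = seed_clusters(m, 3)
        chroms = sorted(cl.members[0][0] for cl in clusters)
        assert chroms == ["a", "b", "c"]

    def test_zero_contact_pair_both_selected(self):
        dense = np.full((4, 4), 50.0)
        dense[0:2, 2:4] = 0.0
        dense[2:4, 0:2] = 0.0
        np.fill_diagonal(dense, 0.0)
        m = make_contact_matrix({"a": 2, "b": 2}, dense)
        clusters = seed_clusters(m, 2)
        assert sorted(cl.members[0] for cl in clusters) == ["a", "b"]

    def test_too_many_seeds_raises(self):
        m = make_contact_matrix({"a": 1}, np.zeros((1, 1)))
        with pytest.raises(ValueError):
            seed_clusters(m, 2)


class TestAssignContigs:
    def test_exclusive_linkage_joins_cluster(self):
        # "x" contacts only chromosome a
        names = {"a1": 2, "a2": 2, "b1": 2, "b2": 2, "x": 2}
        n = 10
        dense = np.zeros((n, n))
        dense[0:4, 0:4] = 100.0
        dense[4:8, 4:8] = 100.0
        dense[8:10, 0:4] = 50.0
        dense[0:4, 8:10] = 50.0
        np.fill_diagonal(dense, 0.0)
        m = make_contact_matrix(names, dense)
        clusters = [Cluster(0, ["a1"]), Cluster(1, ["b1"])]
        out, unassigned = assign_contigs(clusters, m, min_linkage=0.0)
        by_id = {c.cluster_id: set(c.members) for c in out}
        assert "x" in by_id[0]
        assert "a2" in by_id[0] and "b2" in by_id[1]
        assert unassigned == set()

    def test_ambiguous_contig_left_unassigned(self):
        # "x" links both chromosomes equally: fails the ratio test
        names = {"a1": 2, "b1": 2, "x": 2}
        dense = np.zeros((6, 6))
        dense[4:6, 0:2] = 10.0
        dense[0:2, 4:6] = 10.0
        dense[4:6, 2:4] = 10.0
        dense[2:4, 4:6] = 10.0
        m = make_contact_matrix(names, dense)
        clusters = [Cluster(0, ["a1"]), Cluster(1, ["b1"])]
        out, unassigned = assign_contigs(clusters, m, min_linkage=0.0)
        assert unassigned == {"x"}

    def test_below_min_linkage_left_unassigned(self):
        names = {"a1": 2, "b1": 2, "x": 2}
        dense = np.zeros((6, 6))
        dense[4:6, 0:2] = 1.0
        dense[0:2, 4:6] = 1.0
        m = make_contact_matrix(names, dense)
        clusters = [Cluster(0, ["a1"]), Cluster(1, ["b1"])]
        _, unassigned = assign_contigs(clusters, m, min_linkage=1e9)
        assert unassigned == {"x"}


class TestEvictMisfits:
    def test_contaminant_returned_to_pool(self):
        m = _three_chromosome_matrix()
        clusters = [Cluster(0, ["a1", "a2", "b1"]), Cluster(1, ["b2"])]
        out, evicted = evict_misfits(clusters, m)
        assert evicted == {"b1"}
        assert {tuple(sorted(c.members)) for c in out} \
            == {("a1", "a2"), ("b2",)}

    def test_clean_clusters_untouched(self):
        m = _three_chromosome_matrix()
        clusters = [Cluster(0, ["a1", "a2"]), Cluster(1, ["b1", "b2"])]
        out, evicted = evict_misfits(clusters, m)
        assert evicted == set()
        assert [c.members for c in out] == [["a1", "a2"], ["b1", "b2"]]


class TestMergeSplit:
    def test_same_chromosome_clusters_merge(self):
        m = _three_chromosome_matrix()
        clusters = [Cluster(0, ["a1"]), Cluster(1, ["a2", "b1", "b2"])]
        out = merge_split(clusters, m)
        parts = {tuple(sorted(c.members)) for c in out}
        assert ("a1", "a2") in parts
        assert ("b1", "b2") in parts

    def test_chimeric_cluster_splits(self):
        m = _three_chromosome_matrix(weak=0.0)
        clusters = [Cluster(0, ["a1", "a2", "c1", "c2"]),
                    Cluster(1, ["b1", "b2"])]
        out = merge_split(clusters, m)
        parts = {tuple(sorted(c.members)) for c in out}
        assert ("a1", "a2") in parts and ("c1", "c2") in parts

    def test_background_level_clusters_unchanged(self):
        m = _three_chromosome_matrix(strong=200.0, weak=1.0)
        clusters = [Cluster(0, ["a1", "a2"]), Cluster(1, ["b1", "b2"]),
                    Cluster(2, ["c1", "c2"])]
        out = merge_split(clusters, m)
        assert {tuple(sorted(c.members)) for c in out} \
            == {("a1", "a2"), ("b1", "b2"), ("c1", "c2")}


def _chain_matrix(n_contigs=5, bins_per=3, w=40.0):
    """Contigs forming a linear chain: tail(i) touches head(i+1)."""
    names = [f"c{i}" for i in range(n_contigs)]
    n = n_contigs * bins_per
    dense = np.zeros((n, n))
    for i in range(n_contigs - 1):
        tail = i * bins_per + bins_per - 1
        head = (i + 1) * bins_per
        dense[tail, head] = dense[head, tail] = w * (n_contigs - i)
    return names, make_contact_matrix({c: bins_per for c in names}, dense)


def _layout_score(layout, m, end_window=1):
    """Sum of facing-end weights over adjacent placements (oracle metric)."""
    dense = m.counts.toarray()

    def win(cid, side):
        lo, hi = m.contig_bin_range(cid)
        w = min(end_window, hi - lo)
        return list(range(lo, lo + w)) if side == "head" \
            else list(range(hi - w, hi))

    score = 0.0
    for (c1, o1, _), (c2, o2, _) in zip(layout.placements,
                                        layout.placements[1:]):
        exit_side = "tail" if o1 == "+" else "head"
        entry_side = "head" if o2 == "+" else "tail"
        b1, b2 = win(c1, exit_side), win(c2, entry_side)
        score += dense[np.ix_(b1, b2)].sum() / (len(b1) * len(b2))
    return score


class TestOrderOrient:
    def test_two_contigs_tail_to_head(self):
        names, m = _chain_matrix(2)
        layout = order_orient(Cluster(0, names), m, end_window=1)
        assert [(c, o) for c, o, _ in layout.placements] \
            == [("c0", "+"), ("c1", "+")]

    def test_chain_matches_exhaustive_signed_permutation_oracle(self):
        names, m = _chain_matrix(5)
        layout = order_orient(Cluster(0, names), m, end_window=1)
        best = 0.0
        for perm in itertools.permutations(names):
            for signs in itertools.product("+-", repeat=5):
                cand = scaffolder.ScaffoldLayout(
                    [(c, s, 100) for c, s in zip(perm, signs)])
                best = max(best, _layout_score(cand, m))
        assert _layout_score(layout, m) == pytest.approx(best)

    def test_chain_recovers_order_up_to_reversal(self):
        names, m = _chain_matrix(5)
        layout = order_orient(Cluster(0, names), m, end_window=1)
        order = layout.contig_order()
        assert order in (names, names[::-1])

    def test_canonical_direction_deterministic(self):
        names, m = _chain_matrix(3)
        layout = order_orient(Cluster(0, names), m, end_window=1)
        assert layout.contig_order()[0] <= layout.contig_order()[-1]

    def test_singleton_layout(self):
        m = make_contact_matrix({"only": 2}, np.zeros((2, 2)))
        layout = order_orient(Cluster(0, ["only"]), m)
        assert layout.placements == [("only", "+", 0)]


class TestN50:
    def test_definition_scan(self):
        assert n50([5, 4, 3, 2, 1]) == 4

    def test_single_piece(self):
        assert n50([7]) == 7

    def test_equal_pieces(self):
        assert n50([10, 10]) == 10

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            n50([])

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            n50([5, 0])


class TestAgpAndFasta:
    def test_agp_coordinates(self):
        layout = scaffolder.ScaffoldLayout(
            [("c1", "+", 100), ("c2", "-", 0)])
        agp = build_agp([layout], {"c1": 500, "c2": 300})
        rows = agp.to_records(index=False).tolist()
        assert rows[0] == ("scaffold001", 1, 500, 1, "W", "c1", 1, 500, "+")
        assert rows[1] == ("scaffold001", 501, 600, 2, "N", 100, "scaffold",
                           "yes", "proximity_ligation")
        assert rows[2] == ("scaffold001", 601, 900, 3, "W", "c2", 1, 300, "-")

    def test_write_agp_header(self, tmp_path):
        layout = scaffolder.ScaffoldLayout([("c1", "+", 0)])
        agp = build_agp([layout], {"c1": 10})
        write_agp(agp, tmp_path / "x.agp")
        lines = (tmp_path / "x.agp").read_text().splitlines()
        assert lines[0] == "##agp-version\t2.1"

    def test_fasta_gap_and_orientation(self):
        layout = scaffolder.ScaffoldLayout([("c1", "+", 10), ("c2", "-", 0)])
        fasta = build_scaffold_fasta([layout], {"c1": "AACC", "c2": "AAAG"},
                                     gap_size=10)
        assert fasta == {"scaffold001": "AACC" + "N" * 10 + "CTTT"}


class TestScaffoldDriver:
    def test_zero_pairs_all_singletons(self):
        contigs = {"a": "ACGT" * 100, "b": "GGCC" * 100}
        pairs = pd.DataFrame(columns=["readID", "chrom1", "pos1", "chrom2",
                                      "pos2", "strand1", "strand2"])
        agp, fasta, report = scaffolder.scaffold(pairs, contigs)
        assert report["n_scaffolds"] == 2
        w = agp[agp["component_type"] == "W"]
        assert sorted(w["component_id"]) == ["a", "b"]

    def test_every_contig_placed_exactly_once(self):
        cfg = fixtures.SimConfig(seed=5, chromosome_lengths=(300_000, 200_000),
                                 contig_break_count=8,
                                 min_segment_length=15_000,
                                 hic_pair_count=20_000)
        genome, truth = fixtures.simulate_genome(cfg)
        contigs, truth = fixtures.simulate_contigs(genome, cfg, truth)
        pairs = fixtures.simulate_hic(genome, cfg, truth)
        agp, fasta, report = scaffolder.scaffold(
            pairs, contigs, ScaffoldConfig(n_seeds=2, bin_size=2_000))
        w = agp[agp["component_type"] == "W"]
        assert sorted(w["component_id"]) == sorted(contigs)
        assert report["n_contigs"] == len(contigs)
        # scaffold FASTA lengths match AGP spans
        spans = agp.groupby("object")["object_end"].max()
        for sid, seq in fasta.items():
            assert len(seq) == spans[sid]
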