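"""Simulation fixtures: determinism, truth-table consistency, formats."""

import numpy as np
import pandas as pd
import pytest

from gigasm import fixtures
from gigasm.alignio import revcomp
from gigasm.fixtures import RepeatFamily, SimConfig


class TestConfigValidation:
    def test_rejects_nonpositive_chromosome(self):
        with pytest.raises(ValueError):
            SimConfig(chromosome_lengths=(0,))

    def test_rejects_bad_error_rate(self):
        with pytest.raises(ValueError):
            SimConfig(read_error_rate=1.5)

    def test_rejects_misjoins_exceeding_breaks(self):
        with pytest.raises(ValueError):
            SimConfig(contig_break_count=2, misjoin_count=3)

    def test_rejects_bad_family(self):
        with pytest.raises(ValueError):
            RepeatFamily("f", 0, 10, 0.1)
        with pytest.raises(ValueError):
            RepeatFamily("f", 100, 10, 0.9)


class TestSimulateGenome:
    def test_lengths_without_repeats(self):
        cfg = SimConfig(seed=1, chromosome_lengths=(30_000, 20_000))
        genome, truth = fixtures.simulate_genome(cfg)
        assert {c: len(s) for c, s in genome.items()} == \
            {"chr1": 30_000, "chr2": 20_000}
        assert len(truth.repeat_intervals) == 0

    def test_repeat_copies_recorded_and_inserted(self):
        cfg = SimConfig(seed=1, chromosome_lengths=(50_000,),
                        repeat_families=(RepeatFamily("fam1", 300, 50, 0.02),))
        genome, truth = fixtures.simulate_genome(cfg)
        assert len(truth.repeat_intervals) == 50
        assert len(truth.repeat_copies) == 50
        # insertion: genome grows by exactly the inserted repeat bases
        assert len(genome["chr1"]) == 50_000 + 50 * 300
        widths = truth.repeat_intervals["end"] - truth.repeat_intervals["start"]
        assert (widths == 300).all()

    def test_interval_coordinates_are_final(self):
        cfg = SimConfig(seed=3, chromosome_lengths=(40_000,),
                        repeat_families=(RepeatFamily("fam1", 200, 20, 0.0),))
        genome, truth = fixtures.simulate_genome(cfg)
        # zero divergence: every interval slice is the identical consensus
        slices = {genome[r.chrom][r.start:r.end]
                  for r in truth.repeat_intervals.itertuples()}
        assert len(slices) == 1

    def test_deterministic(self):
        cfg = SimConfig(seed=7, chromosome_lengths=(20_000,),
                        repeat_families=(RepeatFamily("fam1", 100, 5, 0.05),))
        g1, t1 = fixtures.simulate_genome(cfg)
        g2, t2 = fixtures.simulate_genome(cfg)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1.repeat_copies, t2.repeat_copies)


class TestSimulateReads:
    def test_coverage_reached(self):
        cfg = SimConfig(seed=2, chromosome_lengths=(50_000,), read_coverage=5)
        genome, truth = fixtures.simulate_genome(cfg)
        reads, truth = fixtures.simulate_reads(genome, cfg, truth)
        total = sum(len(s) for s in reads.values())
        assert total >= 5 * 50_000

    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimConfig(seed=2, chromosome_lengths=(50_000,), read_coverage=2)
        genome, truth = fixtures.simulate_genome(cfg)
        reads, truth = fixtures.simulate_reads(genome, cfg, truth)
        for row in truth.read_origins.head(30).itertuples():
            expect = genome[row.chrom][row.start:row.end]
            if row.strand == "-":
                expect = revcomp(expect)
            assert reads[row.read_id] == expect

    def test_error_rate_realised(self):
        cfg = SimConfig(seed=2, chromosome_lengths=(50_000,), read_coverage=2,
                        read_error_rate=0.05)
        genome, truth = fixtures.simulate_genome(cfg)
        reads, truth = fixtures.simulate_reads(genome, cfg, truth)
        mismatches = bases = 0
        for row in truth.read_origins.head(50).itertuples():
            ref = genome[row.chrom][row.start:row.end]
            if row.strand == "-":
                ref = revcomp(ref)
            read = reads[row.read_id]
            mismatches += sum(a != b for a, b in zip(read, ref))
            bases += len(ref)
        rate = mismatches / bases
        assert 0.03 < rate < 0.07

    def test_deterministic(self):
        cfg = SimConfig(seed=5, chromosome_lengths=(20_000,), read_coverage=2)
        genome, _ = fixtures.simulate_genome(cfg)
        r1, _ = fixtures.simulate_reads(genome, cfg)
        r2, _ = fixtures.simulate_reads(genome, cfg)
        assert r1 == r2

    def test_rejects_empty_genome(self):
        with pytest.raises(ValueError):
            fixtures.simulate_reads({}, SimConfig())


class TestSimulateContigs:
    def test_contigs_tile_genome(self):
        cfg = SimConfig(seed=4, chromosome_lengths=(100_000, 60_000),
                        contig_break_count=6, min_segment_length=10_000)
        genome, truth = fixtures.simulate_genome(cfg)
        contigs, truth = fixtures.simulate_contigs(genome, cfg, truth)
        co = truth.contig_origins
        for chrom, L in (("chr1", 100_000), ("chr2", 60_000)):
            sub = co[co["chrom"] == chrom].sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == L
            assert (sub["start"].iloc[1:].to_numpy()
                    == sub["end"].iloc[:-1].to_numpy()).all()
        # sequence content matches origins
        for cid, grp in co.groupby("contig_id"):
            grp = grp.sort_values("part_index")
            joined = "".join(genome[r.chrom][r.start:r.end]
                             for r in grp.itertuples())
            assert contigs[cid] == joined

    def test_misjoins_are_cross_chromosome_with_offsets(self):
        cfg = SimConfig(seed=4, chromosome_lengths=(100_000, 60_000),
                        contig_break_count=6, misjoin_count=2,
                        min_segment_length=10_000)
        genome, truth = fixtures.simulate_genome(cfg)
        contigs, truth = fixtures.simulate_contigs(genome, cfg, truth)
        assert len(truth.misjoin_positions) == 2
        co = truth.contig_origins
        for row in truth.misjoin_positions.itertuples():
            parts = co[co["contig_id"] == row.contig_id] \
                .sort_values("part_index")
            assert len(parts) == 2
            assert parts["chrom"].nunique() == 2
            assert row.offset == int(parts.iloc[0]["end"]
                                     - parts.iloc[0]["start"])

    def test_segment_floor_respected(self):
        cfg = SimConfig(seed=4, chromosome_lengths=(100_000,),
                        contig_break_count=5, min_segment_length=12_000)
        genome, truth = fixtures.simulate_genome(cfg)
        _, truth = fixtures.simulate_contigs(genome, cfg, truth)
        widths = truth.contig_origins["end"] - truth.contig_origins["start"]
        assert (widths >= 12_000).all()

    def test_too_many_breaks_raises(self):
        cfg = SimConfig(seed=1, chromosome_lengths=(30_000,),
                        contig_break_count=5, min_segment_length=10_000)
        genome, _ = fixtures.simulate_genome(cfg)
        with pytest.raises(ValueError):
            fixtures.simulate_contigs(genome, cfg)


class TestSimulateHic:
    def test_pair_count_and_orientation(self):
        cfg = SimConfig(seed=6, chromosome_lengths=(80_000, 40_000),
                        hic_pair_count=5_000)
        genome, truth = fixtures.simulate_genome(cfg)
        pairs = fixtures.simulate_hic(genome, cfg, truth)
        assert len(pairs) == 5_000
        # upper-triangular ordering
        same = pairs["chrom1"] == pairs["chrom2"]
        assert (pairs.loc[same, "pos1"] <= pairs.loc[same, "pos2"]).all()
        assert (pairs.loc[~same, "chrom1"] <= pairs.loc[~same, "chrom2"]).all()
        assert pairs["pos1"].min() >= 1

    def test_zero_trans_fraction_all_cis(self):
        cfg = SimConfig(seed=6, chromosome_lengths=(80_000, 40_000),
                        hic_pair_count=3_000, hic_trans_fraction=0.0)
        genome, _ = fixtures.simulate_genome(cfg)
        pairs = fixtures.simulate_hic(genome, cfg)
        assert (pairs["chrom1"] == pairs["chrom2"]).all()

    def test_steeper_decay_shortens_separations(self):
        base = dict(seed=6, chromosome_lengths=(200_000,),
                    hic_pair_count=5_000, hic_trans_fraction=0.0)
        cfg_shallow = SimConfig(**base, hic_decay_exponent=0.5)
        cfg_steep = SimConfig(**base, hic_decay_exponent=1.5)
        shallow = fixtures.simulate_hic(
            fixtures.simulate_genome(cfg_shallow)[0], cfg_shallow)
        steep = fixtures.simulate_hic(
            fixtures.simulate_genome(cfg_steep)[0], cfg_steep)
        med = lambda df: (df["pos2"] - df["pos1"]).median()  # noqa: E731
        assert med(steep) < med(shallow) / 3

    def test_misjoined_layout_coordinates_consistent(self):
        cfg = SimConfig(seed=8, chromosome_lengths=(100_000, 60_000),
                        contig_break_count=6, misjoin_count=2,
                        min_segment_length=10_000, hic_pair_count=2_000)
        genome, truth = fixtures.simulate_genome(cfg)
        contigs, truth = fixtures.simulate_contigs(genome, cfg, truth)
        pairs = fixtures.simulate_hic(genome, cfg, truth)
        lengths = {c: len(s) for c, s in contigs.items()}
        assert set(pairs["chrom1"]) <= set(lengths)
        for side in ("1", "2"):
            ok = pairs[f"pos{side}"] <= pairs[f"chrom{side}"].map(lengths)
            assert ok.all()

    def test_deterministic(self):
        cfg = SimConfig(seed=9, chromosome_lengths=(50_000, 30_000),
                        hic_pair_count=1_000)
        genome, _ = fixtures.simulate_genome(cfg)
        p1 = fixtures.simulate_hic(genome, cfg)
        p2 = fixtures.simulate_hic(genome, cfg)
        pd.testing.assert_frame_equal(p1, p2)


class TestTruthTracks:
    def test_read_truth_tracks_flip_minus_strand(self):
        truth = fixtures.TruthTables(
            repeat_intervals=pd.DataFrame(
                [{"chrom": "chr1", "start": 100, "end": 200,
                  "family_id": "f", "te_class": "LINE", "divergence": 0.0}]),
            read_origins=pd.DataFrame([
                {"read_id": "plus", "chrom": "chr1", "start": 50, "end": 250,
                 "strand": "+"},
                {"read_id": "minus", "chrom": "chr1", "start": 50, "end": 250,
                 "strand": "-"},
                {"read_id": "outside", "chrom": "chr1", "start": 300,
                 "end": 400, "strand": "+"},
            ]))
        tracks = fixtures.read_truth_tracks(truth)
        assert tracks["plus"] == [(50, 150)]
        assert tracks["minus"] == [(50, 150)]  # symmetric read: same flipped
        assert tracks["outside"] == []

    def test_clipping_at_read_edges(self):
        truth = fixtures.TruthTables(
            repeat_intervals=pd.DataFrame(
                [{"chrom": "chr1", "start": 0, "end": 500, "family_id": "f",
                  "te_class": "LINE", "divergence": 0.0}]),
            read_origins=pd.DataFrame([
                {"read_id": "r", "chrom": "chr1", "start": 400, "end": 700,
                 "strand": "+"}]))
        assert fixtures.read_truth_tracks(truth)["r"] == [(0, 100)]


class TestFileFormats:
    def test_fasta_round_trip(self, tmp_path):
        seqs = {"a": "ACGT" * 50, "b": "GGGTTTAAACCC"}
        path = tmp_path / "x.fa"
        fixtures.write_fasta(seqs, path)
        assert fixtures.read_fasta(path) == seqs

    def test_pairs_round_trip(self, tmp_path):
        cfg = SimConfig(seed=1, chromosome_lengths=(30_000,),
                        hic_pair_count=200, hic_trans_fraction=0.0)
        genome, _ = fixtures.simulate_genome(cfg)
        pairs = fixtures.simulate_hic(genome, cfg)
        path = tmp_path / "x.pairs"
        fixtures.write_pairs(pairs, path)
        back = fixtures.read_pairs(path)
        pd.testing.assert_frame_equal(pairs.reset_index(drop=True), back)

    def test_write_truth_emits_all_tables(self, tmp_path):
        cfg = SimConfig(seed=1, chromosome_lengths=(30_000,))
        genome, truth = fixtures.simulate_genome(cfg)
        fixtures.write_truth(truth, tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {"repeat_intervals.bed", "repeat_copies.tsv",
                "read_origins.tsv", "contig_origins.tsv",
                "misjoin_positions.tsv"} <= names
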