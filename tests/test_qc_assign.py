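"""Trimming/length-filter exactness and the sequential assignment contracts:
brute-force index equivalence, calibration-first precedence, uniqueness
filtering, partition accounting and truth agreement on simulated reads."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import calchip as cc
from calchip.qc import filter_short, trim_read, trim_readset
from calchip.sequtils import reverse_complement


def brute_force_occurrences(genome: cc.Genome, query: str):
    """Independent oracle: scan every chromosome position on both strands."""
    hits = []
    rc = reverse_complement(query)
    for name, seq in genome.chromosomes:
        for i in range(len(seq) - len(query) + 1):
            if seq[i : i + len(query)] == query:
                hits.append((name, i, "+"))
            if seq[i : i + len(query)] == rc:
                hits.append((name, i, "-"))
    return sorted(hits)


class TestTrim:
    @pytest.mark.parametrize(
        "length,expected",
        [(220, 190), (8, 0), (150, 140), (200, 190), (10, 0), (11, 1)],
    )
    def test_trimmed_lengths(self, length, expected):
        seq = "ACGT" * 60
        assert len(trim_read(seq[:length])) == expected

    def test_trim_content_is_index_slice(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 150))
        assert trim_read(seq) == seq[10:200]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            trim_read("ACGT", trim5=-1)
        with pytest.raises(ValueError):
            trim_read("ACGT", trim5=10, max_len=10)


class TestFilterShort:
    def test_threshold_boundary(self):
        rs = cc.ReadSet("t0", "IP", [cc.Read(f"r{i}", "A" * n) for i, n in enumerate([49, 50, 190])])
        kept = filter_short(rs, 50)
        assert [len(r.sequence) for r in kept.reads] == [50, 190]

    def test_zero_threshold_is_identity(self):
        rs = cc.ReadSet("t0", "IP", [cc.Read("a", "ACG"), cc.Read("b", "")])
        assert [r.id for r in filter_short(rs, 0).reads] == ["a", "b"]

    def test_all_removed(self):
        rs = cc.ReadSet("t0", "WCE", [cc.Read(f"r{i}", "A" * 10) for i in range(5)])
        assert len(filter_short(rs, 50)) == 0


class TestExactIndex:
    def test_repeated_palindromic_query(self):
        genome = cc.Genome("experimental", [("c1", "ACGTACGT")])
        index = cc.build_index(genome)
        hits = sorted(index.lookup("ACGT"))
        # ACGT is its own reverse complement: both strands at both starts
        assert hits == [("c1", 0, "+"), ("c1", 0, "-"), ("c1", 4, "+"), ("c1", 4, "-")]

    def test_absent_query_empty(self):
        genome = cc.Genome("experimental", [("c1", "AAAACCCC")])
        assert cc.build_index(genome).lookup("GTGTG") == []

    def test_empty_query_errors(self):
        genome = cc.Genome("experimental", [("c1", "ACGT")])
        with pytest.raises(ValueError):
            cc.build_index(genome).lookup("")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_lookup_matches_brute_force(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        # small alphabet-dense genome so repeats and rc hits actually occur
        chroms = [
            (f"c{i}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 120)))))
            for i in range(int(rng.integers(1, 4)))
        ]
        genome = cc.Genome("experimental", chroms)
        index = cc.build_index(genome)
        qlen = data.draw(st.integers(1, 40))
        if data.draw(st.booleans()):
            # query drawn from the genome so hits exist
            name, seq = chroms[0]
            if len(seq) >= qlen:
                start = int(rng.integers(0, len(seq) - qlen + 1))
                query = seq[start : start + qlen]
            else:
                query = "".join(rng.choice(list("ACGT"), qlen))
        else:
            query = "".join(rng.choice(list("ACGT"), qlen))
        assert sorted(index.lookup(query)) == brute_force_occurrences(genome, query)


@pytest.fixture(scope="module")
def toy():
    # calibration carries a copy of SHARED; experimental has SHARED and a repeat
    shared = "ACGTTGCAACGTTGCAACGTTGCA"  # 24 bp
    exp_unique = "GGATCCGGATAACCGGTTAACCGG"
    repeat = "TTGACCATTGGCCAATGGTCATGC"
    exp = cc.Genome(
        "experimental",
        [("chrA", exp_unique + shared + repeat + "ACTG" + repeat)],
    )
    cal = cc.Genome("calibration", [("calA", "CCTAGGCCTATTGGCCAATTGGCC" + shared)])
    return exp, cal, shared, exp_unique, repeat


class TestAssignReads:

    def test_cross_genome_read_goes_to_calibration(self, toy):
        exp, cal, shared, *_ = toy
        rs = cc.ReadSet("t0", "IP", [cc.Read("r1", shared)])
        res = cc.assign_reads(rs, cc.build_index(cal, k=8), cc.build_index(exp, k=8))
        assert res.counts["calib_unique"] == 1
        assert res.experimental_records == []
        assert res.calibration_records[0].chrom == "calA"

    def test_experimental_multimapper_excluded_from_records(self, toy):
        exp, cal, _, _, repeat = toy
        rs = cc.ReadSet("t0", "IP", [cc.Read("r1", repeat)])
        res = cc.assign_reads(rs, cc.build_index(cal, k=8), cc.build_index(exp, k=8))
        assert res.counts["exp_multi"] == 1
        assert res.experimental_records == []

    def test_unmatched_read_unassigned_and_partition_sums(self, toy):
        exp, cal, shared, exp_unique, repeat = toy
        reads = [
            cc.Read("both", shared),
            cc.Read("exp", exp_unique),
            cc.Read("multi", repeat),
            cc.Read("nowhere", "A" * 24),
        ]
        rs = cc.ReadSet("t0", "IP", reads)
        res = cc.assign_reads(rs, cc.build_index(cal, k=8), cc.build_index(exp, k=8),
                              count_cross_genome=True)
        assert res.counts == {
            "calib_unique": 1, "calib_multi": 0,
            "exp_unique": 1, "exp_multi": 1, "unassigned": 1,
        }
        assert res.n_input == len(reads)
        assert res.cross_genome_count == 1

    def test_duplicate_ids_rejected(self, toy):
        exp, cal, shared, *_ = toy
        rs = cc.ReadSet("t0", "IP", [cc.Read("r", shared), cc.Read("r", shared)])
        with pytest.raises(ValueError):
            cc.assign_reads(rs, cc.build_index(cal, k=8), cc.build_index(exp, k=8))

    def test_order_insensitivity(self, small_config, small_world, small_indexes):
        exp, cal, _, land, cland = small_world
        calib_index, exp_index = small_indexes
        cfg = cc.SimConfig(**{**small_config.__dict__, "reads_per_sample": 2_000})
        rs, _ = cc.simulate_readset(exp, land, cal, cland, cfg, "IP", "t0", 13)
        forward = cc.assign_reads(rs, calib_index, exp_index)
        reversed_rs = cc.ReadSet(rs.condition, rs.fraction, list(reversed(rs.reads)))
        backward = cc.assign_reads(reversed_rs, calib_index, exp_index)
        assert forward.counts == backward.counts
        assert sorted((r.read_id, r.chrom, r.start) for r in forward.experimental_records) == \
            sorted((r.read_id, r.chrom, r.start) for r in backward.experimental_records)


class TestTruthAgreement:
    def test_assigned_genome_and_position_match_truth(
        self, small_config, small_world, small_indexes
    ):
        """After trimming, forward reads align at truth_start + trim5 and
        reverse reads at truth_start; every read lands on its true genome."""
        exp, cal, _, land, cland = small_world
        calib_index, exp_index = small_indexes
        cfg = cc.SimConfig(**{**small_config.__dict__, "reads_per_sample": 5_000})
        rs, truth = cc.simulate_readset(exp, land, cal, cland, cfg, "IP", "t0", 23)
        trim5 = 10
        kept = filter_short(trim_readset(rs, trim5=trim5, max_len=200), 30)
        res = cc.assign_reads(kept, calib_index, exp_index)
        assert res.counts["unassigned"] == 0
        assert res.counts["calib_multi"] == 0 and res.counts["exp_multi"] == 0
        by_id = truth.records.set_index("read_id")
        for rec in res.experimental_records + res.calibration_records:
            row = by_id.loc[rec.read_id]
            assert rec.genome == row.genome
            assert rec.chrom == row.chrom
            if row.strand == "+":
                assert rec.start == row.start + trim5
            else:
                assert rec.start == row.start
            assert rec.strand == row.strand
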