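"""Generator contracts: determinism, genome separation, landscape shape,
release scaling, and the read-sampling model's closed-form expectations."""
import numpy as np
import pytest

import calchip as cc
from calchip.io import write_fasta, write_fastq
from calchip.sequtils import reverse_complement


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class TestMakeGenomes:
    def test_sizes_and_anchor_count(self, small_config, small_world):
        experimental, calibration, anchors, *_ = small_world
        assert len(experimental.chromosomes) == small_config.n_chromosomes
        assert all(
            experimental.length(n) == small_config.chromosome_length
            for n in experimental.names
        )
        assert calibration.total_size == small_config.calib_genome_size
        assert set(anchors.positions) == set(experimental.names)

    def test_fasta_determinism(self, small_config, tmp_path):
        paths = []
        for i in range(2):
            exp, cal, _ = cc.make_genomes(small_config)
            p = tmp_path / f"run{i}.fasta"
            write_fasta(exp, p)
            write_fasta(cal, tmp_path / f"cal{i}.fasta")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "cal0.fasta").read_bytes() == (tmp_path / "cal1.fasta").read_bytes()

    def test_no_shared_kmers_at_read_length(self):
        """Exhaustive oracle: zero shared 25-mers (either strand) between genomes."""
        cfg = cc.SimConfig(
            seed=5, n_chromosomes=4, chromosome_length=3000, read_length=25,
            fragment_min=30, fragment_max=60, pericentric_half_width=500,
            calib_genome_size=5000, calib_n_chromosomes=2,
        )
        exp, cal, _ = cc.make_genomes(cfg)
        exp_kmers = set()
        for _, seq in exp.chromosomes:
            exp_kmers |= _kmer_set(seq, 25)
        cal_kmers = set()
        for _, seq in cal.chromosomes:
            cal_kmers |= _kmer_set(seq, 25)
            cal_kmers |= _kmer_set(reverse_complement(seq), 25)
        assert not exp_kmers & cal_kmers

    def test_shared_segment_injection_creates_ambiguity(self):
        cfg = cc.SimConfig(
            seed=5, n_chromosomes=2, chromosome_length=3000, read_length=25,
            fragment_min=30, fragment_max=60, pericentric_half_width=500,
            shared_segment_length=200,
        )
        exp, cal, _ = cc.make_genomes(cfg)
        exp_kmers = _kmer_set(exp.chromosomes[0][1], 25)
        cal_kmers = _kmer_set(cal.chromosomes[0][1], 25)
        assert exp_kmers & cal_kmers

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cc.SimConfig(fragment_min=500, fragment_max=200)
        with pytest.raises(ValueError):
            cc.SimConfig(read_length=300, fragment_min=200)
        with pytest.raises(ValueError):
            cc.SimConfig(mix_ratio=0)


class TestLandscape:
    def test_triangular_peak_values(self, small_world):
        experimental, _, anchors, *_ = small_world
        land = cc.build_landscape(experimental, anchors, 1.0, 4.0, 10_000)
        name = experimental.names[0]
        a = anchors[name]
        assert land.tracks[name][a] == pytest.approx(5.0)
        # at or beyond the half-width the track is back at baseline
        assert land.tracks[name][max(0, a - 10_000)] == pytest.approx(1.0)
        assert np.all(land.tracks[name] >= 1.0)

    def test_triangle_mass_closed_form(self):
        """Discrete landscape mass matches baseline*L + amplitude*half_width
        within one amplitude (discretisation of the triangle area)."""
        cfg = cc.SimConfig(seed=2, n_chromosomes=1, chromosome_length=50_000,
                           pericentric_half_width=5_000)
        exp, _, anchors = cc.make_genomes(cfg)
        land = cc.build_landscape(exp, anchors, 1.0, 4.0, 5_000)
        mass = land.tracks["chr1"].sum()
        expected = 1.0 * 50_000 + 4.0 * 5_000
        assert abs(mass - expected) <= 4.0

    def test_negative_parameters_rejected(self, small_world):
        experimental, _, anchors, *_ = small_world
        with pytest.raises(ValueError):
            cc.build_landscape(experimental, anchors, -1.0, 4.0, 100)
        with pytest.raises(ValueError):
            cc.build_landscape(experimental, anchors, 1.0, 4.0, 0)


class TestApplyRelease:
    def test_identity_and_scaling(self, small_world):
        landscape = small_world[3]
        same = cc.apply_release(landscape, 1.0)
        for n in landscape.tracks:
            np.testing.assert_array_equal(same.tracks[n], landscape.tracks[n])
        fifth = cc.apply_release(landscape, 0.2)
        for n in landscape.tracks:
            np.testing.assert_allclose(fifth.tracks[n], 0.2 * landscape.tracks[n])

    def test_masked_release_elementwise(self, small_world):
        experimental, _, anchors, landscape, _ = small_world
        half_width = 2_000
        mask = {}
        for name, track in landscape.tracks.items():
            p = np.arange(len(track))
            mask[name] = np.abs(p - anchors[name]) >= half_width  # arms only
        released = cc.apply_release(landscape, 0.5, mask)
        for name, track in landscape.tracks.items():
            a = anchors[name]
            assert released.tracks[name][a] == track[a]  # anchor untouched
            arm = np.flatnonzero(mask[name])[0]
            assert released.tracks[name][arm] == pytest.approx(0.5 * track[arm])

    def test_mask_length_mismatch(self, small_world):
        landscape = small_world[3]
        bad = {n: np.ones(3, dtype=bool) for n in landscape.tracks}
        with pytest.raises(ValueError):
            cc.apply_release(landscape, 0.5, bad)

    def test_out_of_range_fraction(self, small_world):
        with pytest.raises(ValueError):
            cc.apply_release(small_world[3], 1.5)


class TestSimulateReadset:
    def test_empty_readset(self, small_config, small_world):
        exp, cal, _, land, cland = small_world
        cfg = cc.SimConfig(**{**small_config.__dict__, "reads_per_sample": 0})
        readset, truth = cc.simulate_readset(exp, land, cal, cland, cfg, "WCE", "t0", 1)
        assert len(readset) == 0 and len(truth) == 0

    def test_mass_conservation_and_fastq_determinism(
        self, small_config, small_world, tmp_path
    ):
        exp, cal, _, land, cland = small_world
        sets = []
        for i in range(2):
            readset, truth = cc.simulate_readset(
                exp, land, cal, cland, small_config, "IP", "t0", 99
            )
            assert len(truth) == len(readset) == small_config.reads_per_sample
            p = tmp_path / f"r{i}.fastq"
            write_fastq(readset, p)
            sets.append(p.read_bytes())
        assert sets[0] == sets[1]

    def test_wce_calibration_fraction_binomial(self):
        """WCE calibration-read share matches the DNA-mass fraction within 3 SD."""
        cfg = cc.SimConfig(seed=21, reads_per_sample=200_000)
        exp, cal, anchors = cc.make_genomes(cfg)
        land = cc.build_landscape(exp, anchors)
        cland = cc.uniform_landscape(cal, 1.0)
        _, truth = cc.simulate_readset(exp, land, cal, cland, cfg, "WCE", "t0", 4)
        calib_mass = cal.total_size
        total_mass = cfg.mix_ratio * exp.total_size + calib_mass
        p = calib_mass / total_mass
        n = cfg.reads_per_sample
        observed = (truth.records.genome == "calibration").sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < 3 * sd

    def test_ip_uniform_landscape_matches_wce_fraction(self, small_config, small_world):
        """With equal flat landscapes and no background, occupancy weighting
        degenerates to mass weighting."""
        exp, cal, *_ = small_world
        cfg = cc.SimConfig(**{**small_config.__dict__, "ip_background": 0.0,
                              "reads_per_sample": 100_000})
        flat_exp = cc.uniform_landscape(exp, 1.0)
        flat_cal = cc.uniform_landscape(cal, 1.0)
        _, truth = cc.simulate_readset(exp, flat_exp, cal, flat_cal, cfg, "IP", "t0", 8)
        p = cal.total_size / (cfg.mix_ratio * exp.total_size + cal.total_size)
        n = cfg.reads_per_sample
        observed = (truth.records.genome == "calibration").sum()
        assert abs(observed - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_zero_landscape_without_background_errors(self, small_world):
        exp, cal, *_ = small_world
        cfg = cc.SimConfig(seed=1, n_chromosomes=4, chromosome_length=20_000,
                           read_length=50, fragment_min=60, fragment_max=120,
                           ip_background=0.0, pericentric_half_width=2000)
        zero = cc.OccupancyLandscape("experimental",
                                     {n: np.zeros(exp.length(n)) for n in exp.names})
        zero_cal = cc.OccupancyLandscape("calibration",
                                         {n: np.zeros(cal.length(n)) for n in cal.names})
        with pytest.raises(ValueError):
            cc.simulate_readset(exp, zero, cal, zero_cal, cfg, "IP", "t0", 1)

    def test_mixing_contract_over_seeds(self, small_config, small_world):
        """Mean WCE calibration fraction over 10 seeds within 1% of the mass fraction."""
        exp, cal, _, land, cland = small_world
        cfg = cc.SimConfig(**{**small_config.__dict__, "reads_per_sample": 20_000})
        p_true = cal.total_size / (cfg.mix_ratio * exp.total_size + cal.total_size)
        fractions = []
        for seed in range(10):
            _, truth = cc.simulate_readset(exp, land, cal, cland, cfg, "WCE", "t0", seed)
            fractions.append((truth.records.genome == "calibration").mean())
        assert abs(np.mean(fractions) - p_true) < 0.01

    def test_release_contract_window_counts(self, small_config, small_world):
        """IP read counts in a fixed window drop by the retained fraction,
        within 3 Poisson SD, under seed-paired sampling."""
        exp, cal, _, land, cland = small_world
        r = 0.3
        released = cc.apply_release(land, r)
        cfg = cc.SimConfig(**{**small_config.__dict__, "reads_per_sample": 100_000,
                              "ip_background": 0.0})
        window = ("chr1", 8_000, 12_000)  # spans the pericentric peak

        def window_count(landscape, seed):
            _, truth = cc.simulate_readset(exp, landscape, cal, cland, cfg, "IP", "x", seed)
            rec = truth.records
            sel = (rec.chrom == window[0]) & (rec.start >= window[1]) & (rec.start < window[2])
            return sel.sum()

        before = window_count(land, 17)
        after = window_count(released, 17)
        # account for the occupancy-mass renormalisation of the after-sample
        mass_before = cfg.mix_ratio * land.total_mass() + cland.total_mass()
        mass_after = cfg.mix_ratio * released.total_mass() + cland.total_mass()
        expected = before * r * mass_before / mass_after
        assert abs(after - expected) < 3 * np.sqrt(expected)
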