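"""Trim, length-filter and assign reads, then compute the occupancy ratio.

Reads are assigned calibration-genome-first (any read matching the spike-in
genome is consumed there), and only uniquely matching reads enter the four
counts Wx, Wc, IPx, IPc from which OR = (Wc*IPx)/(Wx*IPc) is formed.
"""
import calchip as cc

config = cc.SimConfig(
    seed=42, n_chromosomes=4, chromosome_length=20_000, read_length=50,
    fragment_min=60, fragment_max=120, reads_per_sample=30_000,
    pericentric_half_width=2_000,
)
experimental, calibration, anchors = cc.make_genomes(config)
landscape = cc.build_landscape(experimental, anchors, 1.0, 4.0, 2_000)
calib_landscape = cc.uniform_landscape(calibration, 1.0)

calib_index = cc.build_index(calibration)
exp_index = cc.build_index(experimental)

results = {}
for fraction, seed in ((cc.WCE, 1), (cc.IP, 2)):
    readset, _ = cc.simulate_readset(
        experimental, landscape, calibration, calib_landscape,
        config, fraction, "t0", seed,
    )
    # 50 bp synthetic reads trim to 40 bp, so the length filter is lowered
    kept = cc.filter_short(cc.trim_readset(readset), min_len=30)
    results[fraction] = cc.assign_reads(kept, calib_index, exp_index)
    print(f"{fraction} partition: {results[fraction].counts}")

stats = cc.stats_from_assignments(results[cc.WCE], results[cc.IP])
scale = cc.calibration_scale(stats)
print(f"Wx={stats.wx} Wc={stats.wc} IPx={stats.ipx} IPc={stats.ipc}")
print(f"occupancy ratio OR = {stats.occupancy_ratio:.3f}")
print(f"calibration scale (OR * 1e6 / IPx) = {scale:.3f}")

# OR > 1 means the IP pulled down proportionally more experimental than
# calibration chromatin relative to the input - i.e. genuine enrichment of
# the tagged protein on the experimental genome.
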