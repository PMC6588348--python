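"""Generate a small spike-in ChIP-seq experiment with known ground truth.

Builds an experimental genome (4 x 20 kb chromosomes with CDEIII anchors),
a calibration genome sharing no k-mer with it, a pericentric occupancy
landscape, and one WCE + one IP read set from the 3:1 cell mixture.
"""
import calchip as cc

config = cc.SimConfig(
    seed=42,
    n_chromosomes=4,
    chromosome_length=20_000,
    read_length=50,
    fragment_min=60,
    fragment_max=120,
    reads_per_sample=30_000,
    pericentric_half_width=2_000,
)

experimental, calibration, anchors = cc.make_genomes(config)
landscape = cc.build_landscape(
    experimental, anchors,
    config.arm_baseline, config.pericentric_amplitude, config.pericentric_half_width,
)
calib_landscape = cc.uniform_landscape(calibration, 1.0)

print(f"experimental genome: {len(experimental.chromosomes)} chromosomes, "
      f"{experimental.total_size:,} bp; anchors at {anchors.positions}")
print(f"calibration genome:  {len(calibration.chromosomes)} chromosomes, "
      f"{calibration.total_size:,} bp")

for fraction in (cc.WCE, cc.IP):
    readset, truth = cc.simulate_readset(
        experimental, landscape, calibration, calib_landscape,
        config, fraction, "t0", seed=7,
    )
    calib_frac = (truth.records.genome == "calibration").mean()
    print(f"{fraction}: {len(readset):,} reads, "
          f"{100 * calib_frac:.1f}% from the calibration genome")

# WCE reads follow DNA mass: at 3:1 mixing of equally sized genomes the
# calibration share should be ~25%. The IP share is lower because the
# experimental landscape carries extra (pericentric) occupancy that competes
# for IP capture.
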