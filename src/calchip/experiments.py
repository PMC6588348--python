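"""Ready-made synthetic experiments at the study's design conditions.

These helpers run the full pipeline under the default generator settings
(16 chromosomes x 150 kb, 3:1 cell mixing, 200-1,000 bp fragments, 190 bp
reads, 2e5 reads per sample, +/-60 kb windows) and return the recovered
statistics, so parameter-recovery and invariance checks can be scripted in a
few lines.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .assign import assign_reads, build_index
from .calibration import calibration_scale, stats_from_assignments
from .coverage import calibrate_track, pileup
from .pipeline import PipelineConfig, RunReport, run_experiment
from .qc import IP, WCE, filter_short, trim_readset
from .simulate import SimConfig, build_landscape, make_genomes, simulate_readset, uniform_landscape


def retention_recovery(
    retained_fraction: float,
    seed: int,
    sim_overrides: dict | None = None,
    **pipeline_kwargs,
) -> RunReport:
    """One before/after experiment; the report carries the recovered retention
    next to the known retained fraction."""
    sim = SimConfig(seed=seed, **(sim_overrides or {}))
    config = PipelineConfig(sim=sim, retained_fraction=retained_fraction, **pipeline_kwargs)
    return run_experiment(config, seed=seed)


def calibrated_mean_signal(
    mix_ratio: float, seed: int, sim_overrides: dict | None = None
) -> float:
    """Genome-wide mean calibrated experimental signal for one WCE/IP pair.

    The quantity the spike-in design promises to keep invariant when the
    cell-mixing ratio changes.
    """
    overrides = dict(sim_overrides or {})
    overrides["mix_ratio"] = mix_ratio
    sim = SimConfig(seed=seed, **overrides)
    ss = np.random.SeedSequence(seed)
    genome_child, wce_child, ip_child = ss.spawn(3)
    experimental, calibration, anchors = make_genomes(sim, seed=genome_child)
    landscape = build_landscape(
        experimental, anchors, sim.arm_baseline, sim.pericentric_amplitude,
        sim.pericentric_half_width,
    )
    calib_land = uniform_landscape(calibration, sim.arm_baseline or 1.0)
    calib_index = build_index(calibration)
    exp_index = build_index(experimental)

    results = {}
    for fraction, child in ((WCE, wce_child), (IP, ip_child)):
        readset, _ = simulate_readset(
            experimental, landscape, calibration, calib_land, sim, fraction, "t0", child
        )
        kept = filter_short(trim_readset(readset))
        results[fraction] = assign_reads(kept, calib_index, exp_index)

    stats = stats_from_assignments(results[WCE], results[IP])
    scale = calibration_scale(stats)
    track = calibrate_track(
        pileup(results[IP].experimental_records, experimental.lengths), scale
    )
    values = np.concatenate([t for t in track.tracks.values()])
    return float(values.mean())


def study_conditions() -> dict:
    """The default generator settings as a plain dict (for reporting)."""
    return dataclasses.asdict(SimConfig())
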