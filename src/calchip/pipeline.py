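"""End-to-end orchestration: simulate -> QC/assign -> calibrate -> profile -> meta.

Synthetic mode generates the genome pair and four read sets (WCE and IP for a
"before" and an "after" condition, the perturbation scaling occupancy by a
known retained fraction), runs the full quantification, and reports the
recovered retention next to the ground truth. Real mode ingests per-sample
alignment tables (converted upstream from BAM), reference FASTAs and an
anchor BED, and runs the identical quantification stages.

All randomness derives from one root seed: a SeedSequence is spawned in a
fixed order (genomes first, then WCE/IP per condition), so reruns with the
same configuration and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assign import AssignmentResult, assign_reads, build_index
from .calibration import calibration_scale, stats_from_assignments
from .coverage import calibrate_track, pileup, retention_track
from .metaprofile import anchor_average, genome_fold_change, pericentric_fraction, ratio_profile
from .qc import IP, WCE, DEFAULT_MAXLEN, DEFAULT_MINLEN, DEFAULT_TRIM5, filter_short, trim_readset
from .simulate import (
    AnchorSet,
    Genome,
    SimConfig,
    apply_release,
    build_landscape,
    make_genomes,
    simulate_readset,
    uniform_landscape,
)

logger = logging.getLogger("calchip")


@dataclass
class RealInputs:
    """Paths for real-data mode: one alignment table per condition x fraction."""

    experimental_fasta: str
    anchors_bed: str
    alignment_tables: dict[str, dict[str, str]]  # condition -> {"WCE": path, "IP": path}


@dataclass
class PipelineConfig:
    sim: SimConfig | None = field(default_factory=SimConfig)
    real: RealInputs | None = None
    retained_fraction: float = 0.14
    conditions: tuple[str, str] = ("t0", "t20")
    window: int = 60_000
    window_left: int | None = None
    window_right: int | None = None
    bin_size: int = 1000
    trim5: int = DEFAULT_TRIM5
    max_len: int = DEFAULT_MAXLEN
    min_len: int = DEFAULT_MINLEN
    calibration_denominator: str = "ip_experimental"
    write_fastq: bool = True

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions (before, after) are compared")
        if (self.sim is None) == (self.real is None):
            raise ValueError("exactly one of synthetic (sim) or real mode must be configured")
        if self.sim is not None and not 0.0 <= self.retained_fraction <= 1.0:
            raise ValueError("retained_fraction must be in [0, 1]")


@dataclass
class RunReport:
    version: str
    seed: int | None
    mode: str
    conditions: tuple[str, str]
    calibration: dict[str, dict[str, float]]
    assignment_counts: dict[str, dict[str, dict[str, int]]]
    retention: float
    fold_reduction: float
    retention_median_pct: dict[str, float]
    retention_masked_fraction: dict[str, float]
    pericentric_fraction_before: dict[str, float]
    pericentric_fraction_after: dict[str, float]
    truth_retained_fraction: float | None = None
    recovery_error: float | None = None

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


def _process_sample(readset, calib_index, exp_index, cfg: PipelineConfig) -> AssignmentResult:
    n_in = len(readset)
    trimmed = trim_readset(readset, cfg.trim5, cfg.max_len)
    kept = filter_short(trimmed, cfg.min_len)
    result = assign_reads(kept, calib_index, exp_index)
    result.counts["length_filtered"] = n_in - len(kept)
    logger.info(
        "%s/%s: %d reads in, %d after QC, counts=%s",
        readset.condition, readset.fraction, n_in, len(kept), result.counts,
    )
    return result


def _quantify(
    results: dict[str, dict[str, AssignmentResult]],
    experimental: Genome,
    anchors: AnchorSet,
    cfg: PipelineConfig,
):
    """Calibration, tracks, retention and meta-profile statistics for two conditions."""
    before, after = cfg.conditions
    lengths = experimental.lengths
    stats, tracks, profiles = {}, {}, {}
    for cond in cfg.conditions:
        st = stats_from_assignments(results[cond][WCE], results[cond][IP])
        scale = calibration_scale(st, denominator=cfg.calibration_denominator)
        depth = pileup(results[cond][IP].experimental_records, lengths)
        track = calibrate_track(
            depth, scale, {"condition": cond, "OR": st.occupancy_ratio, "IPx": st.ipx}
        )
        profile = anchor_average(
            track, anchors, cfg.window, cfg.window_left, cfg.window_right
        )
        stats[cond], tracks[cond], profiles[cond] = (st, scale), track, profile

    retention, fold = genome_fold_change(profiles[before], profiles[after])
    summary = retention_track(tracks[before], tracks[after], cfg.bin_size)
    ratio = ratio_profile(profiles[before], profiles[after])
    peri = {
        cond: {
            chrom: pericentric_fraction(tracks[cond], anchors, cfg.window, chrom)
            for chrom in experimental.names
        }
        | {"genome": pericentric_fraction(tracks[cond], anchors, cfg.window)}
        for cond in cfg.conditions
    }
    return stats, tracks, profiles, ratio, retention, fold, summary, peri


def run_experiment(
    config: PipelineConfig, seed: int | None = None, outdir: str | Path | None = None
) -> RunReport:
    """Run the full pipeline; write intermediates when ``outdir`` is given."""
    if config.sim is not None:
        return _run_synthetic(config, seed, outdir)
    return _run_real(config, outdir)


def _run_synthetic(config: PipelineConfig, seed: int | None, outdir) -> RunReport:
    sim = config.sim
    assert sim is not None
    root_seed = sim.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    genome_child, *sample_children = ss.spawn(1 + 2 * len(config.conditions))

    experimental, calibration, anchors = make_genomes(sim, seed=genome_child)
    land_before = build_landscape(
        experimental, anchors, sim.arm_baseline, sim.pericentric_amplitude,
        sim.pericentric_half_width,
    )
    landscapes = {
        config.conditions[0]: land_before,
        config.conditions[1]: apply_release(land_before, config.retained_fraction),
    }
    calib_land = uniform_landscape(calibration, sim.arm_baseline or 1.0)

    calib_index = build_index(calibration)
    exp_index = build_index(experimental)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        from . import io

        io.write_fasta(experimental, out / "experimental.fasta")
        io.write_fasta(calibration, out / "calibration.fasta")
        io.write_bed_anchors(anchors, out / "anchors.bed")

    results: dict[str, dict[str, AssignmentResult]] = {}
    truths = []
    child_iter = iter(sample_children)
    for cond in config.conditions:
        results[cond] = {}
        for fraction in (WCE, IP):
            child = next(child_iter)
            readset, truth = simulate_readset(
                experimental, landscapes[cond], calibration, calib_land,
                sim, fraction, cond, child,
                retained_fraction=config.retained_fraction,
            )
            truths.append(truth)
            if out is not None and config.write_fastq:
                from . import io

                io.write_fastq(readset, out / f"{cond}_{fraction}.fastq")
            results[cond][fraction] = _process_sample(
                readset, calib_index, exp_index, config
            )

    stats, tracks, profiles, ratio, retention, fold, summary, peri = _quantify(
        results, experimental, anchors, config
    )

    report = RunReport(
        version=__version__,
        seed=root_seed,
        mode="synthetic",
        conditions=config.conditions,
        calibration={
            cond: {
                "Wx": st.wx, "Wc": st.wc, "IPx": st.ipx, "IPc": st.ipc,
                "occupancy_ratio": st.occupancy_ratio, "scale": scale,
            }
            for cond, (st, scale) in stats.items()
        },
        assignment_counts={
            cond: {fr: dict(res.counts) for fr, res in by_fraction.items()}
            for cond, by_fraction in results.items()
        },
        retention=retention,
        fold_reduction=fold,
        retention_median_pct=summary.medians,
        retention_masked_fraction=summary.masked_fraction,
        pericentric_fraction_before=peri[config.conditions[0]],
        pericentric_fraction_after=peri[config.conditions[1]],
        truth_retained_fraction=config.retained_fraction,
        recovery_error=abs(retention - config.retained_fraction),
    )

    if out is not None:
        _write_artifacts(out, config, results, stats, tracks, profiles, ratio, summary, truths)
        (out / "report.json").write_text(report.to_json() + "\n")
    return report


def _run_real(config: PipelineConfig, outdir) -> RunReport:
    from . import io

    real = config.real
    assert real is not None
    experimental = io.read_fasta(real.experimental_fasta, "experimental")
    anchors = io.read_bed_anchors(real.anchors_bed)
    anchors.validate_against(experimental)

    results: dict[str, dict[str, AssignmentResult]] = {}
    for cond in config.conditions:
        if cond not in real.alignment_tables:
            raise ValueError(f"no alignment tables for condition {cond!r}")
        results[cond] = {}
        for fraction in (WCE, IP):
            records = io.read_alignment_table(real.alignment_tables[cond][fraction])
            calib_recs = [r for r in records if r.genome != experimental.label]
            exp_recs = [r for r in records if r.genome == experimental.label]
            counts = {
                "calib_unique": sum(r.unique for r in calib_recs),
                "calib_multi": sum(not r.unique for r in calib_recs),
                "exp_unique": sum(r.unique for r in exp_recs),
                "exp_multi": sum(not r.unique for r in exp_recs),
                "unassigned": 0,
            }
            results[cond][fraction] = AssignmentResult(
                cond, fraction,
                [r for r in calib_recs if r.unique],
                [r for r in exp_recs if r.unique],
                counts,
            )

    stats, tracks, profiles, ratio, retention, fold, summary, peri = _quantify(
        results, experimental, anchors, config
    )
    report = RunReport(
        version=__version__,
        seed=None,
        mode="real",
        conditions=config.conditions,
        calibration={
            cond: {
                "Wx": st.wx, "Wc": st.wc, "IPx": st.ipx, "IPc": st.ipc,
                "occupancy_ratio": st.occupancy_ratio, "scale": scale,
            }
            for cond, (st, scale) in stats.items()
        },
        assignment_counts={
            cond: {fr: dict(res.counts) for fr, res in by_fraction.items()}
            for cond, by_fraction in results.items()
        },
        retention=retention,
        fold_reduction=fold,
        retention_median_pct=summary.medians,
        retention_masked_fraction=summary.masked_fraction,
        pericentric_fraction_before=peri[config.conditions[0]],
        pericentric_fraction_after=peri[config.conditions[1]],
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_artifacts(out, config, results, stats, tracks, profiles, ratio, summary, [])
        (out / "report.json").write_text(report.to_json() + "\n")
    return report


def _write_artifacts(out: Path, config, results, stats, tracks, profiles, ratio, summary, truths):
    from . import io
    import pandas as pd

    if truths:
        frames = [t.records for t in truths if len(t)]
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "truth.tsv", sep="\t", index=False
            )
    for cond, by_fraction in results.items():
        for fraction, res in by_fraction.items():
            io.write_alignment_table(
                res.calibration_records + res.experimental_records,
                out / f"{cond}_{fraction}.alignments.tsv",
            )
            io.write_assignment_summary(res, out / f"{cond}_{fraction}.counts.tsv")
    for cond, (st, scale) in stats.items():
        io.write_calibration_report(st, scale, out / f"{cond}.calibration.tsv")
        io.write_bedgraph(tracks[cond], out / f"{cond}.calibrated.bedgraph")
        io.write_metaprofile(profiles[cond], out / f"{cond}.metaprofile.tsv")
    ratio_df = pd.DataFrame({"offset": ratio.offsets, "ratio": ratio.values})
    ratio_df.to_csv(out / "ratio_profile.tsv", sep="\t", index=False, na_rep="NA")
    io.write_retention(summary, out / "retention")
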