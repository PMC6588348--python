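"""Dense per-base coverage, gap filling, calibrated tracks and retention.

Coverage counts the full span of every unique alignment (the semantics of a
samtools mpileup over single-end reads), and every chromosome position is
materialised - positions with no reads are explicit zeros, matching the
gap-filling step of the original per-chromosome pileup processing. A
calibrated track is the depth track multiplied by the calibration scale
(OR x 1e6 / IPx). Retention compares two calibrated tracks position-wise
(after / before, "percent remaining"), after mean-binning to stabilise the
ratio at realistic depth; bins with zero signal before the perturbation are
masked rather than producing infinities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assign import AlignmentRecord


@dataclass
class DepthTrack:
    genome: str
    tracks: dict[str, np.ndarray]  # per-chromosome dense int coverage

    def __post_init__(self) -> None:
        self.tracks = {n: np.asarray(t, dtype=np.int64) for n, t in self.tracks.items()}


@dataclass
class CalibratedTrack:
    genome: str
    tracks: dict[str, np.ndarray]  # per-chromosome dense float coverage
    provenance: dict = field(default_factory=dict)  # e.g. OR, IPx, condition

    def __post_init__(self) -> None:
        self.tracks = {n: np.asarray(t, dtype=float) for n, t in self.tracks.items()}

    def scaled(self, factor: float) -> "CalibratedTrack":
        return CalibratedTrack(
            self.genome, {n: t * factor for n, t in self.tracks.items()}, dict(self.provenance)
        )


@dataclass
class RetentionSummary:
    """Percent-remaining per bin and its median, per chromosome.

    ``percent`` holds one vector per chromosome with NaN at masked bins
    (zero signal before the perturbation); ``medians`` are computed over
    defined bins only. Orientation is always after/before x 100.
    """

    percent: dict[str, np.ndarray]
    medians: dict[str, float]
    masked_fraction: dict[str, float]
    bin_size: int
    orientation: str = "retention (after/before)"

    @property
    def genome_median(self) -> float:
        values = np.concatenate([v for v in self.percent.values()])
        return float(np.nanmedian(values)) if values.size else float("nan")


def pileup(records: list[AlignmentRecord], chromosome_lengths: dict[str, int]) -> DepthTrack:
    """Dense read-span coverage: depth(p) = #records with start <= p < end."""
    diffs = {n: np.zeros(length + 1, dtype=np.int64) for n, length in chromosome_lengths.items()}
    genome = ""
    for rec in records:
        if rec.chrom not in diffs:
            raise ValueError(f"record on unknown chromosome {rec.chrom!r}")
        length = chromosome_lengths[rec.chrom]
        if not 0 <= rec.start < rec.end <= length:
            raise ValueError(
                f"record {rec.read_id!r} [{rec.start}, {rec.end}) out of bounds on "
                f"{rec.chrom!r} (length {length})"
            )
        diffs[rec.chrom][rec.start] += 1
        diffs[rec.chrom][rec.end] -= 1
        genome = rec.genome
    tracks = {n: np.cumsum(d[:-1]) for n, d in diffs.items()}
    return DepthTrack(genome, tracks)


def fill_gaps(sparse: list[tuple[int, int]], length: int) -> np.ndarray:
    """Expand (position, depth) pairs to a dense vector with zeros elsewhere."""
    out = np.zeros(length, dtype=np.int64)
    seen = set()
    for pos, depth in sparse:
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside [0, {length})")
        if pos in seen:
            raise ValueError(f"duplicate position {pos}")
        seen.add(pos)
        out[pos] = depth
    return out


def calibrate_track(
    depth: DepthTrack, scale: float, provenance: dict | None = None
) -> CalibratedTrack:
    """Multiply every position by the calibration scale, recording provenance."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    tracks = {n: t.astype(float) * scale for n, t in depth.tracks.items()}
    prov = dict(provenance or {})
    prov["scale"] = scale
    return CalibratedTrack(depth.genome, tracks, prov)


def bin_means(values: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean of consecutive ``bin_size`` windows; a trailing partial bin is averaged
    over its actual width."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = len(values)
    edges = np.arange(0, n, bin_size)
    sums = np.add.reduceat(values.astype(float), edges)
    widths = np.minimum(edges + bin_size, n) - edges
    return sums / widths


def retention_track(
    before: CalibratedTrack, after: CalibratedTrack, bin_size: int = 1000
) -> RetentionSummary:
    """Percent of calibrated signal remaining (after/before x 100) per bin.

    Both tracks are mean-binned first; bins whose before-signal is zero are
    masked (NaN) and their fraction reported. The median per chromosome is
    over defined bins only.
    """
    if set(before.tracks) != set(after.tracks):
        raise ValueError("chromosome sets differ between tracks")
    percent, medians, masked = {}, {}, {}
    for name, b in before.tracks.items():
        a = after.tracks[name]
        if len(a) != len(b):
            raise ValueError(f"length mismatch on chromosome {name!r}")
        bb = bin_means(b, bin_size)
        ab = bin_means(a, bin_size)
        ratio = np.full(len(bb), np.nan)
        defined = bb > 0
        ratio[defined] = 100.0 * ab[defined] / bb[defined]
        percent[name] = ratio
        medians[name] = float(np.nanmedian(ratio)) if defined.any() else float("nan")
        masked[name] = float(1.0 - defined.mean())
    return RetentionSummary(percent, medians, masked, bin_size)
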