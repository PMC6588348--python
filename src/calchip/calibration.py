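"""Occupancy-ratio (OR) calibration from matched WCE and IP read counts.

In a spike-in design the IP signal on the experimental genome can be placed
on a common occupancy scale by comparing, between the whole-cell-extract
(WCE) and immunoprecipitated (IP) libraries, the unique read counts on the
experimental (x) and calibration (c) genomes:

    OR = (Wc * IPx) / (Wx * IPc)

The calibrated track is the raw unique-read depth multiplied by
OR * 1e6 / IPx (occupancy ratio, normalised to one million experimental IP
reads). This scaling is exactly invariant to uniform rescaling of either
library's depth, invariant to the spike-in mixing fraction, and proportional
to the underlying occupancy - the three contracts that pin the formula down.
"""
from __future__ import annotations

from dataclasses import dataclass

from .assign import AssignmentResult
from .qc import IP, WCE

PER_READS = 1_000_000


@dataclass(frozen=True)
class CalibrationStats:
    """Unique read counts per genome/sample and the occupancy ratio.

    wx/wc: experimental/calibration unique counts in the WCE library;
    ipx/ipc: the same in the IP library.
    """

    wx: int
    wc: int
    ipx: int
    ipc: int

    def __post_init__(self) -> None:
        for name in ("wx", "wc", "ipx", "ipc"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(
                    f"count {name} must be a positive number of unique reads, got {value}"
                )

    @property
    def occupancy_ratio(self) -> float:
        return (self.wc * self.ipx) / (self.wx * self.ipc)


def occupancy_ratio(wx: int, wc: int, ipx: int, ipc: int) -> CalibrationStats:
    """Validate the four unique-read counts and package them with the OR."""
    return CalibrationStats(wx, wc, ipx, ipc)


def calibration_scale(
    stats: CalibrationStats,
    per_reads: int = PER_READS,
    denominator: str = "ip_experimental",
) -> float:
    """Per-depth multiplier: calibrated value = raw depth x scale.

    ``denominator`` selects what "normalised to 1 million reads" divides by:
    the unique experimental-genome IP reads (default, the reads the track is
    made of) or all unique IP reads (``"ip_total"``).
    """
    if denominator == "ip_experimental":
        denom = stats.ipx
    elif denominator == "ip_total":
        denom = stats.ipx + stats.ipc
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return stats.occupancy_ratio * per_reads / denom


def stats_from_assignments(wce: AssignmentResult, ip: AssignmentResult) -> CalibrationStats:
    """Build CalibrationStats from the unique counts of a WCE/IP assignment pair."""
    if wce.fraction != WCE or ip.fraction != IP:
        raise ValueError("expected a WCE result and an IP result, in that order")
    return CalibrationStats(
        wx=wce.counts["exp_unique"],
        wc=wce.counts["calib_unique"],
        ipx=ip.counts["exp_unique"],
        ipc=ip.counts["calib_unique"],
    )
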