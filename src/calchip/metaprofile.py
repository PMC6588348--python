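"""Anchor-centred meta-profiles and before/after occupancy statistics.

The headline visualisation of calibrated cohesin ChIP-seq is the
centromere-anchored average: for every offset within +/-60 kb of each
chromosome's CDEIII element, the calibrated signal is averaged across all 16
chromosomes. Offsets that run past a chromosome end on some chromosomes are
averaged over the chromosomes that do cover them (truncation, not
zero-padding, which would drag the average toward zero at the window edges).

Before/after comparisons divide two such profiles offset-wise (retention,
after/before) and summarise them as a single genome-wide retention and its
reciprocal fold-reduction ("a sevenfold reduction" ~ retention 0.14). The
pericentric fraction asks how much of a chromosome's total signal lies
within a window of the anchor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CalibratedTrack
from .simulate import AnchorSet

DEFAULT_WINDOW = 60_000


@dataclass
class MetaProfile:
    """Per-offset mean signal around anchors, plus contributing-chromosome counts.

    Offsets run from -window_left to +window_right inclusive; offset 0 is the
    anchor position itself. ``values`` is NaN where no chromosome covers the
    offset.
    """

    offsets: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    window_left: int
    window_right: int


@dataclass
class RatioProfile:
    offsets: np.ndarray
    values: np.ndarray  # NaN where the denominator is zero/undefined
    orientation: str = "retention (after/before)"


def anchor_average(
    track: CalibratedTrack,
    anchors: AnchorSet,
    window: int = DEFAULT_WINDOW,
    window_left: int | None = None,
    window_right: int | None = None,
) -> MetaProfile:
    """Average the track across chromosomes at each offset from the anchors.

    ``window`` sets a symmetric window; asymmetric spans (e.g. -100 kb to
    +60 kb) use ``window_left``/``window_right``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    wl = window if window_left is None else window_left
    wr = window if window_right is None else window_right
    if wl < 0 or wr < 0:
        raise ValueError("window sides must be >= 0")
    n_off = wl + wr + 1
    sums = np.zeros(n_off)
    counts = np.zeros(n_off, dtype=np.int64)
    for name, values in track.tracks.items():
        if name not in anchors.positions:
            raise ValueError(f"no anchor for chromosome {name!r}")
        a = anchors[name]
        lo = max(0, a - wl)
        hi = min(len(values), a + wr + 1)
        if hi <= lo:
            continue
        first = lo - (a - wl)  # index of offset lo-a within the profile
        sums[first : first + (hi - lo)] += values[lo:hi]
        counts[first : first + (hi - lo)] += 1
    means = np.full(n_off, np.nan)
    covered = counts > 0
    means[covered] = sums[covered] / counts[covered]
    return MetaProfile(np.arange(-wl, wr + 1), means, counts, wl, wr)


def ratio_profile(before: MetaProfile, after: MetaProfile) -> RatioProfile:
    """Offset-wise after/before of two equal-window profiles, masked where before == 0."""
    if before.window_left != after.window_left or before.window_right != after.window_right:
        raise ValueError("window mismatch between profiles")
    values = np.full(len(before.offsets), np.nan)
    defined = (before.counts > 0) & (after.counts > 0)
    defined &= np.nan_to_num(before.values, nan=0.0) > 0
    values[defined] = after.values[defined] / before.values[defined]
    return RatioProfile(before.offsets.copy(), values)


def genome_fold_change(before: MetaProfile, after: MetaProfile) -> tuple[float, float]:
    """(retention, fold_reduction) of mean profile signal over defined offsets.

    retention = mean(after) / mean(before) over offsets defined in both
    profiles; fold_reduction is its reciprocal.
    """
    if before.window_left != after.window_left or before.window_right != after.window_right:
        raise ValueError("window mismatch between profiles")
    defined = (before.counts > 0) & (after.counts > 0)
    b = float(np.mean(before.values[defined]))
    if b <= 0:
        raise ValueError("before-profile mean is zero; retention undefined")
    retention = float(np.mean(after.values[defined])) / b
    return retention, 1.0 / retention if retention > 0 else float("inf")


def pericentric_fraction(
    track: CalibratedTrack,
    anchors: AnchorSet,
    window: int = DEFAULT_WINDOW,
    chromosome: str | None = None,
) -> float:
    """Fraction of total signal within [anchor - window, anchor + window].

    Restricted to one chromosome when given, otherwise summed over the whole
    genome (each chromosome's own anchor window).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if chromosome is not None and chromosome not in track.tracks:
        raise ValueError(f"unknown chromosome {chromosome!r}")
    names = [chromosome] if chromosome is not None else list(track.tracks)
    inside = 0.0
    total = 0.0
    for name in names:
        values = track.tracks[name]
        a = anchors[name]
        lo = max(0, a - window)
        hi = min(len(values), a + window + 1)
        inside += float(values[lo:hi].sum())
        total += float(values.sum())
    if total == 0:
        raise ValueError("track has zero total signal")
    return inside / total
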