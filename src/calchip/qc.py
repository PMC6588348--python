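"""Read containers and the trimming / length-filter stage.

Sequencing reads are hard-clipped at the 5' end (adapter / biased-composition
bases) and capped at a maximum original position, then reads that end up
shorter than a minimum length are dropped before genome assignment. The
defaults (drop the first 10 bases, cap at position 200, keep >= 50 bp) turn a
typical 220 bp single-end read into a 190 bp one and discard degenerate
fragments.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

DEFAULT_TRIM5 = 10
DEFAULT_MAXLEN = 200
DEFAULT_MINLEN = 50

WCE = "WCE"
IP = "IP"


@dataclass(slots=True)
class Read:
    id: str
    sequence: str


@dataclass
class ReadSet:
    """A sample's reads plus its descriptor (condition label, WCE or IP fraction)."""

    condition: str
    fraction: str  # "WCE" or "IP"
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("condition label must be non-empty")
        if self.fraction not in (WCE, IP):
            raise ValueError(f"fraction must be {WCE!r} or {IP!r}, got {self.fraction!r}")

    def __len__(self) -> int:
        return len(self.reads)


def trim_read(sequence: str, trim5: int = DEFAULT_TRIM5, max_len: int = DEFAULT_MAXLEN) -> str:
    """Drop the first ``trim5`` bases and truncate at original position ``max_len``.

    Returns bases (trim5, max_len] of the input, possibly empty: a 220 bp read
    becomes 190 bp under the defaults, an 8 bp read becomes empty.
    """
    if trim5 < 0:
        raise ValueError("trim5 must be >= 0")
    if max_len <= trim5:
        raise ValueError("max_len must exceed trim5")
    return sequence[trim5:max_len]


def trim_readset(
    readset: ReadSet, trim5: int = DEFAULT_TRIM5, max_len: int = DEFAULT_MAXLEN
) -> ReadSet:
    """Apply :func:`trim_read` to every read, preserving ids and order."""
    reads = [Read(r.id, trim_read(r.sequence, trim5, max_len)) for r in readset.reads]
    return replace(readset, reads=reads)


def filter_short(readset: ReadSet, min_len: int = DEFAULT_MINLEN) -> ReadSet:
    """Keep only reads of length >= ``min_len``, order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    reads = [r for r in readset.reads if len(r.sequence) >= min_len]
    return replace(readset, reads=reads)
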