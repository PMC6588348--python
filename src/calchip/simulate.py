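"""Synthetic calibrated ChIP-seq experiments with known ground truth.

The generator emulates the spike-in design: experimental-species cells are
mixed with calibration-species cells at a fixed culture ratio (3:1 by
default), chromatin is sheared to 200-1,000 bp fragments, and two libraries
are sequenced per sample - a whole-cell-extract (WCE) library whose reads
sample naked DNA mass, and an immunoprecipitated (IP) library whose reads
sample fragments in proportion to protein occupancy at the fragment midpoint.
Single-end reads of ~190 bp are taken from the fragment 5' end on a uniformly
chosen strand.

Ground-truth occupancy is a per-bp landscape: a flat chromosome-arm baseline
plus a triangular pericentric peak centred on each chromosome's CDEIII
anchor. A "release" perturbation multiplies the landscape by a known retained
fraction, which downstream stages must recover.

The two reference genomes are i.i.d. uniform nucleotide sequences regenerated
until they share no k-mer (forward or reverse-complement), so exact full-read
matching assigns every synthetic read unambiguously unless ambiguity is
injected on purpose (``shared_segment_length``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qc import IP, WCE, Read, ReadSet
from .sequtils import MAX_KMER, encode_kmers, random_sequence, reverse_complement

EXPERIMENTAL = "experimental"
CALIBRATION = "calibration"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A labelled, ordered collection of named chromosome sequences."""

    label: str
    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in genome {self.label!r}")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
        self._seqs = dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    @property
    def total_size(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)


@dataclass
class AnchorSet:
    """One anchor coordinate (0-based, the CDEIII position) per chromosome."""

    positions: dict[str, int]

    def __post_init__(self) -> None:
        for name, pos in self.positions.items():
            if pos < 0:
                raise ValueError(f"anchor for {name!r} is negative")

    def validate_against(self, genome: Genome) -> None:
        for name in genome.names:
            if name not in self.positions:
                raise ValueError(f"no anchor for chromosome {name!r}")
            if not 0 <= self.positions[name] < genome.length(name):
                raise ValueError(f"anchor for {name!r} outside chromosome")

    def __getitem__(self, name: str) -> int:
        return self.positions[name]


@dataclass
class OccupancyLandscape:
    """Per-bp relative protein occupancy (arbitrary units, >= 0) per chromosome."""

    genome_label: str
    tracks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, t in self.tracks.items():
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"track for {name!r} must be 1-D")
            if not np.all(np.isfinite(t)) or np.any(t < 0):
                raise ValueError(f"track for {name!r} has negative or non-finite values")
            self.tracks[name] = t

    def total_mass(self) -> float:
        return float(sum(t.sum() for t in self.tracks.values()))


@dataclass
class SimConfig:
    """Parameters of one synthetic calibrated ChIP-seq experiment.

    Defaults mirror the study design: 16 experimental chromosomes, a 3:1
    experimental:calibration cell mixture, 200-1,000 bp fragments and 190 bp
    reads. ``ip_background`` is the fraction of IP reads captured
    occupancy-independently (drawn like WCE reads).
    """

    seed: int = 0
    n_chromosomes: int = 16
    chromosome_length: int = 150_000
    anchor_positions: dict[str, int] | None = None
    calib_genome_size: int | None = None  # default: match experimental total
    calib_n_chromosomes: int = 4
    mix_ratio: float = 3.0  # experimental cells : calibration cells
    reads_per_sample: int = 200_000
    fragment_min: int = 200
    fragment_max: int = 1000
    read_length: int = 190
    arm_baseline: float = 1.0
    pericentric_amplitude: float = 4.0
    pericentric_half_width: int = 10_000
    ip_background: float = 0.02
    shared_segment_length: int = 0  # >0 injects cross-genome ambiguity on purpose

    def __post_init__(self) -> None:
        if self.calib_genome_size is None:
            self.calib_genome_size = self.n_chromosomes * self.chromosome_length
        self.validate()

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.fragment_min > self.fragment_max:
            raise ValueError("fragment_min must be <= fragment_max")
        if self.read_length > self.fragment_min:
            raise ValueError("read_length must be <= fragment_min")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.mix_ratio <= 0:
            raise ValueError("mix_ratio must be > 0")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if not 0.0 <= self.ip_background <= 1.0:
            raise ValueError("ip_background must be in [0, 1]")
        if self.arm_baseline < 0 or self.pericentric_amplitude < 0:
            raise ValueError("landscape parameters must be non-negative")
        if self.pericentric_half_width <= 0:
            raise ValueError("pericentric_half_width must be positive")
        if self.calib_genome_size < self.calib_n_chromosomes:
            raise ValueError("calibration genome too small for its chromosome count")


@dataclass
class GroundTruth:
    """Per-read origin records plus the perturbation truth, for recovery tests."""

    records: pd.DataFrame  # read_id, genome, chrom, start, strand, sample, condition
    retained_fraction: float | None = None

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _chrom_sizes(total: int, n: int) -> list[int]:
    base = total // n
    sizes = [base] * n
    sizes[-1] += total - base * n
    return sizes


def make_genomes(
    config: SimConfig,
    seed: int | np.random.SeedSequence | None = None,
    max_retries: int = 10,
) -> tuple[Genome, Genome, AnchorSet]:
    """Generate the experimental/calibration genome pair and the anchor set.

    The calibration genome is regenerated (bounded retries) until the two
    genomes share no k-mer, forward or reverse-complement, at
    k = min(31, read_length); since any shared substring of length >= k
    contains a shared k-mer, full-length reads then match exactly one genome.
    Deterministic for a given (config, seed).
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(2 + max_retries)
    rng_exp = np.random.default_rng(children[0])

    exp_chroms = [
        (f"chr{i + 1}", random_sequence(rng_exp, config.chromosome_length))
        for i in range(config.n_chromosomes)
    ]
    experimental = Genome(EXPERIMENTAL, exp_chroms)

    k = min(MAX_KMER, config.read_length)
    exp_kmers = np.unique(
        np.concatenate([encode_kmers(s, k) for _, s in exp_chroms])
        if exp_chroms
        else np.empty(0, np.uint64)
    )

    calib_sizes = _chrom_sizes(config.calib_genome_size, config.calib_n_chromosomes)
    calibration = None
    for attempt in range(max_retries):
        rng_cal = np.random.default_rng(children[1 + attempt])
        cal_chroms = [
            (f"calib{i + 1}", random_sequence(rng_cal, size))
            for i, size in enumerate(calib_sizes)
        ]
        cal_kmers = [encode_kmers(s, k) for _, s in cal_chroms]
        cal_kmers += [encode_kmers(reverse_complement(s), k) for _, s in cal_chroms]
        cal_all = np.unique(np.concatenate(cal_kmers))
        if np.intersect1d(exp_kmers, cal_all, assume_unique=True).size == 0:
            calibration = Genome(CALIBRATION, cal_chroms)
            break
    if calibration is None:
        raise RuntimeError(
            f"could not generate a calibration genome sharing no {k}-mer with the "
            f"experimental genome after {max_retries} attempts; the configuration is "
            "likely alphabet-saturated (genomes too large for the k-mer space)"
        )

    if config.shared_segment_length > 0:
        calibration = _inject_shared_segment(
            experimental, calibration, config.shared_segment_length, children[-1]
        )

    if config.anchor_positions is not None:
        anchors = AnchorSet(dict(config.anchor_positions))
    else:
        anchors = AnchorSet({name: len(seq) // 2 for name, seq in exp_chroms})
    anchors.validate_against(experimental)
    return experimental, calibration, anchors


def _inject_shared_segment(
    experimental: Genome, calibration: Genome, length: int, seed_seq: np.random.SeedSequence
) -> Genome:
    """Copy an experimental segment into the calibration genome (deliberate ambiguity)."""
    rng = np.random.default_rng(seed_seq)
    src_name, src_seq = experimental.chromosomes[0]
    if length > len(src_seq):
        raise ValueError("shared_segment_length exceeds the source chromosome")
    src_start = int(rng.integers(0, len(src_seq) - length + 1))
    segment = src_seq[src_start : src_start + length]
    dst_name, dst_seq = calibration.chromosomes[0]
    if length > len(dst_seq):
        raise ValueError("shared_segment_length exceeds the target chromosome")
    dst_start = int(rng.integers(0, len(dst_seq) - length + 1))
    new_seq = dst_seq[:dst_start] + segment + dst_seq[dst_start + length :]
    chroms = [(dst_name, new_seq)] + calibration.chromosomes[1:]
    return Genome(calibration.label, chroms)


# ---------------------------------------------------------------------------
# occupancy landscapes
# ---------------------------------------------------------------------------

def build_landscape(
    genome: Genome,
    anchors: AnchorSet,
    arm_baseline: float = 1.0,
    pericentric_amplitude: float = 4.0,
    pericentric_half_width: int = 10_000,
) -> OccupancyLandscape:
    """Arm baseline plus a triangular pericentric peak at each anchor.

    value(p) = baseline + amplitude * max(0, 1 - |p - anchor| / half_width)
    """
    if arm_baseline < 0 or pericentric_amplitude < 0 or pericentric_half_width <= 0:
        raise ValueError("landscape parameters must be non-negative (half width positive)")
    anchors.validate_against(genome)
    tracks = {}
    for name, seq in genome.chromosomes:
        p = np.arange(len(seq), dtype=float)
        tri = np.maximum(0.0, 1.0 - np.abs(p - anchors[name]) / pericentric_half_width)
        tracks[name] = arm_baseline + pericentric_amplitude * tri
    return OccupancyLandscape(genome.label, tracks)


def uniform_landscape(genome: Genome, level: float = 1.0) -> OccupancyLandscape:
    """Flat occupancy at ``level`` everywhere (used for the calibration genome)."""
    if level < 0:
        raise ValueError("level must be >= 0")
    return OccupancyLandscape(
        genome.label, {n: np.full(len(s), float(level)) for n, s in genome.chromosomes}
    )


def apply_release(
    landscape: OccupancyLandscape,
    retained_fraction: float,
    region_mask: dict[str, np.ndarray] | None = None,
) -> OccupancyLandscape:
    """Scale occupancy by ``retained_fraction`` genome-wide or within a boolean mask."""
    if not 0.0 <= retained_fraction <= 1.0:
        raise ValueError("retained_fraction must be in [0, 1]")
    tracks = {}
    for name, t in landscape.tracks.items():
        if region_mask is None:
            tracks[name] = t * retained_fraction
        else:
            if name not in region_mask:
                raise ValueError(f"region mask missing chromosome {name!r}")
            mask = np.asarray(region_mask[name], dtype=bool)
            if mask.shape != t.shape:
                raise ValueError(f"mask length mismatch on chromosome {name!r}")
            out = t.copy()
            out[mask] = out[mask] * retained_fraction
            tracks[name] = out
    return OccupancyLandscape(landscape.genome_label, tracks)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class _ChromEntry:
    genome_label: str
    name: str
    seq: str
    length: int
    mass_weight: float  # cells x length
    occ_weight: float  # cells x total occupancy
    occ_cumsum: np.ndarray


def _entries(
    genome: Genome, landscape: OccupancyLandscape, cells: float
) -> list[_ChromEntry]:
    if set(landscape.tracks) != set(genome.names):
        raise ValueError(f"landscape does not match genome {genome.label!r}")
    out = []
    for name, seq in genome.chromosomes:
        t = landscape.tracks[name]
        if len(t) != len(seq):
            raise ValueError(f"landscape length mismatch on {name!r}")
        out.append(
            _ChromEntry(
                genome.label,
                name,
                seq,
                len(seq),
                cells * len(seq),
                cells * float(t.sum()),
                np.cumsum(t),
            )
        )
    return out


def simulate_readset(
    experimental: Genome,
    exp_landscape: OccupancyLandscape,
    calibration: Genome,
    calib_landscape: OccupancyLandscape,
    config: SimConfig,
    sample: str,
    condition: str,
    seed: int | np.random.SeedSequence,
    retained_fraction: float | None = None,
) -> tuple[ReadSet, GroundTruth]:
    """Draw one WCE or IP read set from the mixed-cell chromatin model.

    WCE fragments start uniformly within chromosomes chosen in proportion to
    DNA mass (cells x genome size). IP fragment midpoints are drawn in
    proportion to cells x occupancy, except for a fraction ``ip_background``
    drawn like WCE. Fragment lengths are uniform on
    [fragment_min, fragment_max], truncated at chromosome ends; one read of
    ``read_length`` bases is taken from the fragment 5' end on a uniform
    strand. Deterministic for a given seed.
    """
    if sample not in (WCE, IP):
        raise ValueError(f"sample must be {WCE!r} or {IP!r}")
    config.validate()
    rng = np.random.default_rng(seed)
    entries = _entries(experimental, exp_landscape, config.mix_ratio) + _entries(
        calibration, calib_landscape, 1.0
    )
    n = config.reads_per_sample
    empty_truth = pd.DataFrame(
        columns=["read_id", "genome", "chrom", "start", "strand", "sample", "condition"]
    )
    if n == 0:
        return (
            ReadSet(condition, sample, []),
            GroundTruth(empty_truth, retained_fraction),
        )

    mass_w = np.array([e.mass_weight for e in entries])
    occ_w = np.array([e.occ_weight for e in entries])

    if sample == IP:
        if occ_w.sum() == 0 and config.ip_background == 0:
            raise ValueError("all-zero occupancy landscape with ip_background=0 in IP mode")
        is_mass = rng.random(n) < config.ip_background
    else:
        is_mass = np.ones(n, dtype=bool)

    u_chrom = rng.random(n)
    u_pos = rng.random(n)
    lengths = rng.integers(config.fragment_min, config.fragment_max + 1, size=n)
    strands = rng.integers(0, 2, size=n)  # 0 = '+', 1 = '-'

    ci = np.empty(n, dtype=np.int64)
    cm_mass = np.cumsum(mass_w)
    ci[is_mass] = np.searchsorted(cm_mass, u_chrom[is_mass] * cm_mass[-1], side="right")
    if not is_mass.all():
        cm_occ = np.cumsum(occ_w)
        ci[~is_mass] = np.searchsorted(
            cm_occ, u_chrom[~is_mass] * cm_occ[-1], side="right"
        )
    np.clip(ci, 0, len(entries) - 1, out=ci)

    pos = np.empty(n, dtype=np.int64)
    chrom_len = np.empty(n, dtype=np.int64)
    for k, entry in enumerate(entries):
        sel = ci == k
        if not sel.any():
            continue
        chrom_len[sel] = entry.length
        sel_mass = sel & is_mass
        if sel_mass.any():
            pos[sel_mass] = (u_pos[sel_mass] * entry.length).astype(np.int64)
        sel_occ = sel & ~is_mass
        if sel_occ.any():
            total = entry.occ_cumsum[-1]
            pos[sel_occ] = np.searchsorted(
                entry.occ_cumsum, u_pos[sel_occ] * total, side="right"
            )
        pos[sel] = np.clip(pos[sel], 0, entry.length - 1)

    # fragment bounds: WCE-style draws are fragment starts, occupancy draws midpoints
    raw_start = np.where(is_mass, pos, pos - lengths // 2)
    frag_end = np.minimum(raw_start + lengths, chrom_len)
    frag_start = np.maximum(raw_start, 0)

    # read span: read_length bases from the fragment 5' end on the chosen strand
    read_start = np.where(
        strands == 0, frag_start, np.maximum(frag_end - config.read_length, frag_start)
    )
    read_end = np.where(
        strands == 0, np.minimum(frag_start + config.read_length, frag_end), frag_end
    )

    prefix = f"{condition}_{sample}"
    reads: list[Read] = [None] * n  # type: ignore[list-item]
    for k, entry in enumerate(entries):
        idx = np.flatnonzero(ci == k)
        s = entry.seq
        for i in idx:
            frag = s[read_start[i] : read_end[i]]
            if strands[i]:
                frag = reverse_complement(frag)
            reads[i] = Read(f"{prefix}_{i:07d}", frag)

    labels = np.array([e.genome_label for e in entries])
    chroms = np.array([e.name for e in entries])
    truth = pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "genome": labels[ci],
            "chrom": chroms[ci],
            "start": read_start,
            "strand": np.where(strands == 0, "+", "-"),
            "sample": sample,
            "condition": condition,
        }
    )
    return ReadSet(condition, sample, reads), GroundTruth(truth, retained_fraction)
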