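"""Sequential two-genome read assignment with uniqueness filtering.

Each read is tested against the calibration genome first; any read with at
least one exact full-length occurrence there (forward or reverse complement)
is consumed by the calibration genome and never tested against the
experimental one, mirroring the calibration-first alignment order of the
spike-in protocol. Reads left over are tested against the experimental
genome, and reads matching neither are unassigned. Only reads with exactly
one occurrence in their genome ("unique") yield alignment records; those
records feed the occupancy-ratio counts and the coverage pileups.

Matching is exact end-to-end string matching backed by a sorted k-mer index
(k = 31, or the full read if shorter): a read's first k bases locate
candidate positions, which are then verified by full string comparison, so
lookup is exact, not heuristic. The synthetic genomes are built to share no
k-mer, which makes this the correct oracle for simulated data; real data is
aligned upstream and ingested as tabular alignment records.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qc import ReadSet
from .sequtils import (
    MAX_KMER,
    encode_bases,
    encode_kmer_matrix,
    encode_kmers,
    reverse_complement,
)
from .simulate import Genome


@dataclass(slots=True)
class AlignmentRecord:
    read_id: str
    genome: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    unique: bool = True


@dataclass
class AssignmentResult:
    """Partition of one sample's reads over the two genomes.

    ``counts`` has keys calib_unique, calib_multi, exp_unique, exp_multi,
    unassigned; they always sum to the number of input reads. Only unique
    alignments are kept as records.
    """

    condition: str
    fraction: str
    calibration_records: list[AlignmentRecord] = field(default_factory=list)
    experimental_records: list[AlignmentRecord] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    cross_genome_count: int | None = None

    @property
    def n_input(self) -> int:
        return sum(self.counts.values())


class ExactIndex:
    """Exact full-sequence occurrence lookup over one genome, both strands."""

    def __init__(self, genome: Genome, k: int = MAX_KMER):
        if not genome.chromosomes:
            raise ValueError("cannot index an empty genome")
        if not 1 <= k <= MAX_KMER:
            raise ValueError(f"k must be in [1, {MAX_KMER}]")
        self.genome = genome
        self.k = k
        hashes, chrom_idx, starts = [], [], []
        for ci, (_, seq) in enumerate(genome.chromosomes):
            h = encode_kmers(seq, k) if len(seq) >= k else np.empty(0, np.uint64)
            hashes.append(h)
            chrom_idx.append(np.full(len(h), ci, dtype=np.int32))
            starts.append(np.arange(len(h), dtype=np.int64))
        h = np.concatenate(hashes) if hashes else np.empty(0, np.uint64)
        order = np.argsort(h, kind="stable")
        self._hashes = h[order]
        self._chrom_idx = np.concatenate(chrom_idx)[order]
        self._starts = np.concatenate(starts)[order]
        self._names = genome.names
        self._seqs = [s for _, s in genome.chromosomes]

    # -- single-query API ---------------------------------------------------

    def lookup(self, sequence: str) -> list[tuple[str, int, str]]:
        """All occurrences of ``sequence`` as (chrom, start, strand).

        A '-' hit at position p means genome[p : p+len] equals the reverse
        complement of the query (start is always the leftmost coordinate).
        Raises on an empty query.
        """
        if not sequence:
            raise ValueError("cannot look up an empty sequence")
        if len(sequence) < self.k:
            return self._scan(sequence)
        hits = [
            (self._names[ci], s, "+")
            for ci, s in self._verified(sequence)
        ]
        rc = reverse_complement(sequence)
        hits += [(self._names[ci], s, "-") for ci, s in self._verified(rc)]
        return hits

    def _candidates(self, h: np.uint64) -> range:
        lo = int(np.searchsorted(self._hashes, h, side="left"))
        hi = int(np.searchsorted(self._hashes, h, side="right"))
        return range(lo, hi)

    def _verified(self, sequence: str) -> list[tuple[int, int]]:
        """(chrom_idx, start) positions where the genome literally equals ``sequence``."""
        h = encode_kmers(sequence[: self.k], self.k)
        if h.size == 0:
            return []
        out = []
        L = len(sequence)
        for p in self._candidates(h[0]):
            ci = int(self._chrom_idx[p])
            s = int(self._starts[p])
            if self._seqs[ci][s : s + L] == sequence:
                out.append((ci, s))
        return out

    def _scan(self, sequence: str) -> list[tuple[str, int, str]]:
        """Brute-force scan for queries shorter than the index k-mer size."""
        hits = []
        rc = reverse_complement(sequence)
        for name, seq in zip(self._names, self._seqs):
            for query, strand in ((sequence, "+"), (rc, "-")):
                start = seq.find(query)
                while start != -1:
                    hits.append((name, start, strand))
                    start = seq.find(query, start + 1)
        return hits

    # -- batched API used by assign_reads -----------------------------------

    def match_batch(
        self, sequences: list[str]
    ) -> tuple[np.ndarray, list[tuple[str, int, int, str] | None]]:
        """Occurrence counts and, for uniquely matching reads, the single hit.

        Returns (counts, hits) where hits[i] is (chrom, start, end, strand)
        when counts[i] == 1 and None otherwise. Empty sequences count as no
        occurrence.
        """
        n = len(sequences)
        counts = np.zeros(n, dtype=np.int64)
        hits: list[tuple[str, int, int, str] | None] = [None] * n

        long_idx = [i for i, s in enumerate(sequences) if len(s) >= self.k]
        short_idx = [i for i, s in enumerate(sequences) if 0 < len(s) < self.k]

        for i in short_idx:
            occ = self._scan(sequences[i])
            counts[i] = len(occ)
            if len(occ) == 1:
                c, s, strand = occ[0]
                hits[i] = (c, s, s + len(sequences[i]), strand)

        if long_idx:
            k = self.k
            fwd_buf = "".join(sequences[i][:k] for i in long_idx)
            last_buf = "".join(sequences[i][-k:] for i in long_idx)
            fwd_codes = encode_bases(fwd_buf).reshape(len(long_idx), k)
            last_codes = encode_bases(last_buf).reshape(len(long_idx), k)
            fwd_h = encode_kmer_matrix(fwd_codes)
            # rc(seq)[:k] is the reverse complement of seq[-k:]
            rc_h = encode_kmer_matrix(3 - last_codes[:, ::-1])

            f_lo = np.searchsorted(self._hashes, fwd_h, side="left")
            f_hi = np.searchsorted(self._hashes, fwd_h, side="right")
            r_lo = np.searchsorted(self._hashes, rc_h, side="left")
            r_hi = np.searchsorted(self._hashes, rc_h, side="right")

            for j, i in enumerate(long_idx):
                seq = sequences[i]
                L = len(seq)
                occ = 0
                hit = None
                for p in range(f_lo[j], f_hi[j]):
                    ci = int(self._chrom_idx[p])
                    s = int(self._starts[p])
                    if self._seqs[ci][s : s + L] == seq:
                        occ += 1
                        hit = (self._names[ci], s, s + L, "+")
                if r_lo[j] < r_hi[j]:
                    rc = reverse_complement(seq)
                    for p in range(r_lo[j], r_hi[j]):
                        ci = int(self._chrom_idx[p])
                        s = int(self._starts[p])
                        if self._seqs[ci][s : s + L] == rc:
                            occ += 1
                            hit = (self._names[ci], s, s + L, "-")
                counts[i] = occ
                if occ == 1:
                    hits[i] = hit
        return counts, hits


def build_index(genome: Genome, k: int = MAX_KMER) -> ExactIndex:
    """Build the exact occurrence index for a genome."""
    return ExactIndex(genome, k=k)


def assign_reads(
    readset: ReadSet,
    calib_index: ExactIndex,
    exp_index: ExactIndex,
    count_cross_genome: bool = False,
) -> AssignmentResult:
    """Partition reads calibration-first, keeping unique alignments as records.

    With ``count_cross_genome`` the reads consumed by the calibration genome
    are additionally probed against the experimental genome and the number
    matching both is reported (a bias diagnostic for the sequential order).
    """
    if calib_index.genome.label == exp_index.genome.label:
        raise ValueError("indexes must come from distinct genomes")
    ids = [r.id for r in readset.reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in input")
    seqs = [r.sequence for r in readset.reads]

    calib_counts, calib_hits = calib_index.match_batch(seqs)
    calib_records, exp_records = [], []
    counts = {"calib_unique": 0, "calib_multi": 0, "exp_unique": 0, "exp_multi": 0, "unassigned": 0}

    leftover_idx = []
    for i, c in enumerate(calib_counts):
        if c == 0:
            leftover_idx.append(i)
        elif c == 1:
            counts["calib_unique"] += 1
            chrom, start, end, strand = calib_hits[i]  # type: ignore[misc]
            calib_records.append(
                AlignmentRecord(ids[i], calib_index.genome.label, chrom, start, end, strand)
            )
        else:
            counts["calib_multi"] += 1

    exp_counts, exp_hits = exp_index.match_batch([seqs[i] for i in leftover_idx])
    for j, i in enumerate(leftover_idx):
        c = exp_counts[j]
        if c == 0:
            counts["unassigned"] += 1
        elif c == 1:
            counts["exp_unique"] += 1
            chrom, start, end, strand = exp_hits[j]  # type: ignore[misc]
            exp_records.append(
                AlignmentRecord(ids[i], exp_index.genome.label, chrom, start, end, strand)
            )
        else:
            counts["exp_multi"] += 1

    cross = None
    if count_cross_genome:
        consumed = [seqs[i] for i, c in enumerate(calib_counts) if c > 0]
        cc, _ = exp_index.match_batch(consumed)
        cross = int((cc > 0).sum())

    return AssignmentResult(
        readset.condition, readset.fraction, calib_records, exp_records, counts, cross
    )
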