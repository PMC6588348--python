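"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tabular artifacts (truth tables, alignment
tables, assignment-count summaries, meta-profiles) are tab-separated files
handled with pandas; coverage tracks are 4-column bedGraph (0-based,
half-open, runs of equal value merged). The alignment-table format
(read_id, genome, chrom, start, end, strand, unique) is also the ingestion
point for real data aligned externally and converted from BAM upstream.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assign import AlignmentRecord, AssignmentResult
from .calibration import CalibrationStats
from .coverage import CalibratedTrack, DepthTrack, RetentionSummary
from .metaprofile import MetaProfile
from .qc import Read, ReadSet
from .simulate import AnchorSet, Genome, GroundTruth

ALIGNMENT_COLUMNS = ["read_id", "genome", "chrom", "start", "end", "strand", "unique"]
FASTQ_QUALITY = "I"  # constant placeholder quality (Q40)


# -- FASTA / FASTQ ----------------------------------------------------------

def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, label: str) -> Genome:
    chroms = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return Genome(label, chroms)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in readset.reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{FASTQ_QUALITY * len(read.sequence)}\n")


def read_fastq(path: str | Path, condition: str, fraction: str) -> ReadSet:
    reads = [
        Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(condition, fraction, reads)


# -- BED anchors ------------------------------------------------------------

def write_bed_anchors(anchors: AnchorSet, path: str | Path, name: str = "CDEIII") -> None:
    with open(path, "w") as fh:
        for chrom, pos in anchors.positions.items():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\n")


def read_bed_anchors(path: str | Path) -> AnchorSet:
    positions: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start = fields[0], int(fields[1])
            if chrom in positions:
                raise ValueError(f"multiple anchors for chromosome {chrom!r}")
            positions[chrom] = start
    return AnchorSet(positions)


# -- truth and alignment tables ---------------------------------------------

def write_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.records.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_alignment_table(records: list[AlignmentRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.read_id, r.genome, r.chrom, r.start, r.end, r.strand, int(r.unique)) for r in records],
        columns=ALIGNMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_alignment_table(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return [
        AlignmentRecord(
            str(row.read_id), str(row.genome), str(row.chrom),
            int(row.start), int(row.end), str(row.strand), bool(row.unique),
        )
        for row in df.itertuples(index=False)
    ]


def write_assignment_summary(result: AssignmentResult, path: str | Path) -> None:
    rows = [("condition", result.condition), ("fraction", result.fraction)]
    rows += sorted(result.counts.items())
    if result.cross_genome_count is not None:
        rows.append(("cross_genome", result.cross_genome_count))
    with open(path, "w") as fh:
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")


def read_assignment_summary(path: str | Path) -> dict[str, str | int]:
    out: dict[str, str | int] = {}
    with open(path) as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            out[key] = int(value) if value.lstrip("-").isdigit() else value
    return out


def write_calibration_report(stats: CalibrationStats, scale: float, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"Wx\t{stats.wx}\nWc\t{stats.wc}\nIPx\t{stats.ipx}\nIPc\t{stats.ipc}\n")
        fh.write(f"occupancy_ratio\t{stats.occupancy_ratio!r}\nscale\t{scale!r}\n")


# -- bedGraph ---------------------------------------------------------------

def write_bedgraph(track: DepthTrack | CalibratedTrack, path: str | Path) -> None:
    """4-column bedGraph with runs of equal value merged (zeros included)."""
    with open(path, "w") as fh:
        for chrom, values in track.tracks.items():
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                v_out = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{v_out}\n")


def read_bedgraph(path: str | Path, genome_label: str = "experimental") -> CalibratedTrack:
    """Dense track from a bedGraph; chromosome length is the maximum end seen."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            intervals.setdefault(chrom, []).append((int(start), int(end), float(value)))
    tracks = {}
    for chrom, ivals in intervals.items():
        length = max(e for _, e, _ in ivals)
        dense = np.zeros(length)
        for s, e, v in ivals:
            dense[s:e] = v
        tracks[chrom] = dense
    return CalibratedTrack(genome_label, tracks)


# -- profiles and retention -------------------------------------------------

def write_metaprofile(profile: MetaProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {"offset": profile.offsets, "value": profile.values, "n_chroms": profile.counts}
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metaprofile(path: str | Path) -> MetaProfile:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    offsets = df["offset"].to_numpy(dtype=np.int64)
    return MetaProfile(
        offsets,
        df["value"].to_numpy(dtype=float),
        df["n_chroms"].to_numpy(dtype=np.int64),
        window_left=int(-offsets[0]),
        window_right=int(offsets[-1]),
    )


def write_retention(summary: RetentionSummary, prefix: str | Path) -> None:
    """Retention as bedGraph (<prefix>.bedgraph) plus per-chromosome summary lines."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bedgraph"), "w") as fh:
        for chrom, values in summary.percent.items():
            for i, v in enumerate(values):
                if np.isnan(v):
                    continue
                s = i * summary.bin_size
                fh.write(f"{chrom}\t{s}\t{s + summary.bin_size}\t{v!r}\n")
    with open(prefix.with_suffix(".summary.tsv"), "w") as fh:
        fh.write("chrom\tmedian_percent\tdefined_bins\tmasked_fraction\n")
        for chrom, values in summary.percent.items():
            defined = int(np.sum(~np.isnan(values)))
            fh.write(
                f"{chrom}\t{summary.medians[chrom]!r}\t{defined}\t"
                f"{summary.masked_fraction[chrom]!r}\n"
            )
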