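"""Core data model and I/O: genomes, genes, reads, binned tracks, intervals.

All internal coordinates are 0-based half-open (BED native); GTF-lite input
(1-based closed) is converted on read.  Touching intervals (end == start) do
not overlap.  The TSS of a minus-strand gene is ``end - 1``; "upstream"
always means 5' of the gene.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GeneModel",
    "ReadSet",
    "BinnedTrack",
    "IntervalSet",
    "ParseError",
    "read_regions",
    "write_regions",
    "read_genes_bed12",
    "write_genes_bed12",
    "bin_reads",
    "extract_signal",
    "read_fasta",
    "write_fasta",
    "write_bedgraph",
    "write_wiggle",
]

MISSING = np.nan

ACTIVITIES = ("constitutive", "active_regulated", "inactive")


class ParseError(ValueError):
    """Malformed line in a region file; message names the line number."""


def open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if len(self.chrom_lengths) == 0:
            raise ValueError("empty genome layout")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chrom_lengths[chrom] / bin_size)


@dataclass(frozen=True)
class GeneModel:
    """A gene: coordinates, strand, activity class and expression level.

    ``tss``/``tes`` are derived, strand-aware: the TSS of a + gene is
    ``start``, of a - gene ``end - 1``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    activity: str = "active_regulated"
    expression: float = 0.0

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"{self.gene_id}: unknown activity {self.activity!r}")
        if self.expression < 0:
            raise ValueError(f"{self.gene_id}: negative expression")
        if self.activity != "inactive" and self.expression == 0:
            # tolerated for plain annotation files with no expression column
            pass

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class ReadSet:
    """Aligned reads as plain genomic intervals (chrom, start, end, strand)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "start", "end", "strand"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"ReadSet frame missing columns: {sorted(missing)}")
        if len(frame) and not (frame["start"] < frame["end"]).all():
            raise ValueError("reads must satisfy start < end")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, chrom, start, end, strand) -> "ReadSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": np.asarray(chrom, dtype=object),
                    "start": np.asarray(start, dtype=np.int64),
                    "end": np.asarray(end, dtype=np.int64),
                    "strand": np.asarray(strand, dtype=object),
                }
            )
        )

    @classmethod
    def empty(cls) -> "ReadSet":
        return cls.from_arrays([], [], [], [])

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self, layout: GenomeLayout) -> None:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            if chrom not in layout:
                raise ValueError(f"read on unknown chromosome {chrom!r}")
            n = layout.chrom_lengths[chrom]
            bad = sub[(sub["start"] < 0) | (sub["end"] > n)]
            if len(bad):
                first = bad.iloc[0]
                raise ValueError(
                    f"read outside chromosome bounds: {chrom}:"
                    f"{first['start']}-{first['end']} (length {n})"
                )

    @staticmethod
    def concat(parts: Sequence["ReadSet"]) -> "ReadSet":
        frames = [p.frame for p in parts if len(p)]
        if not frames:
            return ReadSet.empty()
        return ReadSet(pd.concat(frames, ignore_index=True))

    def to_bed(self, path) -> None:
        with open_text(path, "wt") as fh:
            for row in self.frame.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t{row.strand}\n"
                )

    @classmethod
    def from_bed(cls, path) -> "ReadSet":
        iv = read_regions(path, "bed")
        f = iv.frame
        strand = f["strand"].fillna("+") if "strand" in f else "+"
        return cls.from_arrays(f["chrom"], f["start"], f["end"], strand)


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin vectors of counts or log2FC values."""

    bin_size: int
    data: dict[str, np.ndarray]
    value_kind: Literal["count", "log2fc", "delta"] = "count"

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int, value_kind="count"):
        dtype = np.int64 if value_kind == "count" else float
        data = {
            c: np.zeros(layout.n_bins(c, bin_size), dtype=dtype)
            for c in layout.chrom_names
        }
        return cls(bin_size=bin_size, data=data, value_kind=value_kind)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.data)

    def values_concat(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.data])

    def same_layout_as(self, other: "BinnedTrack") -> bool:
        return self.bin_size == other.bin_size and {
            c: len(v) for c, v in self.data.items()
        } == {c: len(v) for c, v in other.data.items()}

    def map(self, fn, value_kind=None) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            data={c: fn(v) for c, v in self.data.items()},
            value_kind=value_kind or self.value_kind,
        )


class IntervalSet:
    """Labeled genomic intervals (chrom, start, end, name[, score, strand])."""

    COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in frame.columns:
                frame[col] = default
        if len(frame) and not (frame["start"] < frame["end"]).all():
            raise ValueError("intervals must satisfy start < end")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = list(records)
        if not rows:
            return cls(
                pd.DataFrame(
                    {
                        "chrom": pd.Series(dtype=object),
                        "start": pd.Series(dtype=np.int64),
                        "end": pd.Series(dtype=np.int64),
                    }
                )
            )
        ncol = len(rows[0])
        cols = cls.COLUMNS[:ncol]
        return cls(pd.DataFrame(rows, columns=cols))

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.frame.itertuples(index=False))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.frame[["chrom", "start", "end", "name", "strand"]]
        b = other.frame[["chrom", "start", "end", "name", "strand"]]
        return a.equals(b)


# ---------------------------------------------------------------------------
# Region readers / writers
# ---------------------------------------------------------------------------


def _parse_int(token: str, what: str, lineno: int, path) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: cannot parse {what} from {token!r}"
        ) from None


def read_regions(path, fmt: str = "bed", layout: GenomeLayout | None = None):
    """Read genomic regions.

    fmt="bed"      -> IntervalSet (BED3/BED6)
    fmt="bed12"    -> list of GeneModel
    fmt="gtf"      -> list of GeneModel (GTF-lite; 1-based closed converted
                      to 0-based half-open on read)

    Unknown chromosomes are flagged only when a layout is supplied.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        return _read_bed(path, layout)
    if fmt == "bed12":
        return read_genes_bed12(path, layout)
    if fmt in ("gtf", "gtf-lite"):
        return _read_gtf_lite(path, layout)
    raise ValueError(f"unknown region format {fmt!r}")


def _check_chrom(chrom, layout, lineno, path):
    if layout is not None and chrom not in layout:
        raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")


def _read_bed(path, layout) -> IntervalSet:
    records = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno, path)
            end = _parse_int(fields[2], "end", lineno, path)
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            _check_chrom(chrom, layout, lineno, path)
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            records.append((chrom, start, end, name, score, strand))
    return IntervalSet.from_records(records)


def write_regions(regions: IntervalSet, path) -> None:
    """Write an IntervalSet as BED6; empty names become the '.' placeholder."""
    with open_text(path, "wt") as fh:
        for row in regions.frame.itertuples(index=False):
            name = row.name if row.name not in ("", None) else "."
            score = int(row.score) if float(row.score).is_integer() else row.score
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{row.strand}\n"
            )


def read_genes_bed12(path, layout: GenomeLayout | None = None) -> list[GeneModel]:
    genes = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED12 needs >= 6 fields")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno, path)
            end = _parse_int(fields[2], "end", lineno, path)
            _check_chrom(chrom, layout, lineno, path)
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return genes


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    """Write genes as single-block BED12."""
    with open_text(path, "wt") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        "1",
                        f"{g.length},",
                        "0,",
                    ]
                )
                + "\n"
            )


def _read_gtf_lite(path, layout) -> list[GeneModel]:
    genes = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "gene":
                continue
            start = _parse_int(start_s, "start", lineno, path) - 1  # to half-open
            end = _parse_int(end_s, "end", lineno, path)
            _check_chrom(chrom, layout, lineno, path)
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip().strip('"')
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand
                )
            )
    return genes


# ---------------------------------------------------------------------------
# FASTA / track export
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(track: BinnedTrack, path) -> None:
    with open_text(path, "wt") as fh:
        for chrom, values in track.data.items():
            for i, v in enumerate(values):
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n"
                )


def write_wiggle(track: BinnedTrack, path) -> None:
    with open_text(path, "wt") as fh:
        for chrom, values in track.data.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step={track.bin_size} "
                     f"span={track.bin_size}\n")
            for v in values:
                fh.write(f"{v:g}\n")


# ---------------------------------------------------------------------------
# Binning and signal extraction
# ---------------------------------------------------------------------------


def bin_reads(
    reads: ReadSet,
    layout: GenomeLayout,
    bin_size: int = 25,
    mode: Literal["five_prime", "overlap"] = "five_prime",
) -> BinnedTrack:
    """Bin reads into fixed-width windows.

    five_prime: each read is assigned once, to the bin containing its
    strand-aware 5' end (total mass is conserved).  overlap: every bin the
    read interval intersects is incremented by 1.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    reads.validate(layout)
    track = BinnedTrack.zeros(layout, bin_size, "count")
    for chrom, sub in reads.frame.groupby("chrom", sort=False):
        out = track.data[chrom]
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        if mode == "five_prime":
            five = np.where(sub["strand"].to_numpy() == "-", end - 1, start)
            np.add.at(out, five // bin_size, 1)
        elif mode == "overlap":
            first = start // bin_size
            last = (end - 1) // bin_size  # inclusive
            # difference-array trick: +1 at first, -1 after last
            diff = np.zeros(len(out) + 1, dtype=np.int64)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            out += np.cumsum(diff[:-1])
        else:
            raise ValueError(f"unknown binning mode {mode!r}")
    return track


def extract_signal(
    track: BinnedTrack,
    chrom: str,
    anchor: int,
    window: tuple[int, int],
    strand: str = "+",
    out_bin: int | None = None,
) -> np.ndarray:
    """Strand-aware signal around an anchor.

    ``window=(up, down)`` selects gene-oriented offsets [-up, +down); the
    returned vector always reads 5'->3' (upstream left).  Positions outside
    the chromosome are NaN.  ``out_bin`` must be a multiple of the track's
    bin size (default: equal to it).
    """
    up, down = window
    if up + down <= 0:
        raise ValueError("window must have positive length")
    bs = track.bin_size
    out_bin = out_bin or bs
    if out_bin % bs != 0:
        raise ValueError("out_bin must be a multiple of the track bin size")
    if (up + down) % bs != 0:
        raise ValueError("window length must be a multiple of the track bin size")
    values = track.data[chrom]
    n_cells = (up + down) // bs
    # sample the track bin containing each cell's center
    rel_centers = -up + (np.arange(n_cells) + 0.5) * bs
    if strand == "+":
        pos = anchor + rel_centers
    elif strand == "-":
        pos = anchor - rel_centers
    else:
        raise ValueError(f"bad strand {strand!r}")
    idx = np.floor(pos / bs).astype(np.int64)
    out = np.full(n_cells, MISSING)
    valid = (idx >= 0) & (idx < len(values))
    out[valid] = values[idx[valid]]
    if out_bin > bs:
        k = out_bin // bs
        out = out.reshape(-1, k)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(out, axis=1)
    return out
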