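"""Shared genomic-coordinate model and readers/writers for the pipeline's formats.

All coordinates are 0-based, half-open, genome-forward.  The atomic signal of a
ChIP-exo, ChIP-seq or input library is the multiset of tag 5' ends per
chromosome and strand: a plus-strand BED record contributes one tag at its
``start``, a minus-strand record one tag at ``end - 1``.  Fragment 3' ends are
discarded on read; every downstream computation uses 5' ends only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")

#: columns a binding-location table must carry
LOCATION_REQUIRED = ("chrom", "midpoint")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class TagTrack:
    """Strand-separated sparse counts of tag 5' ends.

    Parameters
    ----------
    chrom_lengths
        Optional chromosome sizes; when given, tags outside bounds are
        rejected by :meth:`add`.  When absent, lengths are inferred as the
        maximum seen coordinate + 1.
    name, factor, condition
        Library metadata carried through the pipeline.
    """

    def __init__(self, chrom_lengths=None, name="", factor="", condition=""):
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})
        self._infer_lengths = chrom_lengths is None
        self.name = name
        self.factor = factor
        self.condition = condition
        self._counts: dict[tuple[str, str], Counter] = {}
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    # -- construction -----------------------------------------------------
    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        if count <= 0:
            raise ValueError("tag count must be positive")
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        if self._infer_lengths:
            self.chrom_lengths[chrom] = max(
                self.chrom_lengths.get(chrom, 0), pos + 1
            )
        elif chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        elif pos >= self.chrom_lengths[chrom]:
            raise ValueError(
                f"position {pos} outside {chrom} "
                f"(length {self.chrom_lengths[chrom]})"
            )
        self._counts.setdefault((chrom, strand), Counter())[pos] += count
        self._cache.pop((chrom, strand), None)

    # -- queries ----------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths)

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self._counts.values())

    def positions_counts(self, chrom, strand):
        """Sorted positions and their counts for one chromosome/strand."""
        key = (chrom, strand)
        if key not in self._cache:
            c = self._counts.get(key, Counter())
            pos = np.array(sorted(c), dtype=np.int64)
            cnt = np.array([c[p] for p in pos], dtype=np.int64)
            self._cache[key] = (pos, cnt)
        return self._cache[key]

    def dense(self, chrom, strand) -> np.ndarray:
        """Dense per-base count vector of length ``chrom_lengths[chrom]``."""
        n = self.chrom_lengths.get(chrom, 0)
        out = np.zeros(n, dtype=np.float64)
        pos, cnt = self.positions_counts(chrom, strand)
        if len(pos):
            out[pos] = cnt
        return out

    def count_in(self, chrom, start, end, strand=None) -> int:
        """Total tags with 5' end in [start, end); both strands by default."""
        strands = STRANDS if strand is None else (strand,)
        total = 0
        for s in strands:
            pos, cnt = self.positions_counts(chrom, s)
            lo, hi = np.searchsorted(pos, [start, end])
            total += int(cnt[lo:hi].sum())
        return total


# -- tag BED -------------------------------------------------------------


def read_tags(path, chrom_lengths=None, name="") -> TagTrack:
    """Read a tag BED file: one record per mapped tag, 5' end extracted.

    Plus-strand records contribute a tag at ``start``, minus-strand records
    at ``end - 1``.
    """
    track = TagTrack(chrom_lengths=chrom_lengths, name=name)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{ln}: expected >= 6 BED columns, got {len(fields)}"
                )
            chrom, start, end, _name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            if strand not in STRANDS:
                raise ValueError(f"{path}:{ln}: unknown strand {strand!r}")
            if end_i <= start_i:
                raise ValueError(f"{path}:{ln}: end <= start")
            five_prime = start_i if strand == "+" else end_i - 1
            track.add(chrom, strand, five_prime)
    return track


def write_tags(track: TagTrack, path, read_length: int = 1) -> None:
    """Write a TagTrack as 6-column BED, one record per tag (count=1 each)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            records = []
            for strand in STRANDS:
                pos, cnt = track.positions_counts(chrom, strand)
                for p, c in zip(pos, cnt):
                    for _ in range(int(c)):
                        if strand == "+":
                            records.append((int(p), int(p) + read_length, strand))
                        else:
                            records.append(
                                (int(p) - read_length + 1, int(p) + 1, strand)
                            )
            records.sort()
            for i, (s, e, strand) in enumerate(records):
                s = max(s, 0)
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{track.name or 'tag'}.{i}\t1\t{strand}\n"
                )


# -- intervals & location tables -----------------------------------------


def read_intervals(path) -> list[GenomicInterval]:
    """Read a BED file of intervals (blacklist, occupied segments, ...)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_locations(locations: pd.DataFrame, path) -> None:
    """Write a binding-location table as headered TSV."""
    missing = [c for c in LOCATION_REQUIRED if c not in locations.columns]
    if missing:
        raise ValueError(f"location table missing required columns: {missing}")
    locations.to_csv(path, sep="\t", index=False)


def read_locations(path) -> pd.DataFrame:
    """Read a binding-location TSV; errors list any missing required column."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LOCATION_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: location table missing columns: {missing}")
    df["midpoint"] = df["midpoint"].astype(int)
    return df


# -- FASTA ---------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; duplicate names error."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")
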