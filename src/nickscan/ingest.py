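"""Reduce read alignments to the per-position count arrays the scorer consumes.

All coordinates are 0-based, half-open. Conversion from 1-based SAM
coordinates happens inside :func:`load_alignments` and nowhere else.

For every chromosome three integer arrays are kept:

* ``D`` — sequencing depth (reads covering the position over their
  reference span),
* ``F`` — forward-strand reads whose 5' end (leftmost aligned base) is at
  the position,
* ``R`` — reverse-strand reads whose 5' end (rightmost aligned base) is at
  the position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping

import numpy as np
import pysam

from .errors import ConfigurationError, CoordinateError, InputError, ParseError

FORWARD = "forward"
REVERSE = "reverse"

DEFAULT_MIN_MAPQ = 1


@dataclass(frozen=True)
class ReadStart:
    """One primary, mapped alignment reduced to its fragment-end evidence.

    ``start``/``end`` delimit the reference span (CIGAR-aware, soft clips
    excluded), so the counted 5' end is the aligned fragment boundary, not
    the clipped read boundary.
    """

    chrom: str
    strand: str
    start: int
    end: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise InputError(f"unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise InputError(
                f"degenerate read span [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.mapq < 0:
            raise InputError(f"negative mapping quality {self.mapq}")

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the read's 5' end."""
        return self.start if self.strand == FORWARD else self.end - 1


@dataclass
class ReadSet:
    """Column-oriented collection of reads on one chromosome.

    Equivalent to a sequence of :class:`ReadStart` but stored as numpy
    arrays so simulators and tallying can stay vectorised. ``is_reverse``
    marks reverse-strand reads.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    is_reverse: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.is_reverse = np.asarray(self.is_reverse, dtype=bool)
        if not (len(self.starts) == len(self.ends) == len(self.is_reverse)):
            raise InputError("ReadSet arrays must have equal length")
        if len(self.starts) and not np.all(self.starts < self.ends):
            raise InputError("ReadSet contains degenerate spans")

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[ReadStart]:
        for s, e, rev in zip(
            self.starts.tolist(), self.ends.tolist(), self.is_reverse.tolist()
        ):
            yield ReadStart(self.chrom, REVERSE if rev else FORWARD, s, e)

    @classmethod
    def from_reads(cls, chrom: str, reads: Iterable[ReadStart]) -> "ReadSet":
        starts, ends, rev = [], [], []
        for r in reads:
            if r.chrom != chrom:
                raise InputError(f"read on {r.chrom}, expected {chrom}")
            starts.append(r.start)
            ends.append(r.end)
            rev.append(r.strand == REVERSE)
        return cls(chrom, np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64), np.array(rev, dtype=bool))


@dataclass
class PositionCounts:
    """Per-chromosome depth and read-start tallies.

    Invariants: every count is non-negative, ``F[i] <= D[i]`` and
    ``R[i] <= D[i]`` at every position, and the totals of ``F`` and ``R``
    equal the numbers of forward and reverse reads ingested.
    """

    chrom_lengths: Dict[str, int]
    D: Dict[str, np.ndarray] = field(default_factory=dict)
    F: Dict[str, np.ndarray] = field(default_factory=dict)
    R: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if chrom not in self.D:
                self.D[chrom] = np.zeros(length, dtype=np.int64)
            if chrom not in self.F:
                self.F[chrom] = np.zeros(length, dtype=np.int64)
            if chrom not in self.R:
                self.R[chrom] = np.zeros(length, dtype=np.int64)

    def validate(self) -> None:
        for chrom in self.chrom_lengths:
            d, f, r = self.D[chrom], self.F[chrom], self.R[chrom]
            if (d < 0).any() or (f < 0).any() or (r < 0).any():
                raise InputError(f"negative count on {chrom}")
            if (f > d).any() or (r > d).any():
                raise InputError(f"start count exceeds depth on {chrom}")

    def n_forward(self) -> int:
        return int(sum(f.sum() for f in self.F.values()))

    def n_reverse(self) -> int:
        return int(sum(r.sum() for r in self.R.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionCounts):
            return NotImplemented
        if self.chrom_lengths != other.chrom_lengths:
            return False
        return all(
            np.array_equal(self.D[c], other.D[c])
            and np.array_equal(self.F[c], other.F[c])
            and np.array_equal(self.R[c], other.R[c])
            for c in self.chrom_lengths
        )


def chrom_lengths_from_header(path: str) -> Dict[str, int]:
    """Read chromosome lengths from the @SQ lines of a SAM/BAM header."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
    if not lengths:
        raise ConfigurationError(f"{path}: header declares no sequence lengths")
    return lengths


def load_alignments(
    path: str, min_mapq: int = DEFAULT_MIN_MAPQ
) -> Iterator[ReadStart]:
    """Stream primary, mapped alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped, as are
    records with mapping quality below ``min_mapq``. SAM 1-based
    coordinates are converted to the internal 0-based half-open
    convention (pysam already reports them that way).
    """
    if not os.path.exists(path):
        raise InputError(f"alignment file not found: {path}")
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        if not fh.references:
            raise ConfigurationError(
                f"{path}: header declares no sequence lengths"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            try:
                start = rec.reference_start
                end = rec.reference_end
                if end is None or end <= start:
                    raise ValueError("no aligned reference span")
                yield ReadStart(
                    chrom=rec.reference_name,
                    strand=REVERSE if rec.is_reverse else FORWARD,
                    start=start,
                    end=end,
                    mapq=rec.mapping_quality,
                )
            except (ValueError, TypeError) as exc:
                raise ParseError(
                    f"{path}: malformed record {rec.query_name!r}: {exc}"
                ) from exc


def _tally_readset(counts: PositionCounts, rs: ReadSet) -> None:
    if rs.chrom not in counts.chrom_lengths:
        raise CoordinateError(f"unknown chromosome {rs.chrom!r}")
    length = counts.chrom_lengths[rs.chrom]
    if len(rs) == 0:
        return
    if rs.starts.min() < 0 or rs.ends.max() > length:
        bad = int(np.argmax((rs.starts < 0) | (rs.ends > length)))
        raise CoordinateError(
            f"read [{int(rs.starts[bad])}, {int(rs.ends[bad])}) beyond "
            f"{rs.chrom} (length {length})"
        )
    # depth via boundary-difference + cumulative sum
    diff = np.zeros(length + 1, dtype=np.int64)
    np.add.at(diff, rs.starts, 1)
    np.add.at(diff, rs.ends, -1)
    counts.D[rs.chrom] += np.cumsum(diff[:-1])
    fwd = ~rs.is_reverse
    np.add.at(counts.F[rs.chrom], rs.starts[fwd], 1)
    np.add.at(counts.R[rs.chrom], rs.ends[rs.is_reverse] - 1, 1)


def tally_positions(
    reads: Iterable[ReadStart] | ReadSet,
    chrom_lengths: Mapping[str, int],
) -> PositionCounts:
    """Accumulate depth and 5'-end start counts from a read stream.

    ``D`` is incremented over each read's reference span, ``F`` at a
    forward read's leftmost coordinate and ``R`` at a reverse read's
    rightmost covered coordinate (its 5' end).
    """
    counts = PositionCounts(chrom_lengths=dict(chrom_lengths))
    if isinstance(reads, ReadSet):
        _tally_readset(counts, reads)
        return counts

    # batch plain ReadStart streams per chromosome, then vectorise
    buckets: Dict[str, list] = {}
    for r in reads:
        if r.chrom not in counts.chrom_lengths:
            raise CoordinateError(f"unknown chromosome {r.chrom!r} in read")
        buckets.setdefault(r.chrom, []).append(
            (r.start, r.end, r.strand == REVERSE)
        )
    for chrom, rows in buckets.items():
        arr = np.array(rows, dtype=np.int64)
        _tally_readset(
            counts,
            ReadSet(chrom, arr[:, 0], arr[:, 1], arr[:, 2].astype(bool)),
        )
    return counts


def write_counts(counts: PositionCounts, path: str) -> None:
    """Write the tab-separated counts sidecar (rows only where D > 0)."""
    with open(path, "w") as out:
        for chrom, length in counts.chrom_lengths.items():
            out.write(f"#chrom_length\t{chrom}\t{length}\n")
        out.write("#chrom\tpos\tD\tF\tR\n")
        for chrom in counts.chrom_lengths:
            d, f, r = counts.D[chrom], counts.F[chrom], counts.R[chrom]
            for pos in np.nonzero(d)[0].tolist():
                out.write(f"{chrom}\t{pos}\t{d[pos]}\t{f[pos]}\t{r[pos]}\n")


def read_counts(path: str) -> PositionCounts:
    """Load a counts sidecar written by :func:`write_counts`."""
    if not os.path.exists(path):
        raise InputError(f"counts file not found: {path}")
    chrom_lengths: Dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#chrom_length\t"):
                _, chrom, length = line.split("\t")
                chrom_lengths[chrom] = int(length)
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            rows.append(parts)
    if not chrom_lengths:
        raise ConfigurationError(f"{path}: no #chrom_length header lines")
    counts = PositionCounts(chrom_lengths=chrom_lengths)
    for chrom, pos, d, f, r in rows:
        if chrom not in chrom_lengths:
            raise ParseError(f"{path}: row references unknown chromosome {chrom}")
        i = int(pos)
        counts.D[chrom][i] = int(d)
        counts.F[chrom][i] = int(f)
        counts.R[chrom][i] = int(r)
    return counts
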