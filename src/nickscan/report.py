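"""Motif summaries and a minimal per-position conversion counter.

The position-frequency matrix summarises captured-site sequences aligned in
the guide frame (the tabular equivalent of a sequence logo; rendering is
out of scope). The conversion counter is deliberately simple plumbing: it
tallies aligned read bases per reference position and reports the A-to-G
conversion frequency at reference-A positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from .errors import InputError
from .sites import AnnotatedSite

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_ORDER = "ACGT"


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts and proportions over aligned site sequences.

    ``counts`` is (length, 4) over A/C/G/T; ``frequencies`` divides each
    row by its sum (rows with zero counts stay zero).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise InputError("PFM counts must have shape (length, 4)")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = self.counts / totals
        return np.where(totals > 0, freq, 0.0)

    def conservation(self) -> np.ndarray:
        """Maximum base proportion per position (1.0 = perfectly conserved)."""
        return self.frequencies.max(axis=1)

    def write(self, path: str) -> None:
        freq = self.frequencies
        with open(path, "w") as out:
            out.write("#pos\t" + "\t".join(_BASE_ORDER) + "\t" +
                      "\t".join(f"n_{b}" for b in _BASE_ORDER) + "\n")
            for i in range(self.length):
                props = "\t".join(f"{freq[i, j]:.6g}" for j in range(4))
                cnts = "\t".join(str(int(self.counts[i, j])) for j in range(4))
                out.write(f"{i + 1}\t{props}\t{cnts}\n")


def position_frequency_matrix(
    sites: Sequence[AnnotatedSite] | Sequence[str],
) -> PositionFrequencyMatrix:
    """Tally base counts per position over guide-oriented site sequences.

    Accepts annotated sites (their ``matched_sequence`` is used) or plain
    strings; all sequences must have the same length.
    """
    seqs = [
        s.matched_sequence if isinstance(s, AnnotatedSite) else str(s)
        for s in sites
    ]
    if not seqs:
        raise InputError("no sites to summarise")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise InputError("matched sequences have mixed lengths")
    counts = np.zeros((length, 4), dtype=np.int64)
    for seq in seqs:
        for i, base in enumerate(seq.upper()):
            j = _BASE_INDEX.get(base)
            if j is not None:
                counts[i, j] += 1
    return PositionFrequencyMatrix(counts=counts)


@dataclass
class ConversionTable:
    """Per-position base counts over an amplicon plus A-to-G frequency.

    ``a_to_g`` is ``G / (A + G)`` at reference-A positions and NaN where
    there is no A/G evidence or the reference base is not A (missing, not
    zero: absence of coverage is not absence of conversion).
    """

    reference: str
    counts: np.ndarray  # (len(reference), 4) over A/C/G/T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.reference), 4):
            raise InputError("counts shape does not match reference length")

    @property
    def a_to_g(self) -> np.ndarray:
        a = self.counts[:, _BASE_INDEX["A"]].astype(np.float64)
        g = self.counts[:, _BASE_INDEX["G"]].astype(np.float64)
        ref_a = np.frombuffer(
            self.reference.upper().encode("ascii"), dtype="S1"
        ) == b"A"
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = g / (a + g)
        freq[~ref_a] = np.nan
        freq[(a + g) == 0] = np.nan
        return freq

    def write(self, path: str) -> None:
        a2g = self.a_to_g
        with open(path, "w") as out:
            out.write("#pos\tref\t" + "\t".join(_BASE_ORDER) + "\ta_to_g\n")
            for i, ref_base in enumerate(self.reference.upper()):
                cnts = "\t".join(str(int(c)) for c in self.counts[i])
                freq = "NA" if np.isnan(a2g[i]) else f"{a2g[i]:.4f}"
                out.write(f"{i}\t{ref_base}\t{cnts}\t{freq}\n")


def conversion_frequency(
    alignments: str, reference: str, min_mapq: int = 0
) -> ConversionTable:
    """Count aligned read bases per reference position of an amplicon.

    ``alignments`` is a SAM/BAM path whose reads are confined to a single
    reference sequence of exactly ``len(reference)`` bases.
    """
    counts = np.zeros((len(reference), 4), dtype=np.int64)
    with pysam.AlignmentFile(alignments, check_sq=False) as fh:
        if fh.nreferences != 1 or fh.lengths[0] != len(reference):
            raise InputError(
                "alignment header does not declare a single reference of "
                f"length {len(reference)}"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                j = _BASE_INDEX.get(seq[qpos].upper())
                if j is not None:
                    counts[rpos, j] += 1
    return ConversionTable(reference=reference, counts=counts)
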