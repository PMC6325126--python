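"""Per-position cleavage score over depth and read-start counts.

The score at position ``i`` is the sum of two five-term windows,

    sum_{a=1..5} (F_i - 1)/D_i * (R_{i+8+a} - 1)/D_i * (F_i + R_{i+8+a} - 2)
  + sum_{a=1..5} (R_{i+11} - 1)/D_{i+11} * (F_{i-3+a} - 1)/D_{i-3+a}
                 * (R_{i+11} + F_{i-3+a} - 2)

rewarding a forward-start pileup paired with a reverse-start pileup 9-13 bp
downstream — the stagger produced by the two strand nicks of one cleavage
event. Terms whose denominator is zero contribute nothing; with the default
clamping, so do terms whose start count is below ``min_start_reads`` (a
lone read end is noise, and the printed algebra would otherwise yield
negative "evidence").

Note the first window divides by ``D_i`` twice exactly as printed;
``paired_depth_denominator`` switches the second factor to ``D_{i+8+a}``
for symmetry with the second window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import InputError
from .ingest import PositionCounts


@dataclass(frozen=True)
class ScoringParams:
    alpha_min: int = 1
    alpha_max: int = 5
    forward_pair_offset: int = 8
    reverse_anchor_offset: int = 11
    forward_back_offset: int = -3
    clamp_negative: bool = True
    min_start_reads: int = 2
    paired_depth_denominator: bool = False

    def __post_init__(self) -> None:
        if self.alpha_min > self.alpha_max:
            raise InputError("alpha_min must be <= alpha_max")
        if self.min_start_reads < 1:
            raise InputError("min_start_reads must be >= 1")


@dataclass
class ScoreTrack:
    """Sparse per-position scores; absent positions are implicitly 0."""

    scores: Dict[str, Dict[int, float]] = field(default_factory=dict)

    def get(self, chrom: str, pos: int) -> float:
        return self.scores.get(chrom, {}).get(pos, 0.0)

    def n_positions(self) -> int:
        return sum(len(v) for v in self.scores.values())

    def items(self):
        for chrom in sorted(self.scores):
            for pos in sorted(self.scores[chrom]):
                yield chrom, pos, self.scores[chrom][pos]


def _take(arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """arr[idx] with out-of-range indices reading as 0."""
    ok = (idx >= 0) & (idx < len(arr))
    out = np.zeros(len(idx), dtype=arr.dtype)
    out[ok] = arr[idx[ok]]
    return out


def _scores_at(
    D: np.ndarray,
    F: np.ndarray,
    R: np.ndarray,
    idx: np.ndarray,
    params: ScoringParams,
) -> np.ndarray:
    """Vectorised evaluation of the score at each index in ``idx``."""
    ms = params.min_start_reads
    total = np.zeros(len(idx), dtype=np.float64)

    Fi = _take(F, idx).astype(np.float64)
    Di = _take(D, idx).astype(np.float64)
    for alpha in range(params.alpha_min, params.alpha_max + 1):
        j = idx + params.forward_pair_offset + alpha
        Rj = _take(R, j).astype(np.float64)
        denom2 = _take(D, j).astype(np.float64) if params.paired_depth_denominator else Di
        valid = (Di > 0) & (denom2 > 0)
        if params.clamp_negative:
            valid &= (Fi >= ms) & (Rj >= ms)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (Fi - 1) / Di * (Rj - 1) / denom2 * (Fi + Rj - 2)
        total += np.where(valid, term, 0.0)

    j2 = idx + params.reverse_anchor_offset
    Ra = _take(R, j2).astype(np.float64)
    Da = _take(D, j2).astype(np.float64)
    for alpha in range(params.alpha_min, params.alpha_max + 1):
        k = idx + params.forward_back_offset + alpha
        Fk = _take(F, k).astype(np.float64)
        Dk = _take(D, k).astype(np.float64)
        valid = (Da > 0) & (Dk > 0)
        if params.clamp_negative:
            valid &= (Ra >= ms) & (Fk >= ms)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (Ra - 1) / Da * (Fk - 1) / Dk * (Ra + Fk - 2)
        total += np.where(valid, term, 0.0)

    return total


def cleavage_score(
    counts: PositionCounts,
    chrom: str,
    i: int,
    params: ScoringParams = ScoringParams(),
) -> float:
    """Score a single position; offset positions outside the chromosome
    are treated as having zero counts."""
    if chrom not in counts.chrom_lengths:
        raise InputError(f"unknown chromosome {chrom!r}")
    idx = np.array([i], dtype=np.int64)
    return float(
        _scores_at(counts.D[chrom], counts.F[chrom], counts.R[chrom], idx, params)[0]
    )


def score_genome(
    counts: PositionCounts, params: ScoringParams = ScoringParams()
) -> ScoreTrack:
    """Score every position of every chromosome; keep positions scoring > 0.

    With clamping enabled only positions where ``F_i`` or the anchored
    ``R_{i+11}`` reach ``min_start_reads`` can score non-zero, so the scan
    is restricted to those candidates (exactness preserved). Without
    clamping every covered position is evaluated.
    """
    track = ScoreTrack()
    for chrom in counts.chrom_lengths:
        D, F, R = counts.D[chrom], counts.F[chrom], counts.R[chrom]
        if params.clamp_negative:
            ms = params.min_start_reads
            cand_f = np.nonzero(F >= ms)[0]
            cand_r = np.nonzero(R >= ms)[0] - params.reverse_anchor_offset
            idx = np.union1d(cand_f, cand_r)
            idx = idx[(idx >= 0) & (idx < len(D))]
        else:
            # without clamping any position can score (the second window's
            # denominators do not involve D_i), so scan everything
            idx = np.arange(len(D), dtype=np.int64)
        if len(idx) == 0:
            continue
        vals = _scores_at(D, F, R, idx, params)
        keep = vals > 0
        if keep.any():
            track.scores[chrom] = dict(
                zip(idx[keep].tolist(), vals[keep].tolist())
            )
    return track


def write_scores(track: ScoreTrack, path: str) -> None:
    """Tab-separated score table: chrom, 0-based pos, score."""
    with open(path, "w") as out:
        out.write("#chrom\tpos\tscore\n")
        for chrom, pos, score in track.items():
            out.write(f"{chrom}\t{pos}\t{score:.6g}\n")


def read_scores(path: str) -> ScoreTrack:
    track = ScoreTrack()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, score = line.rstrip("\n").split("\t")
            track.scores.setdefault(chrom, {})[int(pos)] = float(score)
    return track


def write_bedgraph(track: ScoreTrack, path: str) -> None:
    """bedGraph export for genome-browser inspection."""
    with open(path, "w") as out:
        out.write('track type=bedGraph name="cleavage_score"\n')
        for chrom, pos, score in track.items():
            out.write(f"{chrom}\t{pos}\t{pos + 1}\t{score:.6g}\n")
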