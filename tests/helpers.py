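"""Independent oracles and small builders shared by the test modules.

Everything here is deliberately written as direct, naive transcriptions —
separate from the library code paths they check.
"""

from __future__ import annotations

import functools
from typing import Dict, Sequence

import numpy as np

from nickscan import PositionCounts


def make_counts(
    D: Sequence[int],
    F: Sequence[int] | None = None,
    R: Sequence[int] | None = None,
    chrom: str = "chr1",
) -> PositionCounts:
    d = np.asarray(D, dtype=np.int64)
    f = np.zeros_like(d) if F is None else np.asarray(F, dtype=np.int64)
    r = np.zeros_like(d) if R is None else np.asarray(R, dtype=np.int64)
    counts = PositionCounts(chrom_lengths={chrom: len(d)})
    counts.D[chrom] = d
    counts.F[chrom] = f
    counts.R[chrom] = r
    return counts


def naive_cleavage_score(
    D: Sequence[int],
    F: Sequence[int],
    R: Sequence[int],
    i: int,
    alpha_min: int = 1,
    alpha_max: int = 5,
    clamp: bool = True,
    min_start_reads: int = 2,
    paired_depth: bool = False,
) -> float:
    """Direct transcription of the two five-term score windows, evaluated
    with plain Python loops (zero-denominator terms contribute 0)."""

    def get(arr, j):
        return int(arr[j]) if 0 <= j < len(arr) else 0

    score = 0.0
    for a in range(alpha_min, alpha_max + 1):
        Fi, Di = get(F, i), get(D, i)
        Rj = get(R, i + 8 + a)
        d2 = get(D, i + 8 + a) if paired_depth else Di
        ok = Di > 0 and d2 > 0
        if clamp:
            ok = ok and Fi >= min_start_reads and Rj >= min_start_reads
        if ok:
            score += (Fi - 1) / Di * (Rj - 1) / d2 * (Fi + Rj - 2)
    for a in range(alpha_min, alpha_max + 1):
        Ra, Da = get(R, i + 11), get(D, i + 11)
        Fk, Dk = get(F, i - 3 + a), get(D, i - 3 + a)
        ok = Da > 0 and Dk > 0
        if clamp:
            ok = ok and Ra >= min_start_reads and Fk >= min_start_reads
        if ok:
            score += (Ra - 1) / Da * (Fk - 1) / Dk * (Ra + Fk - 2)
    return score


def naive_score_all(D, F, R, **kwargs) -> Dict[int, float]:
    """Naive full-genome scan: every position, keep scores > 0."""
    out = {}
    for i in range(len(D)):
        s = naive_cleavage_score(D, F, R, i, **kwargs)
        if s > 0:
            out[i] = s
    return out


def levenshtein_oracle(a: str, b: str) -> int:
    """Plain recursive edit-distance definition (memoised)."""
    a, b = a.upper(), b.upper()

    @functools.lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            go(i - 1, j) + 1,
            go(i, j - 1) + 1,
            go(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return go(len(a), len(b))


def random_counts(rng: np.random.Generator, max_len: int = 100, max_count: int = 50):
    """Random D/F/R arrays honouring F, R <= D at every position."""
    n = int(rng.integers(10, max_len + 1))
    D = rng.integers(0, max_count + 1, size=n)
    F = (rng.random(n) * (D + 1)).astype(np.int64).clip(0, D)
    R = (rng.random(n) * (D + 1)).astype(np.int64).clip(0, D)
    return D.astype(np.int64), F, R


def write_sam_text(path, chrom_lengths: Dict[str, int], records) -> None:
    """Minimal SAM writer for hand-built fixtures.

    ``records`` rows: (qname, flag, chrom, pos_1based, mapq, cigar, seq).
    """
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, flag, chrom, pos, mapq, cigar, seq in records:
            out.write(
                f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\n"
            )
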