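"""Edit-distance matrix between guide target sites and assignment of
multiplex-captured sites to the nearest guide.

Distances are plain Levenshtein with unit costs (insertion = 1,
deletion = 1, substitution = 1), computed case-insensitively. By default
site strings are protospacers without the PAM; ``include_pam`` appends it
(PAMs are largely shared, but an 18-nt guide makes the toggle
consequential).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import InputError
from .sites import AnnotatedSite, GuideRNA


def levenshtein(a: str, b: str) -> int:
    """Minimum number of unit-cost edits transforming ``a`` into ``b``.

    Classic two-row dynamic programme; comparison is case-insensitive so
    DNA strings match regardless of case.
    """
    a, b = a.upper(), b.upper()
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1,          # deletion
                cur[j - 1] + 1,       # insertion
                prev[j - 1] + (ca != cb),  # substitution / match
            )
        prev = cur
    return prev[-1]


@dataclass
class EditDistanceMatrix:
    """Square table of pairwise site distances (zero diagonal, symmetric)."""

    names: List[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        n = len(self.names)
        if self.distances.shape != (n, n):
            raise InputError("distance matrix shape does not match names")

    def __getitem__(self, pair: Tuple[str, str]) -> int:
        i = self.names.index(pair[0])
        j = self.names.index(pair[1])
        return int(self.distances[i, j])

    def offdiagonal(self) -> np.ndarray:
        """Distances over distinct unordered pairs (upper triangle)."""
        iu = np.triu_indices(len(self.names), k=1)
        return self.distances[iu]

    def max_offdiagonal(self) -> int:
        return int(self.offdiagonal().max())

    def mean_offdiagonal(self) -> float:
        """Mean over distinct unordered pairs; the zero diagonal (each site
        against itself) is excluded from the summary."""
        return float(self.offdiagonal().mean())

    def argmax_offdiagonal(self) -> Tuple[str, str]:
        off = self.distances.copy()
        np.fill_diagonal(off, -1)
        i, j = np.unravel_index(int(off.argmax()), off.shape)
        return self.names[min(i, j)], self.names[max(i, j)]

    def write(self, path: str) -> None:
        with open(path, "w") as out:
            out.write("\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.distances):
                out.write(name + "\t" + "\t".join(map(str, row.tolist())) + "\n")


@dataclass(frozen=True)
class Allocation:
    site_index: int
    guide_name: str
    distance: int
    tie: bool


@dataclass
class AllocationResult:
    allocations: List[Allocation]

    def group_sizes(self) -> dict:
        sizes: dict = {}
        for alloc in self.allocations:
            sizes[alloc.guide_name] = sizes.get(alloc.guide_name, 0) + 1
        return sizes

    def write(self, path: str, sites: Sequence[AnnotatedSite] | None = None) -> None:
        with open(path, "w") as out:
            out.write("#site\tguide\tdistance\ttie\n")
            for alloc in self.allocations:
                if sites is not None:
                    s = sites[alloc.site_index]
                    label = f"{s.chrom}:{s.pos}"
                else:
                    label = str(alloc.site_index)
                out.write(
                    f"{label}\t{alloc.guide_name}\t{alloc.distance}\t{int(alloc.tie)}\n"
                )


def _site_string(guide: GuideRNA, include_pam: bool) -> str:
    return guide.site if include_pam else guide.protospacer


def build_distance_matrix(
    guides: Sequence[GuideRNA], include_pam: bool = False
) -> EditDistanceMatrix:
    """Pairwise Levenshtein distances between guide target sites."""
    if len(guides) < 2:
        raise InputError("need at least two guides")
    names = [g.name for g in guides]
    if len(set(names)) != len(names):
        raise InputError("duplicate guide names")
    strings = [_site_string(g, include_pam) for g in guides]
    n = len(strings)
    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(strings[i], strings[j])
            dist[i, j] = dist[j, i] = d
    return EditDistanceMatrix(names=names, distances=dist)


def allocate_sites(
    sites: Sequence[AnnotatedSite],
    guides: Sequence[GuideRNA],
    include_pam: bool = False,
) -> AllocationResult:
    """Assign each captured site to the guide with the smallest edit
    distance to its matched protospacer. Ties are broken by guide order in
    the input list and flagged."""
    if not guides:
        raise InputError("guide list is empty")
    allocations = []
    for idx, site in enumerate(sites):
        query = (
            site.matched_sequence if include_pam else site.matched_protospacer
        )
        dists = [
            levenshtein(query, _site_string(g, include_pam)) for g in guides
        ]
        best = min(dists)
        winner = dists.index(best)
        tie = dists.count(best) > 1
        allocations.append(
            Allocation(
                site_index=idx,
                guide_name=guides[winner].name,
                distance=best,
                tie=tie,
            )
        )
    return AllocationResult(allocations=allocations)


#: The six-guide multiplex panel (well-characterised human target sites).
#: Protospacers are 5'->3' with NGG PAMs; HBB-28 is the 18-nt guide against
#: the promoter -28(A>G) allele, reconstructed from the HBB promoter
#: sequence. HBG targets the duplicated HBG1/HBG2 promoter CCAAT region.
MULTIPLEX_GUIDES: List[GuideRNA] = [
    GuideRNA("HEK293-2", "GAACACAAAGCATAGACTGC", "NGG", genomic_pam="GGG"),
    GuideRNA("EMX1", "GAGTCCGAGCAGAAGAAGAA", "NGG", genomic_pam="GGG"),
    GuideRNA("FANCF", "GGAATCCCTTCTGCAGCACC", "NGG", genomic_pam="TGG"),
    GuideRNA("HBB-28", "GACTTCTATGCCCAGCCC", "NGG", (4, 8), genomic_pam="TGG"),
    GuideRNA("RNF2", "GTCATCTTAGTCATTACCTG", "NGG", genomic_pam="AGG"),
    GuideRNA("HBG", "CTTGACCAATAGCCTTGACA", "NGG", genomic_pam="AGG"),
]
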