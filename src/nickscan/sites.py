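"""Site calling, protospacer annotation and site-list comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from .errors import InputError
from .scoring import ScoreTrack

IUPAC: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MERGE_WINDOW = 20   # one protospacer+PAM footprint
DEFAULT_SEARCH_RADIUS = 25  # nick-stagger range plus merge slack


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pam_matches(pattern: str, seq: str) -> bool:
    """IUPAC pattern match (case-insensitive, equal lengths)."""
    if len(pattern) != len(seq):
        return False
    return all(
        base.upper() in IUPAC.get(code.upper(), frozenset())
        for code, base in zip(pattern, seq)
    )


@dataclass(frozen=True)
class GuideRNA:
    """A guide definition: protospacer 5'->3' plus an IUPAC PAM pattern.

    ``deamination_window`` is an inclusive 1-based protospacer position
    range counted from the PAM-distal (5') end. ``genomic_pam`` optionally
    records the concrete PAM at the on-target locus; it is used where a
    literal site string is needed (edit distances), while ``pam`` stays the
    matching pattern.
    """

    name: str
    protospacer: str
    pam: str = "NGG"
    deamination_window: Tuple[int, int] = (4, 8)
    genomic_pam: str | None = None

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam", self.pam.upper())
        if self.genomic_pam is not None:
            object.__setattr__(self, "genomic_pam", self.genomic_pam.upper())
        if not 16 <= len(proto) <= 24:
            raise InputError(
                f"{self.name}: protospacer length {len(proto)} outside 16-24"
            )
        if set(proto) - set("ACGT"):
            raise InputError(f"{self.name}: protospacer not over ACGT")
        if set(self.pam) - set(IUPAC):
            raise InputError(f"{self.name}: PAM {self.pam!r} not IUPAC")
        if self.genomic_pam is not None:
            if set(self.genomic_pam) - set("ACGT"):
                raise InputError(f"{self.name}: genomic PAM not over ACGT")
            if not pam_matches(self.pam, self.genomic_pam):
                raise InputError(
                    f"{self.name}: genomic PAM {self.genomic_pam} does not "
                    f"match pattern {self.pam}"
                )
        lo, hi = self.deamination_window
        if not 1 <= lo <= hi <= len(proto):
            raise InputError(f"{self.name}: deamination window outside protospacer")

    @property
    def site(self) -> str:
        """Protospacer with the concrete PAM appended when known, else the
        PAM pattern (the full target footprint)."""
        return self.protospacer + (self.genomic_pam or self.pam)

    def window_a_offsets(self) -> List[int]:
        """0-based protospacer offsets of A's inside the deamination window."""
        lo, hi = self.deamination_window
        return [o for o in range(lo - 1, hi) if self.protospacer[o] == "A"]


@dataclass(frozen=True)
class CandidateSite:
    """A merged run of above-threshold positions.

    ``pos`` is the maximum-scoring position (leftmost on ties) and
    ``interval`` the half-open span of merged positions.
    """

    chrom: str
    pos: int
    score: float
    interval: Tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not lo <= self.pos < hi:
            raise InputError("representative position outside interval")


@dataclass(frozen=True)
class AnnotatedSite(CandidateSite):
    """A candidate site with its best protospacer+PAM match.

    ``matched_sequence`` is the genomic window in guide orientation
    (protospacer frame 5'->3', PAM last); ``pam_length`` splits it into
    protospacer and PAM parts.
    """

    guide_name: str = ""
    matched_strand: str = "forward"
    matched_sequence: str = ""
    pam_length: int = 3
    mismatches: int = 0
    pam_ok: bool = False
    has_window_A: bool = False

    @property
    def matched_protospacer(self) -> str:
        return self.matched_sequence[: len(self.matched_sequence) - self.pam_length]

    @property
    def matched_pam(self) -> str:
        return self.matched_sequence[len(self.matched_sequence) - self.pam_length:]


def call_sites(
    track: ScoreTrack,
    threshold: float,
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> List[CandidateSite]:
    """Merge above-threshold positions within ``merge_window`` of each other
    into candidate sites, sorted by (chrom, pos)."""
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    if merge_window < 1:
        raise InputError("merge_window must be >= 1")
    sites: List[CandidateSite] = []
    for chrom in sorted(track.scores):
        passing = sorted(
            (p, s) for p, s in track.scores[chrom].items() if s > threshold
        )
        cluster: List[Tuple[int, float]] = []
        for pos, score in passing + [(None, None)]:  # sentinel flush
            if cluster and (pos is None or pos - cluster[-1][0] > merge_window):
                best_score = max(s for _, s in cluster)
                best_pos = min(p for p, s in cluster if s == best_score)
                sites.append(
                    CandidateSite(
                        chrom=chrom,
                        pos=best_pos,
                        score=best_score,
                        interval=(cluster[0][0], cluster[-1][0] + 1),
                    )
                )
                cluster = []
            if pos is not None:
                cluster.append((pos, score))
    return sorted(sites, key=lambda s: (s.chrom, s.pos))


def _window_distance(start: int, length: int, pos: int) -> int:
    """Distance from pos to the centre of window [start, start+length)."""
    return abs(start + length // 2 - pos)


def annotate_site(
    site: CandidateSite,
    reference: Mapping[str, str],
    guide: GuideRNA,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> AnnotatedSite:
    """Find the best protospacer+PAM match near a called site.

    All windows of the target-footprint length on both strands within
    ``search_radius`` of ``site.pos`` are examined. Among PAM-bearing
    windows the one with the fewest protospacer mismatches wins (ties:
    nearest the site, then forward strand). If no window carries the PAM,
    the overall minimum-mismatch window is returned with ``pam_ok=False``.
    """
    if site.chrom not in reference:
        raise InputError(f"reference is missing chromosome {site.chrom!r}")
    chrom_seq = reference[site.chrom]
    chrom_len = len(chrom_seq)
    proto_len = len(guide.protospacer)
    pam_len = len(guide.pam)
    L = proto_len + pam_len

    lo = max(0, site.pos - search_radius)
    hi = min(chrom_len, site.pos + search_radius + 1)
    region = str(chrom_seq[max(0, lo - L): min(chrom_len, hi + L)]).upper()
    region_off = max(0, lo - L)

    # (pam_ok_rank, mismatches, distance, strand_rank, payload)
    best = None
    for start in range(max(0, lo - L + 1), min(hi, chrom_len - L + 1)):
        window = region[start - region_off: start - region_off + L]
        if len(window) < L:
            continue
        for strand in ("forward", "reverse"):
            oriented = window if strand == "forward" else reverse_complement(window)
            proto_part, pam_part = oriented[:proto_len], oriented[proto_len:]
            ok = pam_matches(guide.pam, pam_part)
            mism = sum(a != b for a, b in zip(proto_part, guide.protospacer))
            key = (
                0 if ok else 1,
                mism,
                _window_distance(start, L, site.pos),
                0 if strand == "forward" else 1,
            )
            if best is None or key < best[0]:
                best = (key, strand, oriented, mism, ok)
    if best is None:
        raise InputError(
            f"no window of length {L} within radius {search_radius} of "
            f"{site.chrom}:{site.pos}"
        )
    _, strand, oriented, mism, ok = best
    lo_w, hi_w = guide.deamination_window
    window_part = oriented[lo_w - 1: hi_w]
    return AnnotatedSite(
        chrom=site.chrom,
        pos=site.pos,
        score=site.score,
        interval=site.interval,
        guide_name=guide.name,
        matched_strand=strand,
        matched_sequence=oriented,
        pam_length=pam_len,
        mismatches=mism,
        pam_ok=ok,
        has_window_A="A" in window_part,
    )


def annotate_best_guide(
    site: CandidateSite,
    reference: Mapping[str, str],
    guides: Sequence[GuideRNA],
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> AnnotatedSite:
    """Annotate against every guide and keep the best match
    (PAM-bearing first, then fewest mismatches, then guide order)."""
    if not guides:
        raise InputError("guide list is empty")
    annotated = [annotate_site(site, reference, g, search_radius) for g in guides]
    return min(
        annotated,
        key=lambda a: (0 if a.pam_ok else 1, a.mismatches),
    )


def compare_site_lists(
    a: Sequence[CandidateSite],
    b: Sequence[CandidateSite],
    tolerance: int = 0,
) -> Dict[str, int]:
    """Greedy nearest matching of two site lists.

    Two sites are shared when they lie on the same chromosome within
    ``tolerance`` bp; each site is matched at most once. Returns
    ``{"only_a", "only_b", "shared"}`` with
    only_a + shared == len(a) and only_b + shared == len(b).
    """
    pairs = []
    for i, sa in enumerate(a):
        for j, sb in enumerate(b):
            if sa.chrom == sb.chrom and abs(sa.pos - sb.pos) <= tolerance:
                pairs.append((abs(sa.pos - sb.pos), i, j))
    pairs.sort()
    used_a, used_b = set(), set()
    shared = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    return {"only_a": len(a) - shared, "only_b": len(b) - shared, "shared": shared}


def write_bed(sites: Sequence[AnnotatedSite], path: str) -> None:
    """BED6: chrom, interval, guide name, score, matched strand."""
    with open(path, "w") as out:
        for s in sites:
            strand = "+" if s.matched_strand == "forward" else "-"
            out.write(
                f"{s.chrom}\t{s.interval[0]}\t{s.interval[1]}\t"
                f"{s.guide_name}\t{s.score:.4g}\t{strand}\n"
            )


ANNOTATION_COLUMNS = [
    "chrom", "pos", "score", "interval_start", "interval_end", "guide",
    "strand", "matched_sequence", "pam_length", "mismatches", "pam_ok",
    "has_window_A",
]


def write_annotations(sites: Sequence[AnnotatedSite], path: str) -> None:
    with open(path, "w") as out:
        out.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for s in sites:
            out.write(
                f"{s.chrom}\t{s.pos}\t{s.score:.6g}\t{s.interval[0]}\t"
                f"{s.interval[1]}\t{s.guide_name}\t{s.matched_strand}\t"
                f"{s.matched_sequence}\t{s.pam_length}\t{s.mismatches}\t"
                f"{int(s.pam_ok)}\t{int(s.has_window_A)}\n"
            )


def read_annotations(path: str) -> List[AnnotatedSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            (chrom, pos, score, lo, hi, guide, strand, seq, pam_len,
             mism, pam_ok, has_a) = line.rstrip("\n").split("\t")
            sites.append(
                AnnotatedSite(
                    chrom=chrom, pos=int(pos), score=float(score),
                    interval=(int(lo), int(hi)), guide_name=guide,
                    matched_strand=strand, matched_sequence=seq,
                    pam_length=int(pam_len), mismatches=int(mism),
                    pam_ok=bool(int(pam_ok)), has_window_A=bool(int(has_a)),
                )
            )
    return sites


def read_guides(path: str) -> List[GuideRNA]:
    """Guide table: name, protospacer, [pam], [window_start], [window_end],
    [genomic_pam]."""
    guides = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name, proto = parts[0], parts[1]
            pam = parts[2] if len(parts) > 2 and parts[2] else "NGG"
            window = (
                (int(parts[3]), int(parts[4])) if len(parts) > 4 else (4, 8)
            )
            genomic_pam = parts[5] if len(parts) > 5 and parts[5] else None
            guides.append(GuideRNA(name, proto, pam, window, genomic_pam))
    if not guides:
        raise InputError(f"{path}: no guides found")
    return guides


def write_guides(guides: Sequence[GuideRNA], path: str) -> None:
    with open(path, "w") as out:
        out.write(
            "#name\tprotospacer\tpam\twindow_start\twindow_end\tgenomic_pam\n"
        )
        for g in guides:
            lo, hi = g.deamination_window
            out.write(
                f"{g.name}\t{g.protospacer}\t{g.pam}\t{lo}\t{hi}\t"
                f"{g.genomic_pam or ''}\n"
            )
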