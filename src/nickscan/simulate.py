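"""Nick-geometry read simulator.

Generates a random reference, writes guide target sites (on-target plus
mismatched off-targets) into it, and emits WGS-like reads whose fragment
boundaries carry the staggered-nick signature of a deamination/nicking
cleavage event:

* the edited (protospacer) strand is nicked immediately 3' of the
  deaminated A at 0-based protospacer offset ``o`` — cut coordinate
  ``top_nick = start + o + 1``;
* the opposite strand is nicked 3 bp 5' of the PAM (between protospacer
  positions 17 and 18 of a 20-mer) — cut coordinate
  ``bottom_nick = start + len(protospacer) - 2``.

For a forward-strand site the downstream fragment begins at ``top_nick``
(forward read-start pileup) and the upstream fragment ends just before
``bottom_nick`` (reverse 5'-end pileup at ``bottom_nick - 1``), so the two
pileups are separated by 9-13 bp for deamination-window positions 4-8 —
exactly the alpha window the scorer integrates over. Reverse-strand sites
mirror the geometry.

Both nicks are idealised as flush (blunt-end-repaired) fragment ends, and
a cleavage boundary replaces the random boundary that would otherwise have
fallen inside the fragment. Read errors and quality modelling are out of
scope: the score consumes only coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InputError, PlacementError
from .ingest import ReadSet
from .sites import GuideRNA, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters (defaults emulate ~35x WGS of 400-500 bp
    blunt-repaired fragments read at 150 bp)."""

    genome_length: int = 1_000_000
    gc_content: float = 0.41
    depth: float = 35.0
    fragment_length_mean: float = 450.0
    fragment_length_sd: float = 30.0
    read_length: int = 150
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError("depth must be > 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must be in [0, 1]")
        if self.fragment_length_mean <= self.read_length:
            raise ConfigurationError("fragment mean must exceed read length")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted cleavage event.

    ``protospacer_start`` is the 0-based leftmost genome coordinate of the
    protospacer (forward-strand orientation of the footprint);
    ``edited_A_offset`` the 0-based protospacer offset of the deaminated A;
    ``top_nick``/``bottom_nick`` the cut coordinates (half-open convention:
    a cut at ``c`` falls between bases ``c - 1`` and ``c``) on the edited
    and the opposite strand respectively.
    """

    guide_name: str
    chrom: str
    protospacer_start: int
    strand: str
    mismatches: int
    edited_A_offset: int
    cleavage_fraction: float
    top_nick: int
    bottom_nick: int
    planted_sequence: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.cleavage_fraction <= 1.0:
            raise InputError("cleavage_fraction must be in [0, 1]")

    @property
    def cut_interval(self) -> Tuple[int, int]:
        """(left cut, right cut) in genome coordinates."""
        lo = min(self.top_nick, self.bottom_nick)
        hi = max(self.top_nick, self.bottom_nick)
        return lo, hi

    @property
    def expected_forward_pileup(self) -> int:
        """Genome position where forward read starts accumulate."""
        return self.cut_interval[0]

    @property
    def expected_reverse_pileup(self) -> int:
        """Genome position where reverse 5' ends accumulate."""
        return self.cut_interval[1] - 1


def generate_reference(config: SimConfig) -> str:
    """Random DNA sequence with the configured GC content; deterministic
    for a fixed seed."""
    if config.genome_length < 10_000:
        raise ConfigurationError("genome_length must be at least 10 kb")
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=config.genome_length, p=probs)
    return seq.tobytes().decode("ascii")


def write_fasta(sequence: str, path: str, name: str = "chrS", width: int = 80) -> None:
    with open(path, "w") as out:
        out.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            out.write(sequence[i: i + width] + "\n")


def _concrete_pam(pam_pattern: str, guide: GuideRNA, rng: np.random.Generator) -> str:
    from .sites import IUPAC  # local import avoids cycle at module load

    if guide.genomic_pam is not None:
        return guide.genomic_pam
    return "".join(
        code if code in "ACGT"
        else sorted(IUPAC[code])[rng.integers(len(IUPAC[code]))]
        for code in pam_pattern
    )


def _mutate(proto: str, k: int, protect: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``k`` substitutions, biased PAM-distal, never
    touching the protected (edited A) offset."""
    candidates = [i for i in range(len(proto)) if i != protect]
    # PAM-distal bias: weight decreases linearly toward the PAM end
    weights = np.array([len(proto) - i for i in candidates], dtype=np.float64)
    weights /= weights.sum()
    chosen = rng.choice(len(candidates), size=k, replace=False, p=weights)
    seq = list(proto)
    for ci in chosen:
        i = candidates[ci]
        seq[i] = rng.choice([b for b in "ACGT" if b != proto[i]])
    return "".join(seq)


def _nick_coordinates(
    start: int, proto_len: int, strand: str, edited_offset: int
) -> Tuple[int, int]:
    """Cut coordinates (top = edited strand, bottom = nCas9 strand)."""
    if strand == "forward":
        top = start + edited_offset + 1
        bottom = start + proto_len - 2
    else:
        # mirror image: protospacer 5' end is at start + proto_len - 1
        top = start + proto_len - 1 - edited_offset
        bottom = start + 2
    return top, bottom


def plant_sites(
    reference: str,
    guides: Sequence[GuideRNA],
    n_offtargets_per_guide: int,
    mismatch_range: Tuple[int, int],
    config: SimConfig,
    cleavage_fraction: float = 1.0,
    min_separation: int = 2_000,
    margin: int = 1_000,
) -> Tuple[str, List[PlantedSite]]:
    """Write one on-target and ``n_offtargets_per_guide`` off-target sites
    per guide into the reference; returns the edited sequence and the
    ground-truth registry."""
    rng = np.random.default_rng(config.seed + 1)
    genome = np.frombuffer(reference.upper().encode("ascii"), dtype="S1").copy()
    n_sites = len(guides) * (1 + n_offtargets_per_guide)
    lo_m, hi_m = mismatch_range
    if not 0 <= lo_m <= hi_m:
        raise InputError("invalid mismatch range")

    max_footprint = max(len(g.protospacer) + len(g.pam) for g in guides)
    needed = 2 * margin + n_sites * (min_separation + max_footprint)
    if len(genome) < needed:
        raise PlacementError(
            f"reference of {len(genome)} bp cannot host {n_sites} sites "
            f"with {min_separation} bp separation"
        )

    # evenly spaced slots, jittered, so sites never overlap
    slots = np.linspace(
        margin, len(genome) - margin - max_footprint - 3, n_sites
    ).astype(np.int64)
    jitter = rng.integers(0, max(1, min_separation // 4), size=n_sites)
    positions = (slots + jitter).tolist()
    rng.shuffle(positions)

    registry: List[PlantedSite] = []
    pos_iter = iter(sorted(positions))
    for guide in guides:
        a_offsets = guide.window_a_offsets()
        if not a_offsets:
            raise InputError(
                f"{guide.name}: no A inside the deamination window; cannot "
                "plant a deamination event"
            )
        for k_target in [0] + [
            int(rng.integers(lo_m, hi_m + 1)) for _ in range(n_offtargets_per_guide)
        ]:
            start = next(pos_iter)
            strand = "forward" if rng.random() < 0.5 else "reverse"
            edited_offset = int(rng.choice(a_offsets))
            proto = (
                guide.protospacer
                if k_target == 0
                else _mutate(guide.protospacer, k_target, edited_offset, rng)
            )
            pam = _concrete_pam(guide.pam, guide, rng)
            footprint = proto + pam
            proto_len = len(proto)
            if strand == "forward":
                # protospacer at [start, start+L), PAM just 3' of it
                region = footprint
                region_start = start
                proto_start = start
            else:
                # protospacer on the reverse strand at [start, start+L),
                # PAM occupies [start-3, start)
                region = reverse_complement(footprint)
                region_start = start - len(pam)
                proto_start = start
            genome[region_start: region_start + len(region)] = np.frombuffer(
                region.encode("ascii"), dtype="S1"
            )
            top, bottom = _nick_coordinates(
                proto_start, proto_len, strand, edited_offset
            )
            registry.append(
                PlantedSite(
                    guide_name=guide.name,
                    chrom=config.chrom,
                    protospacer_start=proto_start,
                    strand=strand,
                    mismatches=k_target,
                    edited_A_offset=edited_offset,
                    cleavage_fraction=cleavage_fraction,
                    top_nick=top,
                    bottom_nick=bottom,
                    planted_sequence=footprint,
                )
            )
    return genome.tobytes().decode("ascii"), registry


def _fragments(
    genome_length: int, config: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Random fragment intervals at the configured mean depth.

    Each fragment is read from both ends, so coverage per fragment is
    about ``2 * read_length``.
    """
    n = int(round(config.depth * genome_length / (2 * config.read_length)))
    lengths = rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    lengths = np.clip(lengths, 50, None).astype(np.int64)
    starts = rng.integers(0, np.maximum(1, genome_length - lengths))
    ends = np.minimum(starts + lengths, genome_length)
    return starts, ends


def _split_at_sites(
    starts: np.ndarray,
    ends: np.ndarray,
    sites: Sequence[PlantedSite],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Split a cleavage_fraction of the fragments spanning each planted
    site at that site's two cut coordinates."""
    keep = np.ones(len(starts), dtype=bool)
    extra_starts: List[np.ndarray] = []
    extra_ends: List[np.ndarray] = []
    for site in sites:
        cut_lo, cut_hi = site.cut_interval
        spanning = (starts < cut_lo) & (ends > cut_hi) & keep
        if site.cleavage_fraction < 1.0:
            spanning &= rng.random(len(starts)) < site.cleavage_fraction
        if not spanning.any():
            continue
        keep &= ~spanning
        # upstream piece ends at the right cut, downstream piece starts at
        # the left cut (fill-in of the 5' overhang duplicates the stagger)
        extra_starts.append(starts[spanning])
        extra_ends.append(np.full(spanning.sum(), cut_hi, dtype=np.int64))
        extra_starts.append(np.full(spanning.sum(), cut_lo, dtype=np.int64))
        extra_ends.append(ends[spanning])
    if not extra_starts:
        return starts, ends
    return (
        np.concatenate([starts[keep]] + extra_starts),
        np.concatenate([ends[keep]] + extra_ends),
    )


def simulate_reads(
    genome_length: int,
    sites: Sequence[PlantedSite],
    config: SimConfig,
) -> ReadSet:
    """Fragment the genome, split at planted sites, and read both fragment
    ends at ``read_length``. Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed + 2)
    starts, ends = _fragments(genome_length, config, rng)
    starts, ends = _split_at_sites(starts, ends, sites, rng)
    rl = config.read_length
    fwd_starts = starts
    fwd_ends = np.minimum(starts + rl, ends)
    rev_starts = np.maximum(ends - rl, starts)
    rev_ends = ends
    return ReadSet(
        chrom=config.chrom,
        starts=np.concatenate([fwd_starts, rev_starts]),
        ends=np.concatenate([fwd_ends, rev_ends]),
        is_reverse=np.concatenate(
            [np.zeros(len(starts), dtype=bool), np.ones(len(starts), dtype=bool)]
        ),
    )


def plant_and_simulate(
    reference: str,
    guides: Sequence[GuideRNA],
    n_offtargets_per_guide: int,
    mismatch_range: Tuple[int, int],
    config: SimConfig,
    cleavage_fraction: float = 1.0,
) -> Tuple[str, ReadSet, List[PlantedSite]]:
    """Full synthetic run: plant sites, fragment, read.

    Returns the edited reference, the reads and the ground-truth registry.
    """
    edited, registry = plant_sites(
        reference,
        guides,
        n_offtargets_per_guide,
        mismatch_range,
        config,
        cleavage_fraction=cleavage_fraction,
    )
    reads = simulate_reads(len(edited), registry, config)
    return edited, reads, registry


def mix_datasets(
    treated: ReadSet,
    untreated: ReadSet,
    dilution_factor: float,
    seed: int = 0,
) -> ReadSet:
    """Emulate diluting treated DNA with untreated DNA.

    The output has the same total read count as ``treated``, with a
    ``1/dilution_factor`` proportion subsampled (without replacement) from
    the treated pool and the remainder from the untreated pool.
    """
    if dilution_factor < 1:
        raise InputError("dilution_factor must be >= 1")
    if treated.chrom != untreated.chrom:
        raise InputError("treated and untreated reads on different chromosomes")
    total = len(treated)
    n_treated = int(round(total / dilution_factor))
    n_untreated = total - n_treated
    if n_untreated > len(untreated):
        raise InputError(
            f"untreated pool too small: need {n_untreated}, have {len(untreated)}"
        )
    rng = np.random.default_rng(seed)
    pick_t = rng.choice(total, size=n_treated, replace=False)
    pick_u = rng.choice(len(untreated), size=n_untreated, replace=False)
    return ReadSet(
        chrom=treated.chrom,
        starts=np.concatenate([treated.starts[pick_t], untreated.starts[pick_u]]),
        ends=np.concatenate([treated.ends[pick_t], untreated.ends[pick_u]]),
        is_reverse=np.concatenate(
            [treated.is_reverse[pick_t], untreated.is_reverse[pick_u]]
        ),
    )


def write_sam(reads: ReadSet, reference: str, path: str) -> None:
    """Plain-text SAM with a proper header; sequences are taken from the
    reference (uniform high quality, no error model)."""
    order = np.lexsort((reads.is_reverse, reads.ends, reads.starts))
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        out.write(f"@SQ\tSN:{reads.chrom}\tLN:{len(reference)}\n")
        out.write("@PG\tID:nickscan\tPN:nickscan\n")
        for n, i in enumerate(order.tolist()):
            start = int(reads.starts[i])
            end = int(reads.ends[i])
            flag = 16 if reads.is_reverse[i] else 0
            seq = reference[start:end].upper()
            out.write(
                f"read{n}\t{flag}\t{reads.chrom}\t{start + 1}\t60\t"
                f"{end - start}M\t*\t0\t0\t{seq}\t*\n"
            )


def write_registry(registry: Sequence[PlantedSite], path: str) -> None:
    with open(path, "w") as out:
        out.write(
            "#guide\tchrom\tprotospacer_start\tstrand\tmismatches\t"
            "edited_A_offset\tcleavage_fraction\ttop_nick\tbottom_nick\t"
            "planted_sequence\n"
        )
        for s in registry:
            out.write(
                f"{s.guide_name}\t{s.chrom}\t{s.protospacer_start}\t{s.strand}"
                f"\t{s.mismatches}\t{s.edited_A_offset}\t{s.cleavage_fraction}"
                f"\t{s.top_nick}\t{s.bottom_nick}\t{s.planted_sequence}\n"
            )


def read_registry(path: str) -> List[PlantedSite]:
    registry = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            (guide, chrom, start, strand, mism, offset, cf, top, bottom,
             seq) = line.rstrip("\n").split("\t")
            registry.append(
                PlantedSite(
                    guide_name=guide, chrom=chrom, protospacer_start=int(start),
                    strand=strand, mismatches=int(mism),
                    edited_A_offset=int(offset), cleavage_fraction=float(cf),
                    top_nick=int(top), bottom_nick=int(bottom),
                    planted_sequence=seq,
                )
            )
    return registry


def write_manifest(path: str, **entries) -> None:
    """Run manifest: parameters, seeds and package version as JSON."""
    from . import __version__

    payload = {"nickscan_version": __version__}
    for key, value in entries.items():
        if isinstance(value, SimConfig):
            payload[key] = asdict(value)
        else:
            payload[key] = value
    with open(path, "w") as out:
        json.dump(payload, out, indent=2, sort_keys=True)
        out.write("\n")
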