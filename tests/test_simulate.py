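import numpy as np
import pytest

from nickscan import (
    CandidateSite,
    GuideRNA,
    SimConfig,
    annotate_site,
    call_sites,
    generate_reference,
    load_alignments,
    mix_datasets,
    plant_and_simulate,
    score_genome,
    tally_positions,
)
from nickscan.errors import ConfigurationError, InputError, PlacementError
from nickscan.ingest import chrom_lengths_from_header
from nickscan.simulate import (
    plant_sites,
    read_registry,
    simulate_reads,
    write_fasta,
    write_registry,
    write_sam,
)


class TestGenerateReference:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(genome_length=20_000, seed=5)
        assert generate_reference(cfg) == generate_reference(cfg)

    def test_different_seed_differs(self):
        a = generate_reference(SimConfig(genome_length=20_000, seed=5))
        b = generate_reference(SimConfig(genome_length=20_000, seed=6))
        assert a != b

    def test_gc_content_concentrates(self):
        cfg = SimConfig(genome_length=1_000_000, gc_content=0.5, seed=1)
        seq = generate_reference(cfg)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_tiny_genome_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_reference(SimConfig(genome_length=10))

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimConfig(depth=0)
        with pytest.raises(ConfigurationError):
            SimConfig(fragment_length_mean=100.0, read_length=150)
        with pytest.raises(ConfigurationError):
            SimConfig(gc_content=1.5)


class TestPlantSites:
    def test_registry_geometry_invariants(self, small_reference, small_config,
                                          twenty_mer_guides):
        _, registry = plant_sites(
            small_reference, twenty_mer_guides, 2, (1, 3), small_config
        )
        for s in registry:
            L = len(s.planted_sequence) - 3
            assert 3 <= s.edited_A_offset <= 7  # 0-based window 4-8
            if s.strand == "forward":
                assert s.top_nick == s.protospacer_start + s.edited_A_offset + 1
                assert s.bottom_nick == s.protospacer_start + L - 2
            else:
                assert s.top_nick == s.protospacer_start + L - 1 - s.edited_A_offset
                assert s.bottom_nick == s.protospacer_start + 2
            # read-level separation (forward pileup at the left cut,
            # reverse 5' ends at the base before the right cut) spans the
            # scorer's alpha window for deamination-window positions 4-8
            sep = s.expected_reverse_pileup - s.expected_forward_pileup
            assert 9 <= sep <= 13
            # the planted protospacer keeps an A at the edited offset
            assert s.planted_sequence[s.edited_A_offset] == "A"

    def test_planted_sequences_written_into_reference(
        self, small_reference, small_config, twenty_mer_guides
    ):
        from nickscan.sites import reverse_complement

        edited, registry = plant_sites(
            small_reference, twenty_mer_guides, 1, (1, 2), small_config
        )
        for s in registry:
            L = len(s.planted_sequence) - 3
            if s.strand == "forward":
                span = edited[s.protospacer_start: s.protospacer_start + L + 3]
                assert span == s.planted_sequence
            else:
                span = edited[s.protospacer_start - 3: s.protospacer_start + L]
                assert span == reverse_complement(s.planted_sequence)

    def test_mismatch_counts_recovered_by_annotation(
        self, small_reference, small_config, twenty_mer_guides
    ):
        edited, registry = plant_sites(
            small_reference, twenty_mer_guides, 3, (1, 3), small_config
        )
        ref = {small_config.chrom: edited}
        by_name = {g.name: g for g in twenty_mer_guides}
        for s in registry:
            site = CandidateSite(
                s.chrom, s.cut_interval[0], 9.0,
                (s.cut_interval[0], s.cut_interval[0] + 1),
            )
            ann = annotate_site(site, ref, by_name[s.guide_name])
            assert ann.mismatches == s.mismatches
            assert ann.matched_strand == s.strand
            assert ann.pam_ok is True
            assert ann.has_window_A is True

    def test_guide_without_window_a_rejected(self, small_reference, small_config):
        guide = GuideRNA("noA", "GGGTTGGGGGGGGGGGGGGG")
        with pytest.raises(InputError):
            plant_sites(small_reference, [guide], 1, (1, 2), small_config)

    def test_overcrowded_reference_rejected(self, small_config, twenty_mer_guides):
        tiny = generate_reference(SimConfig(genome_length=10_000, seed=0))
        with pytest.raises(PlacementError):
            plant_sites(tiny, twenty_mer_guides, 10, (1, 3), small_config)


class TestSimulateReads:
    def test_deterministic_reads_and_sam(self, tmp_path, small_reference,
                                         small_config, twenty_mer_guides):
        runs = []
        for _ in range(2):
            edited, reads, _ = plant_and_simulate(
                small_reference, twenty_mer_guides[:1], 1, (1, 2), small_config
            )
            path = tmp_path / f"run{len(runs)}.sam"
            write_sam(reads, edited, str(path))
            runs.append(path.read_bytes())
        assert runs[0] == runs[1]

    def test_mean_depth_within_five_percent(self):
        cfg = SimConfig(genome_length=1_000_000, depth=35.0, seed=2)
        reads = simulate_reads(cfg.genome_length, [], cfg)
        counts = tally_positions(reads, {cfg.chrom: cfg.genome_length})
        assert abs(counts.D[cfg.chrom].mean() - 35.0) / 35.0 < 0.05

    def test_null_model_scores_nothing(self):
        # cleavage_fraction 0: read starts are uniform; nothing clears 0.1
        cfg = SimConfig(genome_length=1_000_000, depth=35.0, seed=3)
        ref = generate_reference(cfg)
        guides = [GuideRNA("g", "GAACACAAAGCATAGACTGC")]
        _, reads, _ = plant_and_simulate(
            ref, guides, 2, (1, 3), cfg, cleavage_fraction=0.0
        )
        counts = tally_positions(reads, {cfg.chrom: cfg.genome_length})
        track = score_genome(counts)
        assert call_sites(track, 0.1) == []

    def test_pileups_at_planted_nicks(self, small_reference, small_config,
                                      twenty_mer_guides):
        edited, reads, registry = plant_and_simulate(
            small_reference, twenty_mer_guides[:2], 0, (0, 0), small_config,
            cleavage_fraction=1.0,
        )
        counts = tally_positions(reads, {small_config.chrom: len(edited)})
        F = counts.F[small_config.chrom]
        R = counts.R[small_config.chrom]
        for s in registry:
            f_pos = s.expected_forward_pileup
            r_pos = s.expected_reverse_pileup
            assert 9 <= r_pos - f_pos <= 13
            # dozens of fragments span each site at 35x: strong pileups
            assert F[f_pos] >= 10
            assert R[r_pos] >= 10

    def test_sam_round_trip_reproduces_counts(self, tmp_path, small_reference,
                                              small_config, twenty_mer_guides):
        edited, reads, _ = plant_and_simulate(
            small_reference, twenty_mer_guides[:1], 1, (1, 2), small_config
        )
        lengths = {small_config.chrom: len(edited)}
        direct = tally_positions(reads, lengths)
        path = tmp_path / "reads.sam"
        write_sam(reads, edited, str(path))
        assert chrom_lengths_from_header(str(path)) == lengths
        from_sam = tally_positions(load_alignments(str(path)), lengths)
        assert from_sam == direct

    def test_score_monotone_in_cleavage_fraction(self):
        # median planted-site score is non-decreasing as more molecules cleave
        cfg = SimConfig(genome_length=100_000, depth=35.0, seed=19)
        ref = generate_reference(cfg)
        guides = [GuideRNA("g", "GAACACAAAGCATAGACTGC")]
        medians = []
        for cf in (0.1, 0.4, 0.7, 1.0):
            _, reads, registry = plant_and_simulate(
                ref, guides, 3, (1, 2), cfg, cleavage_fraction=cf
            )
            counts = tally_positions(reads, {cfg.chrom: cfg.genome_length})
            track = score_genome(counts)
            site_scores = []
            for s in registry:
                lo, hi = s.cut_interval
                best = max(
                    (
                        track.get(cfg.chrom, p)
                        for p in range(lo - 25, hi + 25)
                    ),
                    default=0.0,
                )
                site_scores.append(best)
            medians.append(float(np.median(site_scores)))
        assert medians == sorted(medians)


class TestMixDatasets:
    @staticmethod
    def _pools(seed=23):
        cfg = SimConfig(genome_length=50_000, depth=20.0, seed=seed)
        ref = generate_reference(cfg)
        guides = [GuideRNA("g", "GAACACAAAGCATAGACTGC")]
        _, treated, _ = plant_and_simulate(ref, guides, 0, (0, 0), cfg, 1.0)
        cfg_u = SimConfig(genome_length=50_000, depth=20.0, seed=seed + 100)
        untreated = simulate_reads(cfg_u.genome_length, [], cfg_u)
        return treated, untreated

    def test_factor_one_returns_treated_up_to_order(self):
        treated, untreated = self._pools()
        mixed = mix_datasets(treated, untreated, 1.0, seed=0)
        assert len(mixed) == len(treated)
        key = lambda rs: sorted(
            zip(rs.starts.tolist(), rs.ends.tolist(), rs.is_reverse.tolist())
        )
        assert key(mixed) == key(treated)

    def test_factor_2_5_keeps_forty_percent_treated(self):
        treated, untreated = self._pools()
        mixed = mix_datasets(treated, untreated, 2.5, seed=1)
        assert len(mixed) == len(treated)
        n_treated = int(round(len(treated) / 2.5))
        assert n_treated / len(treated) == pytest.approx(0.4, abs=1e-3)
        # the first n_treated entries come from the treated pool by
        # construction; verify multiset containment instead of order
        treated_keys = set(
            zip(treated.starts.tolist(), treated.ends.tolist(),
                treated.is_reverse.tolist())
        )
        mixed_keys = list(
            zip(mixed.starts.tolist(), mixed.ends.tolist(),
                mixed.is_reverse.tolist())
        )
        from_treated = sum(k in treated_keys for k in mixed_keys[:n_treated])
        assert from_treated == n_treated

    def test_untreated_pool_too_small_rejected(self):
        treated, untreated = self._pools()
        tiny = mix_datasets(untreated, untreated, 1.0, seed=0)
        tiny = type(tiny)(
            chrom=tiny.chrom, starts=tiny.starts[:10], ends=tiny.ends[:10],
            is_reverse=tiny.is_reverse[:10],
        )
        with pytest.raises(InputError):
            mix_datasets(treated, tiny, 10.0, seed=0)

    def test_dilution_below_one_rejected(self):
        treated, untreated = self._pools()
        with pytest.raises(InputError):
            mix_datasets(treated, untreated, 0.5)


def test_registry_round_trip(tmp_path, small_reference, small_config,
                             twenty_mer_guides):
    _, registry = plant_sites(
        small_reference, twenty_mer_guides, 2, (1, 3), small_config,
        cleavage_fraction=0.7,
    )
    path = tmp_path / "truth.tsv"
    write_registry(registry, str(path))
    assert read_registry(str(path)) == registry


def test_fasta_writer_wraps_lines(tmp_path):
    path = tmp_path / "ref.fa"
    write_fasta("ACGT" * 50, str(path), name="chrT", width=80)
    lines = path.read_text().strip().split("\n")
    assert lines[0] == ">chrT"
    assert all(len(line) <= 80 for line in lines[1:])
    assert "".join(lines[1:]) == "ACGT" * 50
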