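# nickscan

Genome-wide detection of base-editor cleavage signatures from read
alignments. When in-vitro deaminated, endonuclease-nicked genomic DNA is
fragmented, end-repaired and sequenced, the two staggered strand nicks of
each cleavage event leave coincident read 5'/3' ends. `nickscan` reduces a
SAM/BAM to per-position depth and read-start counts, scores every position
for that staggered-end signature, calls and annotates candidate on/off-target
sites, assigns multiplex-captured sites to guide RNAs by Levenshtein
distance, and summarises captured-site motifs. A nick-geometry read
simulator generates references, planted cleavage events and WGS-like reads
so the whole pipeline is testable without external data.

## Library overview

| module | contents |
| --- | --- |
| `nickscan.ingest` | `load_alignments`, `tally_positions` → per-position `D`/`F`/`R` counts (0-based half-open everywhere) |
| `nickscan.scoring` | `ScoringParams`, `cleavage_score`, `score_genome` → sparse `ScoreTrack` |
| `nickscan.sites` | `GuideRNA`, `call_sites`, `annotate_site`, `compare_site_lists` |
| `nickscan.allocator` | `levenshtein`, `build_distance_matrix`, `allocate_sites`, the bundled `MULTIPLEX_GUIDES` panel |
| `nickscan.simulate` | `SimConfig`, `generate_reference`, `plant_and_simulate`, `mix_datasets`, SAM/FASTA/registry writers |
| `nickscan.report` | `position_frequency_matrix`, `conversion_frequency` |

## CLI

Each command writes a JSON manifest next to its primary output; any flag
may come from a YAML file via `--config`. A full synthetic run:

```sh
nickscan simulate --guides guides.tsv --genome-length 1000000 --depth 35 \
    --seed 7 --cleavage-fraction 0.7 --outdir run/
nickscan tally --sam run/reads.sam --out run/counts.tsv
nickscan score --counts run/counts.tsv --out run/scores.tsv
nickscan call --scores run/scores.tsv --threshold 2.5 --out run/sites.tsv
nickscan annotate --sites run/sites.tsv --reference run/reference.fa \
    --guides guides.tsv --out run/annotated.tsv --bed run/sites.bed
nickscan allocate --sites run/annotated.tsv --guides guides.tsv \
    --out run/allocation.tsv --matrix-out run/matrix.tsv
nickscan compare --a run/sites.tsv --b other/sites.tsv --tolerance 25
nickscan report --sites run/annotated.tsv --pfm-out run/pfm.tsv
```

`guides.tsv` columns: name, protospacer (5'→3'), PAM pattern (IUPAC,
default NGG), deamination-window start/end (1-based from the PAM-distal
end, default 4–8), optional concrete genomic PAM.

## Scoring model

For each position `i` the score sums two five-term windows over
`alpha = 1..5`:

```
sum_a (F_i-1)/D_i * (R_{i+8+a}-1)/D_i * (F_i + R_{i+8+a} - 2)
+ sum_a (R_{i+11}-1)/D_{i+11} * (F_{i-3+a}-1)/D_{i-3+a} * (R_{i+11} + F_{i-3+a} - 2)
```

Zero-denominator terms contribute 0; by default terms whose start counts
fall below `min_start_reads=2` are clamped to 0 as well (a lone read end is
noise and the raw algebra would produce negative evidence).
`paired_depth_denominator` switches the first window's second divisor from
`D_i` to `D_{i+8+a}`.

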