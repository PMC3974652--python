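# mirnome

A miRNA discovery and regulation-analysis toolkit: de-novo and
homology-based pre-miRNA prediction, bootstrap endpoint calling from
tiling-array fluorescence, spike-in quantification, read-coverage
confidence classification, and anti-correlation-filtered tissue-specific
miRNA–mRNA regulatory networks — exercised end-to-end on synthetic data
with planted ground truth.

## Modules

| module | purpose |
| --- | --- |
| `mirnome.synthetic_data` | generators for every pipeline input (genome with planted hairpins and tRNA/CDS-like decoys, foreign-species reference precursors, tiling fluorescence with planted endpoint peaks and spike-ins, small-RNA reads, tissue expression matrices with planted anti-correlated pairs and lincRNA sponges) |
| `mirnome.homology_scan` | conserved-precursor detection by local alignment (≥50% precursor similarity + gap-free exact 6-nt seed), per-species conservation, distance correlation |
| `mirnome.hairpin_discovery` | sliding-window fold-back scan (pluggable engine; built-in self-reverse-complement stem aligner), canonical filters (54 < len < 217, ΔG < −27, ≤2 loops of 3–30 nt), 32-dim triplet features, seeded probabilistic classifier (accept at p > 0.998), structure-only cleavage-site surrogate |
| `mirnome.rake_peaks` | leave-one-out bootstrap endpoint probabilities (10,000 resamples), replicate-consensus calling (0.75×4 for 3′, 0.65×3 for 5′, relaxed 0.58 tier), mature/isomiR reconstruction with underscore IDs, spike-in log-log calibration and below-detection flagging, spike-anchored normalization |
| `mirnome.confidence_classify` | read filtering (≤2 mismatches, ≤3 alignments, drop non-miRNA mappers), per-nt coverage, high (≥10) / medium (≥3) / low labels |
| `mirnome.target_networks` | seed-site target prediction (6mer/7mer-1A/7mer-m8/8mer, UTR-end exclusion), Pearson anti-correlation filter, bipartite permissive/repressive tissue networks with modules, tissue clustering with resampling support, 5p/3p arm ratios, hypergeometric family enrichment, sponge detection, quantile normalization |

## CLI

All stages are exposed as subcommands of `mirnome` (see `--help` on
each): `simulate`, `conserved-scan`, `scan`, `filter`, `train`,
`classify`, `call-ends`, `quantify`, `classify-confidence`,
`predict-targets`, `filter-targets`, `build-network`, `cluster`,
`enrich`.

A typical synthetic round trip:

```sh
mirnome simulate --seed 3 --out sim/
mirnome conserved-scan --reference sim/reference.fa \
    --annotation sim/reference_annotation.tsv \
    --genome sim/genome.fa --out hits.tsv
mirnome scan --genome sim/genome.fa --out candidates.tsv
mirnome filter --candidates candidates.tsv --out filtered.tsv
mirnome call-ends --tiling sim/tiling_3p.tsv --assay 3p-assay \
    --seed 1 --out calls.tsv
mirnome predict-targets --matures sim/matures.fa --utrs utrs.fa \
    --out sites.tsv
```

`simulate` accepts a `key=value` config file (`--config`) overriding any
`SimulationConfig` field; every randomized command takes `--seed`.

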