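# oligoband

A toolkit for **oligo-banding karyotyping**: design panels of fluorescent
oligo FISH probes that paint a distinctive multi-colour band pattern on each
chromosome, optimize the six-colour scheme for maximal between-chromosome
distinctness, analyse banding signatures of traced chromosomes to call
chromosomal rearrangements with genomic breakpoint intervals, and model 2:2
meiotic segregation for sperm-head FISH — with a synthetic-data simulator so
the whole pipeline is testable without a microscope.

## Modules

| module | what it does |
| --- | --- |
| `oligoband.panel_design` | select probe windows (runs of 3000 candidate 39mers) per chromosome under density / spacing / termini rules; densest-1500 subgroup picking; fluorophore alternation for paired colours; Table-style panel summaries |
| `oligoband.oligo_assembly` | simplified 39mer mining from soft-masked FASTA; nearest-neighbour dimer ΔG (37 °C) for orthogonal 20mer selection (−9 kcal/mol threshold, GC-clamp role attribution); 79 nt / 99 nt oligo layouts; order-sheet TSV export with T7-prefixed reverse primers |
| `oligoband.colour_scheme` | six-colour token alphabet (3 fluorophores singly or in pairs), token-level Levenshtein distance, random-scheme generation and best-of-N optimization (maximize min pairwise distance, then sum) |
| `oligoband.signature_analysis` | intensity-profile extraction along traced paths, robust band calling (two-pass background estimate, cross-channel fusion, sub-resolution merging), signature matching in both orientations, split-decomposition translocation / insertion calling, breakpoint mapping to inter-probe intervals, spread-level majority voting, G-band nomenclature formatting |
| `oligoband.rearrangement_model` | karyotypes at band granularity, reciprocal / non-reciprocal translocations and insertions, derivative-chromosome patterns, exhaustive 2:2 quadrivalent segregation (alternate / adjacent-I / adjacent-II), sperm-head signal-multiset classification |
| `oligoband.synthetic_data` | Poisson candidate tables, multi-channel band profiles, metaphase-spread images with traces, sperm-head signal fields — all with ground truth and bit-reproducible per seed |
| `oligoband.fixtures` | bundled pig-like reference data: chromosome sizes, per-chromosome panel statistics and probe counts, deterministic demo panel + colour scheme, named demo rearrangements (`rcp3-6`, `add10`, `rcp1-7`, `rcp12-14`, `t3-9`) |
| `oligoband.cli` | the `oligoband` command wiring everything together |

## CLI

```bash
# probe design from a candidate 39mer BED
oligoband design --candidates cand.bed --genome-sizes sizes.tsv \
    --probes-per-chrom counts.tsv --min-gap 8000000 --margin 6000000 --out design/

# colour scheme (1000 random candidates, Levenshtein-optimal)
oligoband colours --panel design/panel.tsv --n 1000 --seed 17 --out scheme.json

# synthesis-ready oligos and order sheets
oligoband oligos --fasta genome.fa --panel design/panel.tsv \
    --scheme scheme.json --layout 79nt --out oligos/

# synthetic data (demo recipes on the bundled pig-like fixture)
oligoband simulate spread --demo rcp3-6 --seed 1 --out sim/
oligoband simulate profile --demo add10 --seed 1 --out sim_profiles/
oligoband simulate sperm --demo rcp3-6 --n-heads 1000 --out sperm/

# analysis: traced chromosomes -> signatures -> matches -> calls
oligoband analyze --image sim/spread.tif --traces sim/traces.tsv \
    --scheme scheme.json --panel design/panel.tsv --out report/

# 2:2 segregation gamete classes of a demo reciprocal translocation
oligoband segregate --demo rcp3-6 --out seg/
```

Every run writes an `effective_config.json` snapshot next to its outputs;
identical config + seed gives byte-identical TSV/JSON outputs.

## Conventions

- Coordinates are 0-based half-open throughout; BED is native.
- Interprobe distance is measured end-of-previous to start-of-next probe;
  overall panel statistics are unweighted means across chromosomes with
  sample (n−1) standard deviations.
- Breakpoints live in inter-band gaps: gap index `k` means between band `k`
  and band `k+1` (0 = before the first band, n = after the last).
  Terminal-gap breaks are flagged "reciprocity undetermined".
- Distance from chromosome termini uses the probe's nearest edge
  (first-probe start / chromosome end minus last-probe end).
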