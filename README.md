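# rmscan

Comparative-genomics toolkit for finding **solitary restriction
endonucleases (REs)** and predicting **separated restriction–modification
(R-M) systems** in annotated prokaryotic genomes.

Given per-genome annotations of R-M-related genes (RE / MTase / S-subunit,
with R-M type and pseudo-gene status), protein sequences, and optionally
replicon nucleotide sequences, the pipeline:

1. classifies annotated R-M systems as *complete* (≥1 intact RE **and** ≥1
   intact MTase) or *incomplete*;
2. calls an RE **solitary** when no non-corrupted MTase gene or MTase-like
   ORF (six-frame, stop-to-stop, searched against a user-supplied MTase
   reference set at E < 0.01) lies within 4 kb of the gene;
3. flags solitary REs that are **probably truncated** — shorter by ≥20% than
   any homolog (aa identity > 20%) among complete-system REs;
4. finds RE and MTase **orthologs by best bidirectional hits** (REs: >40%
   identity over 80% of the longer sequence; MTases: >50%/80%) and groups
   them by single linkage;
5. transfers a partner MTase to each solitary RE through orthologous
   complete systems; a recovered RE–MTase pair >4 kb apart (or on different
   replicons) is a **separated R-M system**;
6. assigns each solitary RE exactly one class: `probably_truncated`,
   `no_orthologs`, `separated_system_member`, `corrupted_mtase_nearby`, or
   `no_paired_mtase` (fixed precedence, so per-class counts always sum to
   the solitary total);
7. screens solitary REs against methyl-directed (Type IIM/IV) REs —
   similarity search at E < 0.001, single-linkage clustering at >40%
   identity over 60% of each sequence, progressive alignment, neighbor
   joining, bootstrap — and reports mixed clusters without reclassifying;
8. scans 20 kb around the genes of separated systems for mobile-genetic-
   element annotations (transposases, integrases, IS elements, phage genes).

Pairwise similarity uses an internal Smith–Waterman-style aligner (BLOSUM62,
affine gaps 11/1, Karlin–Altschul-style E-values) that approximates a BLASTp
search; tabular output of an external search tool can be adapted instead
(`rmscan.align.read_tabular_hits`).

A fully deterministic **synthetic cohort generator** (`rmscan.synth`) plants
every scenario — ordinary complete systems, separated systems with or
without ortholog support, truncated REs, frameshifted/pseudo MTases, lone
REs, Type IV decoys, nearby mobile elements — with ground-truth labels, so
the entire pipeline is testable without any external downloads.

## Command line

```sh
# generate a synthetic cohort with planted ground truth
rmscan simulate --out cohort/ --seed 1 --n-genomes 20 \
    --separated 5 --truncated 3 --corrupted 3 --lone 2

# run the full pipeline (detect -> truncation -> orthology -> separated ->
# screen -> neighborhood -> reports)
rmscan run --in cohort/ --out results/

# stage-focused views over the same analysis
rmscan detect    --in cohort/ --out results/
rmscan orthology --in cohort/ --out results/
rmscan separated --in cohort/ --out results/
rmscan screen    --in cohort/ --out results/
rmscan report    --in cohort/ --out results/   # per-class counts as JSON
```

An input directory holds `annotation.tsv` (or GFF3; see
`rmscan/io.py` for the documented dialects), `proteins.fasta` (keyed by
gene id), optionally `replicons.fasta` (without it the vicinity scan runs
annotation-only) and `mtase_refs.fasta` (the MTase domain reference set).
Thresholds can be overridden with a YAML config (`--config`); defaults are
the published parameters (4 kb / 20 kb windows, 40/80 and 50/80 orthology,
20/20 truncation, 40/60 clustering, E 0.01 / 0.001).

The output bundle contains per-type class summaries (`table1.*`), per-RE
classifications, putative/separated systems with provenance, ortholog pairs
and groups, group summaries (`table2.tsv`), screen clusters with Newick
trees and bootstrap supports, MGE hits and a `summary.json` + manifest.
Runs are byte-identical for a fixed seed and configuration.

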