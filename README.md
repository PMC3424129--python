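# estssr

A toolkit for mining microsatellites (SSRs) in assembled transcriptome
contigs and designing unique SSR-targeting PCR markers.

It covers the full desk workflow:

- **sequence_io** — FASTA reading/writing, masked-region trimming
  (longest unmasked run), length filtering, mask-aware GC content.
- **ssr_miner** — detection of maximal perfect tandem repeats of
  primitive 2–6 bp units (default minima 6/5/4/3/3 repeats for di
  through hexa), compound-record merging within a configurable
  interruption distance, canonical motif classes (closed under rotation
  and reverse complement), frequency/density summaries, MISA-style TSV
  and GFF3 output.
- **orf_annotator** — coding-region coordinates from user tables
  (TSV/GFF3) or a six-frame longest-ORF stand-in, and classification of
  each SSR as 5'UTR / coding / 3'UTR / undetermined.
- **clustering** — greedy representative-based clustering (identity of
  the shorter sequence against the longer, DP-defined) and single-linkage
  clustering under a local-alignment identity/coverage rule.
- **primer_design** — exhaustive SSR-flanking primer-pair enumeration
  under explicit length/Tm/GC/product/homopolymer/dimer constraints with
  deterministic penalty ranking.
- **insilico_pcr** — amplicon prediction with an exact 3'-anchor rule,
  single-product triage across the whole template collection,
  shortest-product-per-cluster marker selection, known-marker exclusion
  by local alignment score, and the end-to-end pipeline driver.
- **ssr_stats** — motif-by-location summary tables with printed-style
  percentages, binomial/Poisson GLMs with Wald z tests, marker diversity
  indices (Na/Ho/He/PIC), one-sided Fisher enrichment with BH
  adjustment, Welch's t, Spearman/Pearson correlation, and repeat-count
  polymorphism forecasts.
- **synth_fixtures** — seeded generators for contigs with planted SSRs /
  CDS intervals / primer sites and simulated marker outcome tables, plus
  a packaged motif-by-location count table.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (repeat enumeration, binding-site
scanning, hypergeometric tails, six-frame ORF search) and property
tests; `tests/test_acceptance.py` holds the end-to-end acceptance
criteria.

## Command line

```sh
estssr mine contigs.fasta --out outdir            # MISA-style TSV + GFF3
estssr classify contigs.fasta cds.tsv --out outdir
estssr design contigs.fasta --out outdir          # primer pairs per SSR
estssr markers contigs.fasta --known known.fasta --out outdir
estssr stats --table2 --out outdir
estssr synth --n 10 --seed 7 --unit AT --repeats 8 --out outdir
```

Every command echoes its effective configuration to
`<outdir>/run_config.json`; validation errors exit with status 2.

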