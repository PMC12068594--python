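# regconverge

Reusable pipeline for promoter-centred regulatory analysis and
cross-species comparison of transcription-factor binding profiles:

- **`regconverge.promoters`** — GFF3/FASTA parsing and strand-aware
  promoter-window extraction (default 2 kb upstream to 1 kb downstream of
  each transcript's TSS, per-isoform), plus a strict assembly-quality gate
  (scaffold N50 > 500 kb, scaffolds < 30,000).
- **`regconverge.motifs`** — PWM loading (JASPAR and MEME-minimal
  dialects), log-odds scanning of both strands, *exact* background
  p-values by dynamic programming over discretized scores,
  Benjamini–Hochberg FDR over the full family of scored windows, and a
  TF × gene binding-strength matrix of FDR-passing hit counts with an
  annotated-gene mask.
- **`regconverge.expression`** — TPM, upper-quartile normalization,
  expressed-gene filter (mean TPM > 1), strict DEG filter
  (|log2FC| > 1 and padj < 0.05), gene-set intersections, a clearly
  labeled moderated-t differential-expression stand-in (external DEG
  tables are first-class inputs), a shifted-log stand-in transform, and
  Ward.D2 hierarchical clustering.
- **`regconverge.sexchrom`** — per-chromosome DEG ratios, an exact /
  Monte-Carlo label-permutation test of sex-chromosome vs autosome
  enrichment, and dosage-effect classification of Z-linked DEGs
  (1 < |log2FC| ≤ 1.5 dosage band; > 2 strong male bias).
- **`regconverge.convergence`** — Pearson correlation of binding-strength
  matrices across species over cells annotated in both, patristic
  distances on a Newick phylogeny, and a convergence report that flags
  non-sister pairs whose similarity exceeds every sister pair's.
- **`regconverge.qpcr`** — standard-curve amplification factors
  (E = 10^(−1/slope)), efficiency percentages, and Pfaffl expression
  ratios.
- **`regconverge.synthetic`** — deterministic generators for genomes,
  annotations, planted motif copies, negative-binomial count matrices
  with planted fold changes, and Brownian-evolved species sets with a
  planted convergent pair, each returning a machine-readable truth log
  for closed-loop testing.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (scan vs
brute-force oracle, DP p-values vs exhaustive enumeration, planted-motif
recovery, promoter coordinate fixtures, filter-chain oracles, permutation
calibration, DE and convergence recovery, Pfaffl closed forms).

## CLI

```sh
regconverge promoters --genome genome.fa --gff genes.gff3 \
    --upstream 2000 --downstream 1000 --out promoters.fa
regconverge scan --promoters promoters.fa --motifs tfs.jaspar \
    --fdr 0.05 --out hits.tsv --matrix-out binding
regconverge express --counts counts.tsv --out expressed.tsv
regconverge deg --deg-table deseq_output.tsv --out degs.tsv
regconverge cluster --matrix transformed.tsv -k 9 --out clusters.json
regconverge sexchrom --degs degs.tsv --universe genes.tsv \
    --n-perm 10000 --seed 1 --out-prefix sex
regconverge converge --reference taeniopygia_guttata --tree finches.nwk \
    --matrices matrices/ --phenotypes pheno.tsv --out convergence.json
regconverge pfaffl --standards std.tsv --ct ct.tsv --reference GAPDH \
    --control ctrl --treated trt --out ratios.tsv
regconverge run --config run.yaml     # staged run from a flat YAML config
regconverge demo --out demo_out --seed 1   # fully synthetic end-to-end run
```

The demo writes every stage's outputs plus `manifest.json` with
parameters, the seed, and SHA-256 checksums; identical configs reproduce
identical checksums.

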