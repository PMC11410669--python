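# germdrop

Tools for droplet single-cell RNA-seq of germinating plant embryos:
two-genotype SNP/UMI demultiplexing, protoplast-dissociation artifact
correction, the QC → clustering → marker workflow, and bulk-signature
identity scoring — with a synthetic-data generator that provides ground
truth for every step.

## The problem

Single-cell RNA-seq of plant tissue requires protoplasting (enzymatic
removal of cell walls), which itself perturbs the transcriptome, and early
germination time points yield transcriptionally quiescent cells that are
hard to tell from ambient background. A two-ecotype spike-in design solves
the second problem: real single cells carry SNPs from one genotype only,
while doublets and background carry a mixture. A paired bulk experiment
(whole embryos vs protoplasts) solves the first: genes responding to
dissociation are identified and excluded downstream.

`germdrop` implements that full computational path for anyone analysing
(or simulating) such a design:

- **Demultiplexing** — per-barcode allele-informative UMI counts
  (n_A, n_B) embedded as (log10(n_A+1), log10(n_B+1)) and classified by
  two-stage DBSCAN: a coarse pass (ε_background) isolates the low-count
  background cloud, a finer pass (ε_margin) resolves the two singlet arms
  and the balanced doublet cloud via each cluster's mean allele balance
  f = n_A/(n_A+n_B) with margin δ.
- **Bulk DE engine** — per-gene negative-binomial GLMs
  (var = μ + φμ², log link) with TMM normalization, Cox–Reid adjusted
  profile-likelihood dispersion (common + tagwise with a 10-df prior), and
  likelihood-ratio tests. Dissociation-responsive genes: `~time +
  protoplast` vs `~time` at FDR < 1% and |log2FC| ≥ 1.5. Per-interval time
  effects (FDR < 5%, |log2FC| ≥ 1.5) feed a discordance statistic — the
  percentage of genes moving in opposite directions in the two arms — and
  time-vs-rest contrasts with a unique-time filter yield per-time-point
  gene signatures.
- **Cell pipeline** — 3-MAD QC on log10 counts and genes detected,
  library-size normalization, positive-biological-variance HVG selection
  against a LOWESS mean–variance trend, PCA, shared-nearest-neighbour
  graph (Jaccard weights), Louvain clustering, and Wilcoxon rank-sum
  markers at p < 0.01.
- **Scoring** — per-cell module scores against 25 expression-matched
  control bins (100 controls per signature gene), and a pseudobulk-vs-bulk
  Pearson-correlation audit with and without the dissociation-responsive
  gene set.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Simulate a small experiment (1,500 cells + 800 empty droplets, two
genotypes, 60 dissociation-responsive genes), then run the whole path:

```bash
cat > cfg.json <<'EOF'
{"n_genes": 1000, "n_cells": 1500, "n_empty": 800, "n_protoplast_genes": 60}
EOF
germdrop simulate --config cfg.json --out sim --seed 42
germdrop demux --allele-obs sim/allele_observations.tsv --out calls.tsv \
    --truth sim/droplet_truth.tsv --metrics demux_metrics.json
germdrop protoplast-de --counts sim/bulk_counts.tsv --samples sim/samplesheet.tsv \
    --out de.tsv --gene-set proto_genes.txt
germdrop discordance --counts sim/bulk_counts.tsv --samples sim/samplesheet.tsv --out disc.json
germdrop signatures --counts sim/bulk_counts.tsv --samples sim/samplesheet.tsv --out sigs.json
germdrop cluster --mtx sim/mtx --calls calls.tsv --keep GENO_A --seed 42 --out clu
germdrop audit --mtx sim/mtx --cell-meta sim/cell_metadata.tsv \
    --bulk sim/bulk_counts.tsv --samples sim/samplesheet.tsv \
    --exclude proto_genes.txt --out audit.json
```

which prints:

```
simulated 2300 droplets and 18 bulk samples
called 2285 barcodes
60 genes called at FDR 0.01, |log2FC| >= 1.5
12-24: 0.00%; 24-48: 0.00%
12 h: 76 genes; 24 h: 61 genes; 48 h: 75 genes
3 clusters over 722 cells (modularity 0.664)
                 r_all  r_excluded     delta
time_point_h
12            0.788812    0.860347  0.071535
24            0.738706    0.812069  0.073363
48            0.605706    0.672286  0.066580
```

Reading the output: all 60 simulated dissociation-responsive genes are
recovered at FDR 1% (`proto_genes.txt` matches the generator's truth set
exactly); the temporal dynamics of the whole-tissue and protoplast arms
are fully concordant (0% discordance per interval); the time-signature
step yields disjoint per-time gene lists; the genotype-A cells cluster
into the three simulated states; and excluding the dissociation-responsive
genes raises the pseudobulk-vs-bulk correlation at every time point
(e.g. 0.79 → 0.86 at 12 h) — the protoplast correction doing its job.
`demux_metrics.json` reports singlet balanced accuracy, doublet recall and
background recall (all 1.0 here) against the simulation truth.

Every subcommand is byte-deterministic given its inputs and `--seed`.

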