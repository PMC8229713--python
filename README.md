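# tworect

Pathway-guided **two-way rectification** of differentially-expressed-gene
(DEG) lists for two-group transcriptomics experiments.

## The problem

Small designs (often 3 vs 3 replicates) make per-gene DEG statistics
noisy: fold-change ranking is inflated by low-abundance genes, and
t-type statistics are unstable with four residual degrees of freedom.
But genuine expression changes are not scattered at random — they
concentrate in a few cellular functions.  `tworect` exploits that
co-function structure to *rectify* any initial ranked gene list.

## The algorithm

Let `L` be a gene list ranked by a differential score, and take its top
`n` genes as the candidate set `DEGs-i1`.  Each round `i` then:

1. **genes → pathways** — test `DEGs-i1` for pathway over-representation
   (one-sided hypergeometric within a background universe, BH-corrected)
   and keep the significant pathways `Pathways-i`;
2. **pathways → genes** — let `U` be the candidates annotated in at
   least one significant pathway (candidates outside every significant
   pathway are discarded as isolated), and `C` the remaining measured
   pathway genes ranked by their score in `L`.  Admit the top

       |D| = ⌊ m · |C \ U| ⌋

   genes of `C` and set `DEGs-i2 = U ∪ D`.

Iteration proceeds while the list stays within `N_g`, an upper bound of
15% of the measured genes (the plausible ceiling on the DEG fraction),
or until a fixed point, no significant pathway, or a round limit.  The
expansion factor `m` is kept small (0.05–0.1) so only genes strongly
tied to the implicated functions enter.

Also included: the baseline scorers that seed `L` (|log2 fold change|,
pooled two-sample t, and an empirical-Bayes moderated t whose per-gene
variances are shrunk toward a method-of-moments prior), and the two
validation instruments — ROC/AUC against known truth and the
largest-connected-component ratio of the DEG set on a protein-protein
interaction (PPI) network.

## Worked example

A fully synthetic study (2000 genes, 3 vs 3, five active pathways with
113 planted true DEGs, a planted PPI module) exercises the whole
pipeline:

```sh
tworect simulate --preset default --seed 1 --n-genes 2000 --out-dir demo
tworect score --expr demo/expression.tsv --control c1,c2,c3 \
        --test t1,t2,t3 --method modt --out demo/ranked.tsv
tworect run --ranked demo/ranked.tsv --gmt demo/pathways.gmt \
        -n 50 -m 0.1 --out demo/degs.txt --report demo/report.json
tworect eval roc --ranking demo/ranked.tsv --truth demo/truth.txt
tworect eval connectivity --network demo/ppi.tsv --degs demo/degs.txt
```

prints

```
study with 2000 genes, 113 true DEGs written to demo
wrote 2000 ranked genes to demo/ranked.tsv
76 DEGs after 24 rounds (stop: fixed_point)
AUC = 0.845698 (113 positives, 1887 negatives)
LCC 53 / 76 DEGs (ratio 0.6974)
```

The moderated-t ranking alone reaches AUC 0.845698 on this study;
re-ranking with the rectified set first (`tworect.method_ranking`)
raises it to 0.886860, and the 76 rectified genes sit in one dominant
PPI component (ratio 0.70) where an equal-sized top-scoring baseline
set is far more fragmented.  A sensitivity grid over `(n, m)` is
available via `tworect grid`, and `tworect --help` lists all
subcommands (`score`, `enrich`, `run`, `grid`, `eval`, `simulate`).

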