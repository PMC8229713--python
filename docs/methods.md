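# Methods

## The rectification model and its assumptions

The method assumes that true differential expression concentrates in a
small number of cellular functions, and that a pathway annotation (a
KEGG-style gene-set collection) covers those functions well enough that
membership is informative.  Under that assumption, a candidate gene
supported only by its marginal statistic but by no enriched function is
more likely a false positive, while an unselected gene that is both
annotated in an enriched function and carries a decent marginal score
is a likely false negative.  Each round removes the former (`DEGs-i1 \ U`)
and admits a bounded number of the latter (`D`).

The loop is *not* guaranteed to recover all truth: genes outside the
annotation universe can never be selected, and a pathway whose members
never reach significance contributes nothing.  The method is a
re-ranking prior, not a test; no error rate is controlled for the final
set.

## Enrichment details

One-sided hypergeometric (Fisher exact, "greater") over-representation.
The background universe defaults to *measured ∩ annotated* genes —
genes no pathway could contain are excluded so they do not dilute the
test — and is switchable to all measured genes or an explicit list.
Query genes outside the universe are dropped (logged).  Only pathways
with at least one query hit yield a record; Benjamini–Hochberg runs
across those records, and the significance cut (`alpha`, default 0.05
on the adjusted p, `min_overlap` ≥ 2) can be switched to raw p-values,
which published pathway tables often report.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 50 | initial list size; sensible range 20–80 |
| `m` | 0.1 | expansion factor per round, in (0, 1]; ⌊m·\|C\|⌋ genes admitted |
| `alpha` | 0.05 | pathway significance threshold (BH-adjusted by default) |
| `ng_fraction` | 0.15 | size bound N_g as a fraction of measured genes |
| `min_overlap` | 2 | minimum query∩pathway overlap for significance |
| `max_rounds` | 50 | hard iteration cap |

`N_g = max(1, ⌊ng_fraction · #measured genes⌋)`.  The loop returns the
last list within `N_g`; stop reasons are `ng_bound`, `fixed_point`,
`no_significant_pathways` and `max_rounds`.  The driver keeps the full
per-round trace, and identical inputs give byte-identical serialised
results.

### Orderings and tie-breaks

`L` is ordered by the ranking statistic descending, ties by larger
|log2 fold change|, then gene id.  `U` keeps `L`'s order.  `C` is
ordered by score descending with ties broken by the number of
significant-pathway memberships (more first), then gene id.  The
expansion count uses the set difference first (`⌊m·|C\U|⌋`); since `C`
excludes current candidates by construction this equals `⌊m·|C|⌋`, and
flooring keeps expansion conservative (a round can prune without
expanding).

## Scorers

*Fold change*: `log_fc = mean(test) − mean(control)` on the log2 scale;
statistic `|log_fc|`; 1.0 equals the conventional 2-fold cut.

*Ordinary t*: pooled-variance two-sample t, two-sided p on
`n1 + n2 − 2` df.

*Moderated t*: per-gene variance `s_g²` (d residual df) is shrunk to
`s̃_g² = (d0·s0² + d·s_g²)/(d0 + d)` and tested on `d0 + d` df.  The
hyperparameters are fitted by the method of moments on `log s_g²`: with
`e_g = log s_g² − ψ(d/2) + log(d/2)`, solve
`ψ′(d0/2) = var(e) − ψ′(d/2)` for `d0` (Newton on the trigamma
inverse) and set `s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))`; if the
excess variance is non-positive, `d0 = ∞` and every gene gets `s0²`.
Zero-variance genes are excluded from the fit.  The implementation
reproduces Bioconductor limma's `eBayes` hyperparameters and t
statistics to 1e-10 on a frozen fixture (see `tests/test_scoring.py`).

*Degenerate genes*: a gene whose (possibly shrunk) variance is exactly
zero gets statistic +∞ and p = 0 (or t = 0, p = 1 when the means are
also equal) and a `degenerate` flag, so it sorts first but can be
excluded downstream.  Spike-in data contain flat genes; silently
dropping them would change list sizes.

## Evaluation

`roc_curve` sweeps the ranking prefix with tied scores collapsed into a
single threshold step; the trapezoidal AUC then equals the Mann–Whitney
pair-counting probability with ties counted one half.  A set-valued
rectification result is linearised for ROC by `method_ranking`: members
first (by initial score), then the rest (by initial score), with dense
rank scores so ties are preserved.  This block ordering is a
convention — the loop itself produces a set, not a ranking.

`connectivity` reports the largest connected component of the
DEG-induced PPI subgraph over the number of DEGs; genes absent from the
network count as isolated vertices.  `min_degree_filter` applies
iterative removal of low-degree vertices until stable (the k-core of
the induced subgraph); when it is used, the connectivity denominator
deliberately stays at the pre-pruning DEG count so curves at different
thresholds share a scale.

## The synthetic-study generator

`generate_study` draws, from one seeded NumPy generator: baseline log2
abundances uniform on mean ± spread (8 ± 4); per-gene Gaussian noise
whose sd scales linearly from 2.5× the nominal `noise_sd` for the
least-abundant gene down to 0.5× for the most abundant — reproducing
the abundance-linked fold-change trap; 30 pathways of 20–60 members
sampled uniformly (overlaps arise naturally); truth as a fraction
(0.6) of the members of the first 5 pathways, shifted ±1.0 log2 units
in the test group with random sign; optional unannotated decoy DEGs;
and a PPI network with edge probability 0.3 inside the truth module and
0.002 elsewhere, scores uniform on [0.4, 1].  Defaults model a 3-vs-3
microarray-scale experiment with ~5% true DEGs.

What it does **not** model: probe-level artefacts, batch effects,
correlated noise between genes, mean–variance relationships beyond the
monotone sd ramp, and annotation bias (every truth gene is annotated
by construction).  Passing tests therefore show the machinery behaves
as specified under the assumed structure, not that the method wins on
any particular real dataset.

`worked_fixture` is a noiseless 10-gene, 2-pathway, 3-vs-3 study whose
single rectification round (n = 4, m = 0.5, raw p < 0.2) is derived
entirely by hand in the test suite: the unannotated large-fold-change
gene g09 is pruned and the annotated g04 admitted.  With sets this
small the minimum attainable hypergeometric p is C(5,3)/C(8,3) ≈ 0.18,
so the demonstration threshold is necessarily permissive.

## Known limitations and observed behaviour

* The list size is **not** theoretically monotone in `n`: a larger
  current list leaves a smaller expansion pool `C`, so trajectories
  started higher grow more slowly and can be overtaken in later rounds;
  empirically the proportionality in `n` and `m` holds over the first
  ~8 rounds on the standard study at a permissive threshold, and the
  acceptance checks verify it there (on some generator seeds crossings
  appear earlier).
* On null data (no planted truth) the loop usually stops immediately
  with no significant pathway, but a spuriously enriched pathway can
  self-reinforce; the `N_g` bound and `max_rounds` cap the damage, not
  the error rate.
* Enrichment p-values across rounds are reused descriptively; no
  correction is applied across rounds.
* Benchmark problem sizes (2000-gene studies, 20 replicate seeds,
  400-gene fuzzing studies) are the package's own choice of a scale at
  which the Monte-Carlo comparisons are stable and quick to rerun.
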