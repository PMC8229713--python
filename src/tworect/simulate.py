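"""Self-contained synthetic studies for testing and benchmarking.

``generate_study`` emulates the statistical structure the rectification
method assumes in a small two-group transcriptomics experiment:

* a k-vs-k replicate design (3 vs 3 by default, the typical size of the
  animal experiments the method targets);
* a minority of true DEGs concentrated in a few "active" pathways, so the
  truth carries the co-function signal the method exploits;
* uneven baseline abundance with noise that grows as abundance falls, the
  mechanism by which low-expressed genes inflate fold changes and seed
  false positives;
* a protein-interaction network with a dense module among the true DEGs
  on top of a sparse background, so connectivity evaluation has a planted
  signal.

Everything is drawn from a single integer-seeded NumPy generator in a
fixed order, so a study is exactly reproducible from its parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import (CONTROL, TEST, ExpressionMatrix, GeneSetCollection,
                 InteractionNetwork)


@dataclass
class StudyParams:
    """Full generator configuration; regenerating from it is exact."""

    n_genes: int = 2000
    n_replicates: int = 3
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (20, 60)
    n_active_pathways: int = 5
    active_fraction: float = 0.6
    effect_size_log2: float = 1.0
    noise_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_abundance_spread: float = 4.0
    ppi_within_prob: float = 0.3
    ppi_background_prob: float = 0.002
    n_decoy_degs: int = 0
    seed: int = 0


@dataclass
class SyntheticStudy:
    expression: ExpressionMatrix
    truth: set[str]
    effect_signs: dict[str, int]
    pathways: GeneSetCollection
    network: InteractionNetwork
    params: StudyParams

    def params_dict(self) -> dict:
        d = asdict(self.params)
        d["pathway_size_range"] = list(d["pathway_size_range"])
        return d


def _validate(p: StudyParams) -> None:
    if p.n_genes < 10:
        raise ConfigurationError("n_genes must be >= 10")
    if p.n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    lo, hi = p.pathway_size_range
    if not 1 <= lo <= hi:
        raise ConfigurationError("invalid pathway_size_range")
    if hi > p.n_genes:
        raise ConfigurationError("pathways cannot exceed the gene count")
    if p.n_active_pathways > p.n_pathways:
        raise ConfigurationError("n_active_pathways exceeds n_pathways")
    if not 0 <= p.active_fraction <= 1:
        raise ConfigurationError("active_fraction must lie in [0, 1]")
    if p.n_active_pathways > 0 and p.active_fraction * lo < 1:
        raise ConfigurationError(
            "active_fraction x smallest pathway < 1: no active pathway "
            "could contain a true DEG")
    for prob in (p.ppi_within_prob, p.ppi_background_prob):
        if not 0 <= prob <= 1:
            raise ConfigurationError("PPI probabilities must lie in [0, 1]")
    if p.noise_sd <= 0 or p.effect_size_log2 < 0:
        raise ConfigurationError("noise_sd must be > 0 and effect >= 0")


def generate_study(**kwargs) -> SyntheticStudy:
    """Generate a complete synthetic study (see module docstring).

    Keyword arguments override :class:`StudyParams` defaults.  The
    abundance-linked noise gives the least-abundant gene ~2.5x and the
    most-abundant ~0.5x the nominal ``noise_sd``.
    """
    params = StudyParams(**kwargs)
    _validate(params)
    rng = np.random.default_rng(params.seed)
    width = len(str(params.n_genes))
    genes = np.array([f"g{i + 1:0{width}d}" for i in range(params.n_genes)])

    # baseline abundance and abundance-linked noise
    baseline = rng.uniform(params.baseline_mean - params.baseline_abundance_spread,
                           params.baseline_mean + params.baseline_abundance_spread,
                           size=params.n_genes)
    rank_frac = (np.argsort(np.argsort(baseline))) / max(params.n_genes - 1, 1)
    sd = params.noise_sd * (0.5 + 2.0 * (1.0 - rank_frac))

    # pathways: membership sampled uniformly, so overlaps occur naturally
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    members: list[np.ndarray] = []
    lo, hi = params.pathway_size_range
    for j in range(params.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(params.n_genes, size=size, replace=False)
        members.append(idx)
        sets[f"P{j + 1:03d}"] = (f"pathway {j + 1}", frozenset(genes[idx]))
    pathways = GeneSetCollection(sets=sets)

    # truth: a fraction of each active pathway's members, plus decoys
    truth_idx: set[int] = set()
    for j in range(params.n_active_pathways):
        size = len(members[j])
        n_act = max(1, int(round(params.active_fraction * size)))
        chosen = rng.choice(members[j], size=n_act, replace=False)
        truth_idx |= set(int(i) for i in chosen)
    if params.n_decoy_degs:
        annotated = set(int(i) for m in members for i in m)
        free = np.array(sorted(set(range(params.n_genes)) - annotated))
        if len(free) < params.n_decoy_degs:
            raise ConfigurationError("not enough unannotated genes for decoys")
        truth_idx |= set(int(i) for i in
                         rng.choice(free, size=params.n_decoy_degs, replace=False))
    truth_order = np.array(sorted(truth_idx), dtype=int)
    signs = rng.choice([-1, 1], size=len(truth_order))
    effect = np.zeros(params.n_genes)
    effect[truth_order] = signs * params.effect_size_log2
    truth = set(genes[truth_order])
    effect_signs = {genes[i]: int(s) for i, s in zip(truth_order, signs)}

    # expression: control then test replicates
    k = params.n_replicates
    noise = rng.normal(0.0, 1.0, size=(params.n_genes, 2 * k)) * sd[:, None]
    values = baseline[:, None] + noise
    values[:, k:] += effect[:, None]
    samples = [f"c{j + 1}" for j in range(k)] + [f"t{j + 1}" for j in range(k)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                            columns=samples),
        group_labels=pd.Series([CONTROL] * k + [TEST] * k, index=samples),
    )

    # PPI: dense module among true DEGs over a sparse background
    iu, ju = np.triu_indices(params.n_genes, k=1)
    in_truth = np.zeros(params.n_genes, dtype=bool)
    in_truth[truth_order] = True
    p_edge = np.where(in_truth[iu] & in_truth[ju],
                      params.ppi_within_prob, params.ppi_background_prob)
    keep = rng.random(len(p_edge)) < p_edge
    scores = rng.uniform(0.4, 1.0, size=int(keep.sum()))
    g = nx.Graph()
    g.add_nodes_from(genes[np.unique(np.concatenate([iu[keep], ju[keep]]))]
                     if keep.any() else [])
    g.add_weighted_edges_from(
        zip(genes[iu[keep]], genes[ju[keep]], scores), weight="score")
    network = InteractionNetwork(graph=g)

    return SyntheticStudy(expression=expr, truth=truth,
                          effect_signs=effect_signs, pathways=pathways,
                          network=network, params=params)


# ---------------------------------------------------------------------------
# The hand-traceable worked fixture
# ---------------------------------------------------------------------------

# log2 fold changes (test - control) and baseline abundances of the 10
# genes.  g9 is the deliberate trap: a low-abundance gene with a large
# fold change but no pathway annotation, so a round of rectification
# prunes it while admitting the annotated g4.
_WORKED_LFC = {
    "g01": 4.0, "g02": 3.0, "g03": 2.5, "g04": 2.0, "g05": 1.5,
    "g06": 1.0, "g07": 0.5, "g08": 0.25, "g09": 3.5, "g10": 0.0,
}
_WORKED_BASE = {
    "g01": 7.0, "g02": 6.0, "g03": 8.0, "g04": 5.0, "g05": 9.0,
    "g06": 4.0, "g07": 10.0, "g08": 6.5, "g09": 3.0, "g10": 5.5,
}
_WORKED_PATHWAYS = {
    "P1": ("pathway one", frozenset({"g01", "g02", "g03", "g04", "g05"})),
    "P2": ("pathway two", frozenset({"g04", "g05", "g06", "g07", "g08"})),
}
_WORKED_EDGES = [
    ("g01", "g02", 0.9), ("g01", "g03", 0.8), ("g02", "g03", 0.7),
    ("g03", "g04", 0.6), ("g05", "g06", 0.5),
]


def worked_fixture() -> SyntheticStudy:
    """The deterministic 10-gene, 2-pathway, 3-vs-3 toy study.

    Expression is noiseless: every control replicate equals the baseline
    and every test replicate equals baseline + log2 fold change, so all
    per-gene quantities are exact hand arithmetic.  Truth is the five
    annotated genes with a fold change of at least 1.5 log2 units.
    """
    genes = sorted(_WORKED_LFC)
    samples = ["c1", "c2", "c3", "t1", "t2", "t3"]
    rows = [[_WORKED_BASE[g]] * 3 + [_WORKED_BASE[g] + _WORKED_LFC[g]] * 3
            for g in genes]
    expr = ExpressionMatrix(
        values=pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                            columns=samples),
        group_labels=pd.Series([CONTROL] * 3 + [TEST] * 3, index=samples),
    )
    truth = {g for g in genes
             if _WORKED_LFC[g] >= 1.5 and g != "g09"}
    signs = {g: 1 for g in truth}
    g = nx.Graph()
    g.add_weighted_edges_from(_WORKED_EDGES, weight="score")
    params = StudyParams(n_genes=10, n_replicates=3, n_pathways=2,
                         pathway_size_range=(5, 5), n_active_pathways=1,
                         active_fraction=1.0, effect_size_log2=0.0,
                         noise_sd=1e-9, seed=0)
    return SyntheticStudy(
        expression=expr, truth=truth, effect_signs=signs,
        pathways=GeneSetCollection(sets=dict(_WORKED_PATHWAYS)),
        network=InteractionNetwork(graph=g), params=params)
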