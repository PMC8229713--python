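"""Validation instruments: ROC/AUC against known truth, PPI connectivity.

Two complementary checks of a DEG-selection method:

* With spike-in style ground truth, the full gene ranking a method induces
  is swept to produce a ROC curve (TPR over the true DEGs vs FPR over the
  rest) and its AUC.
* Without truth, the coherence of a DEG set is measured on a protein-
  protein interaction network: the size of the largest connected component
  of the DEG-induced subgraph, divided by the number of DEGs.  A set of
  functionally related genes forms one large module; a set of isolated
  statistical artefacts does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .exceptions import ConfigurationError, DomainError
from .io import InteractionNetwork, RankedGeneList
from .rectify import RectificationResult


@dataclass
class RocResult:
    """A ROC curve with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positives: int
    negatives: int


@dataclass
class ConnectivityReport:
    deg_count: int
    lcc_size: int

    @property
    def ratio(self) -> float:
        return self.lcc_size / self.deg_count


def method_ranking(result: RectificationResult | RankedGeneList,
                   all_genes: Sequence[str]) -> RankedGeneList:
    """Turn a method's output into a full ranking over ``all_genes``.

    A plain ranked list passes through (checked for coverage).  A
    rectification result, being set-valued, is linearised as: members of
    ``final_degs`` first, ordered by their initial differential score,
    then every remaining gene by initial score.  Scores are re-coded as
    dense descending ranks so that genes tied on (membership, initial
    score) stay tied — the tie structure the ROC sweep sees.
    """
    all_genes = list(all_genes)
    if isinstance(result, RankedGeneList):
        missing = [g for g in all_genes if g not in result]
        if missing or len(result) != len(all_genes):
            raise ConfigurationError("ranking does not cover all_genes exactly")
        return result

    ranked = result.ranked
    missing = [g for g in all_genes if g not in ranked]
    if missing:
        raise ConfigurationError(
            f"no initial score for genes: {missing[:5]}")
    members = result.final_degs
    order = sorted(all_genes,
                   key=lambda g: (g not in members, -ranked.score_of(g), g))
    keys = [(g in members, ranked.score_of(g)) for g in order]
    scores = np.empty(len(order), dtype=float)
    rank = len(order)
    for i, key in enumerate(keys):
        if i > 0 and key != keys[i - 1]:
            rank -= 1
        scores[i] = rank
    return RankedGeneList(genes=order, scores=scores)


def roc_curve(ranking: RankedGeneList, truth: Iterable[str]) -> RocResult:
    """Sweep the ranking prefix; tied scores form a single threshold step.

    TPR = true positives / |truth|; FPR = false positives / (total -
    |truth|).  The stored curve starts at (0, 0), ends at (1, 1), and the
    AUC is its trapezoidal integral (equal to the Mann-Whitney
    probability of ranking a positive above a negative, counting ties as
    half).
    """
    truth = set(truth)
    genes = ranking.genes
    pos_total = len(truth & set(genes))
    neg_total = len(genes) - pos_total
    if pos_total == 0 or neg_total == 0:
        raise DomainError("truth must be a non-empty proper subset of the ranking")

    y = np.fromiter((g in truth for g in genes), dtype=bool, count=len(genes))
    scores = ranking.scores
    # last index of each tied score group (scores are non-increasing);
    # equality comparison (not diff) so tied infinities stay one group
    boundary = np.nonzero(scores[1:] != scores[:-1])[0]
    idx = np.concatenate([boundary, [len(genes) - 1]])
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(~y)[idx]
    tpr = np.concatenate([[0.0], tp / pos_total])
    fpr = np.concatenate([[0.0], fp / neg_total])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc,
                     positives=pos_total, negatives=neg_total)


def _induced_graph(network: InteractionNetwork, degs: set[str]) -> nx.Graph:
    """Induced subgraph on degs; genes absent from the network are isolated."""
    h = nx.Graph()
    h.add_nodes_from(degs)
    h.add_edges_from((u, v) for u, v in network.graph.edges(degs & network.nodes)
                     if u in degs and v in degs)
    return h


def connectivity(network: InteractionNetwork,
                 degs: Iterable[str]) -> ConnectivityReport:
    """Largest-connected-component ratio of the DEG-induced subgraph."""
    degs = set(degs)
    if not degs:
        raise ConfigurationError("degs must be non-empty")
    h = _induced_graph(network, degs)
    lcc = max((len(c) for c in nx.connected_components(h)), default=0)
    return ConnectivityReport(deg_count=len(degs), lcc_size=lcc)


def min_degree_filter(network: InteractionNetwork, degs: Iterable[str],
                      min_degree: int = 0) -> set[str]:
    """Iteratively drop induced-subgraph vertices of degree < min_degree.

    Removal is repeated until stable (the k-core of the induced subgraph
    with k = min_degree); min_degree = 0 is the identity.
    """
    degs = set(degs)
    if min_degree < 0:
        raise ConfigurationError("min_degree must be >= 0")
    if min_degree == 0:
        return degs
    h = _induced_graph(network, degs)
    return set(nx.k_core(h, k=min_degree).nodes)
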