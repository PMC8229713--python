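"""Hypergeometric over-representation analysis with BH correction.

The enrichment test behind every rectification round is the classical
one-sided hypergeometric (Fisher exact, "greater") test of overlap between
a query gene list and each pathway, within a background universe.  For a
universe of N genes of which K belong to the pathway, and a query of n
genes of which k hit the pathway, the p-value is P(X >= k) for
X ~ Hypergeom(N, K, n).

The background universe is a modelling choice: by convention it is the
intersection of the measured genes with the union of all pathway
annotations, so that genes no pathway could ever contain do not dilute the
test; passing all measured genes instead is supported.

Multiple testing is handled by Benjamini-Hochberg across the tested
pathways; the raw p-values are kept alongside so either can drive the
significance cut.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DomainError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["pathway_id", "name", "k", "K", "n", "N",
                      "p_value", "adjusted_p", "genes"]


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): at-least-k overlap.

    N is the universe size, K the pathway size within the universe, n the
    query size within the universe, k the observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DomainError(f"require 0 <= k <= min(K, n); got k={k}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query: Iterable[str], sets: GeneSetCollection,
           universe: Iterable[str]) -> pd.DataFrame:
    """Test every pathway for over-representation of the query.

    Query genes outside the universe are dropped (with a logged count);
    k, K and n are all computed after intersecting with the universe.
    Only pathways with at least one query hit produce a record; BH runs
    across those records.  Records are sorted by (p_value, pathway_id).
    """
    if len(sets) == 0:
        raise ConfigurationError("empty gene-set collection")
    universe = frozenset(universe)
    if not universe:
        raise ConfigurationError("empty universe")
    query = set(query)
    dropped = len(query - universe)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    q = query & universe
    n, N = len(q), len(universe)

    records = []
    for pid, (name, genes) in sets.sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        overlap = q & in_universe
        k = len(overlap)
        if k < 1:
            continue
        records.append({
            "pathway_id": pid,
            "name": name,
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "p_value": hypergeometric_pvalue(k, K, n, N),
            "genes": frozenset(overlap),
        })
    table = pd.DataFrame(records, columns=[c for c in ENRICHMENT_COLUMNS
                                           if c != "adjusted_p"])
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "pathway_id"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        table["adjusted_p"] = pd.Series(dtype=float)
    return table[ENRICHMENT_COLUMNS]


def significant_pathways(table: pd.DataFrame, alpha: float = 0.05,
                         min_overlap: int = 2,
                         use_adjusted: bool = True) -> pd.DataFrame:
    """Filter an enrichment table down to the significant pathways.

    Keeps records with (adjusted or raw) p below ``alpha`` and overlap
    ``k >= min_overlap``.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must lie in (0, 1]")
    col = "adjusted_p" if use_adjusted else "p_value"
    if len(table) == 0:
        return table
    keep = (table[col] < alpha) & (table["k"] >= min_overlap)
    return table[keep].reset_index(drop=True)


def annotated_genes(table: pd.DataFrame, sets: GeneSetCollection,
                    universe: Iterable[str]) -> set[str]:
    """Union of the full member sets of the table's pathways, in-universe."""
    universe = frozenset(universe)
    out: set[str] = set()
    for pid in table["pathway_id"]:
        out |= sets.genes_of(pid) & universe
    return out
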