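"""The two-way rectification loop.

Starting from the top ``n`` genes of a ranked candidate list ``L``, each
round alternates two directions of rectification:

1. *genes -> pathways*: the current list ``DEGs-i1`` is tested for pathway
   over-representation and the significant pathways ``Pathways-i`` kept;
2. *pathways -> genes*: the list is rewritten from those pathways' full
   annotation.  ``U`` is the subset of ``DEGs-i1`` annotated in at least
   one significant pathway (genes outside every significant pathway are
   discarded as isolated); ``C`` is the remaining annotated, measured
   genes ranked by their differential score; the top

       |D| = floor(m * |C \\ U|)

   genes of ``C`` are admitted, and the next list is ``DEGs-i2 = U ∪ D``.

The expansion factor ``m`` is kept small so each round admits only genes
strongly tied to the functions already implicated.  Iteration stops when
the list would exceed the size bound ``N_g`` (a fixed fraction, by default
15%, of the number of measured genes — an upper bound on how many genes
can plausibly be differentially expressed), reaches a fixed point, finds
no significant pathway, or exhausts ``max_rounds``.  The result keeps the
full per-round trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import enrichment
from .exceptions import ConfigurationError
from .io import GeneSetCollection, RankedGeneList


@dataclass
class RectifyConfig:
    """Tunable parameters of the rectification loop.

    n
        Initial list size (the top-n prefix of L).
    m
        Expansion factor in (0, 1]: each round admits floor(m*|C|) genes.
    alpha
        Significance threshold for pathways; applied to BH-adjusted
        p-values unless ``use_adjusted`` is off.
    ng_fraction
        The stopping bound N_g as a fraction of the measured genes.
    min_overlap
        Minimum query overlap k for a pathway to count as significant.
    """

    n: int
    m: float
    alpha: float = 0.05
    ng_fraction: float = 0.15
    max_rounds: int = 50
    min_overlap: int = 2
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not 0 < self.m <= 1:
            raise ConfigurationError("m must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if not 0 < self.ng_fraction < 1:
            raise ConfigurationError("ng_fraction must lie in (0, 1)")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")
        if self.min_overlap < 1:
            raise ConfigurationError("min_overlap must be >= 1")


@dataclass
class RectificationRound:
    """State of one round: the two lists before/after and the sets between."""

    round_index: int
    degs_in: set[str]
    significant_pathways: pd.DataFrame
    U: list[str]
    C: list[str]
    D: list[str]
    degs_out: set[str]
    no_significant_pathways: bool = False

    def summary(self) -> dict:
        return {
            "round": self.round_index,
            "n_in": len(self.degs_in),
            "n_pathways": len(self.significant_pathways),
            "n_U": len(self.U),
            "n_C": len(self.C),
            "n_D": len(self.D),
            "n_out": len(self.degs_out),
        }


@dataclass
class RectificationResult:
    rounds: list[RectificationRound]
    final_degs: set[str]
    final_pathways: pd.DataFrame
    stop_reason: str  # ng_bound | fixed_point | no_significant_pathways | max_rounds
    n_g: int
    config: RectifyConfig
    ranked: RankedGeneList = field(repr=False)

    def to_dict(self) -> dict:
        """Deterministic, JSON-ready serialisation of the full trace."""
        return {
            "stop_reason": self.stop_reason,
            "n_g": self.n_g,
            "config": {
                "n": self.config.n, "m": self.config.m,
                "alpha": self.config.alpha,
                "ng_fraction": self.config.ng_fraction,
                "max_rounds": self.config.max_rounds,
                "min_overlap": self.config.min_overlap,
                "use_adjusted": self.config.use_adjusted,
            },
            "final_degs": sorted(self.final_degs),
            "final_pathways": self.final_pathways["pathway_id"].tolist()
            if len(self.final_pathways) else [],
            "rounds": [
                {
                    "round": r.round_index,
                    "degs_in": sorted(r.degs_in),
                    "pathways": r.significant_pathways["pathway_id"].tolist()
                    if len(r.significant_pathways) else [],
                    "U": list(r.U),
                    "C": list(r.C),
                    "D": list(r.D),
                    "degs_out": sorted(r.degs_out),
                }
                for r in self.rounds
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def compute_ng(total_genes: int, ng_fraction: float = 0.15) -> int:
    """The list-size bound N_g = floor(ng_fraction * total_genes), >= 1."""
    if total_genes < 1:
        raise ConfigurationError("total_genes must be >= 1")
    return max(1, math.floor(ng_fraction * total_genes))


def take_initial(ranked: RankedGeneList, n: int) -> set[str]:
    """The top-n prefix of L as the initial candidate set DEGs-11."""
    if n < 1 or n > len(ranked):
        raise ConfigurationError(
            f"n must lie in [1, {len(ranked)}]; got {n}")
    return set(ranked.top(n))


def _membership_counts(sig: pd.DataFrame, sets: GeneSetCollection,
                       universe: frozenset[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for pid in sig["pathway_id"]:
        for g in sets.genes_of(pid) & universe:
            counts[g] = counts.get(g, 0) + 1
    return counts


def split_annotated(degs: set[str], sig: pd.DataFrame,
                    sets: GeneSetCollection, universe: Iterable[str],
                    ranked: RankedGeneList) -> tuple[list[str], list[str]]:
    """Split the significant pathways' annotation into U and C.

    Let A be the union of the significant pathways' member sets within the
    universe.  U = degs ∩ A in L's order (score descending).  C = the
    measured genes of A not in degs, ordered by score descending with ties
    broken by more significant-pathway memberships, then gene id.  Genes
    annotated but never measured (absent from L) are excluded from C.
    """
    universe = frozenset(universe)
    counts = _membership_counts(sig, sets, universe)
    annotated = set(counts)
    u_set = degs & annotated
    U = sorted(u_set, key=ranked.position_of)
    c_set = {g for g in annotated - degs if g in ranked}
    C = sorted(c_set, key=lambda g: (-ranked.score_of(g), -counts[g], g))
    return U, C


def expansion_size(m: float, C: list[str], U: list[str]) -> int:
    """floor(m * |C \\ U|); C and U are disjoint by construction."""
    if not 0 < m <= 1:
        raise ConfigurationError("m must lie in (0, 1]")
    return math.floor(m * len(set(C) - set(U)))


def rectify_round(i: int, degs_in: set[str], ranked: RankedGeneList,
                  sets: GeneSetCollection, universe: Iterable[str],
                  config: RectifyConfig) -> RectificationRound:
    """One full round: enrich, select significant pathways, rewrite the list.

    Returns a round with the ``no_significant_pathways`` flag set (and
    empty U/C/D/degs_out) when no pathway passes the significance filter.
    """
    if not degs_in:
        raise ConfigurationError("degs_in must be non-empty")
    universe = frozenset(universe)
    table = enrichment.enrich(degs_in, sets, universe)
    sig = enrichment.significant_pathways(table, alpha=config.alpha,
                                          min_overlap=config.min_overlap,
                                          use_adjusted=config.use_adjusted)
    if len(sig) == 0:
        return RectificationRound(
            round_index=i, degs_in=set(degs_in), significant_pathways=sig,
            U=[], C=[], D=[], degs_out=set(), no_significant_pathways=True)
    U, C = split_annotated(set(degs_in), sig, sets, universe, ranked)
    d_size = expansion_size(config.m, C, U)
    D = C[:d_size]
    degs_out = set(U) | set(D)
    return RectificationRound(
        round_index=i, degs_in=set(degs_in), significant_pathways=sig,
        U=U, C=C, D=D, degs_out=degs_out)


def default_universe(ranked: RankedGeneList,
                     sets: GeneSetCollection) -> frozenset[str]:
    """Measured genes that carry at least one pathway annotation."""
    return frozenset(g for g in ranked.genes if g in sets.annotated_universe)


def run_rectification(ranked: RankedGeneList, sets: GeneSetCollection,
                      config: RectifyConfig,
                      universe: Iterable[str] | None = None) -> RectificationResult:
    """Iterate rectification rounds from the top-n prefix of L.

    The universe defaults to the measured-and-annotated genes; N_g is
    computed from the number of measured genes (|L|) regardless.  Stops on
    the first of: the next list would exceed N_g (``ng_bound``; the result
    keeps the last list within the bound), no change (``fixed_point``), no
    significant pathway (``no_significant_pathways``), or ``max_rounds``.
    """
    if universe is None:
        universe = default_universe(ranked, sets)
    universe = frozenset(universe)
    n_g = compute_ng(len(ranked), config.ng_fraction)
    degs = take_initial(ranked, config.n)
    # the running "last compliant list"; empty if even the seed overshoots
    last_ok = set(degs) if len(degs) <= n_g else set()

    rounds: list[RectificationRound] = []
    final = last_ok
    stop = "max_rounds"
    empty_pathways = pd.DataFrame(columns=enrichment.ENRICHMENT_COLUMNS)
    final_pathways = empty_pathways

    for i in range(1, config.max_rounds + 1):
        rnd = rectify_round(i, degs, ranked, sets, universe, config)
        if rnd.no_significant_pathways:
            stop = "no_significant_pathways"
            final = set() if i == 1 else last_ok
            final_pathways = empty_pathways if i == 1 else \
                rounds[-1].significant_pathways
            break
        rounds.append(rnd)
        final_pathways = rnd.significant_pathways
        if len(rnd.degs_out) > n_g:
            stop = "ng_bound"
            final = last_ok
            break
        last_ok = set(rnd.degs_out)
        if rnd.degs_out == degs:
            stop = "fixed_point"
            final = set(rnd.degs_out)
            break
        degs = set(rnd.degs_out)
        final = last_ok

    return RectificationResult(rounds=rounds, final_degs=final,
                               final_pathways=final_pathways,
                               stop_reason=stop, n_g=n_g, config=config,
                               ranked=ranked)
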