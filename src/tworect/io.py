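"""Domain containers and readers/writers for the external formats.

The tool touches four kinds of files:

* expression matrices — tab-delimited, genes in rows, samples in columns,
  values on the log2 scale;
* gene-set collections — GMT (one named set per line);
* interaction networks — three-column TSV edge lists in the STRING style,
  cleaned at parse time (self-loops dropped, duplicate unordered pairs
  collapsed, low-confidence edges removed);
* ranked gene lists — two-column TSV carrying any scorer's output, which is
  also how externally computed rankings enter the pipeline.

Gene identifiers are matched as exact, case-sensitive strings throughout;
readers accept an ``uppercase`` flag for collections whose annotation and
platform identifiers differ only by case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError

CONTROL = "control"
TEST = "test"


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A log2-scale gene-by-sample matrix with a two-group design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.
    group_labels
        Series mapping each sample id to ``"control"`` or ``"test"``.
        Both groups must contain at least two samples, because every
        scorer that models variance needs replication.
    """

    values: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {sorted(set(dupes))[:5]}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if set(self.group_labels.index) != set(self.values.columns):
            raise ConfigurationError("group labels do not cover the samples")
        bad = set(self.group_labels.unique()) - {CONTROL, TEST}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        for group in (CONTROL, TEST):
            if (self.group_labels == group).sum() < 2:
                raise ConfigurationError(
                    f"group {group!r} needs >= 2 samples for variance estimation"
                )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == CONTROL]

    @property
    def test_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == TEST]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def read_expression(
    path,
    control_ids: Sequence[str],
    test_ids: Sequence[str],
    uppercase: bool = False,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix restricted to the named samples.

    The file must have a header row of sample ids and gene ids in the first
    column.  Samples not listed in either group are dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    if uppercase:
        df.index = df.index.str.upper()
    missing = [s for s in list(control_ids) + list(test_ids) if s not in df.columns]
    if missing:
        raise ConfigurationError(f"samples absent from header: {missing}")
    overlap = set(control_ids) & set(test_ids)
    if overlap:
        raise ConfigurationError(f"samples in both groups: {sorted(overlap)}")
    sub = df[list(control_ids) + list(test_ids)]
    try:
        sub = sub.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    labels = pd.Series(
        [CONTROL] * len(control_ids) + [TEST] * len(test_ids),
        index=list(control_ids) + list(test_ids),
    )
    return ExpressionMatrix(values=sub, group_labels=labels)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene-set collections
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Mapping pathway id -> (name/description, member gene set).

    ``sets`` preserves file order; ``annotated_universe`` (the union of all
    member sets) is computed once and cached.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    _universe: frozenset[str] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {pid!r} is empty")

    @property
    def annotated_universe(self) -> frozenset[str]:
        if self._universe is None:
            u: set[str] = set()
            for _, genes in self.sets.values():
                u |= genes
            object.__setattr__(self, "_universe", frozenset(u))
        return self._universe

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path, uppercase: bool = False) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate member genes within a line are de-duplicated; a duplicate
    pathway name or a line with fewer than three fields is an error.
    An empty file yields an empty (but valid) collection.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if uppercase:
                genes = [g.upper() for g in genes]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            sets[name] = (desc, frozenset(genes))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in collection.sets.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Simple undirected weighted graph used for connectivity evaluation.

    Invariants: no self-loops, no duplicate unordered pairs, every edge
    score at or above the threshold used when the network was built.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d.get("score", math.nan)


def read_edge_list(
    path,
    min_score: float = 0.4,
    score_scale: str = "unit",
    uppercase: bool = False,
) -> InteractionNetwork:
    """Read a 3-column TSV edge list and apply the cleaning rules.

    ``score_scale`` declares the dialect: ``"unit"`` for 0-1 confidence
    scores, ``"milli"`` for the 0-1000 STRING combined score (divided by
    1000 before thresholding).  Edges below ``min_score`` and self-loops
    are dropped; duplicate unordered pairs keep the maximum score.
    """
    if score_scale not in ("unit", "milli"):
        raise ConfigurationError(f"unknown score_scale {score_scale!r}")
    divisor = 1000.0 if score_scale == "milli" else 1.0
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            a, b = fields[0], fields[1]
            if uppercase:
                a, b = a.upper(), b.upper()
            try:
                score = float(fields[2]) / divisor
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad score {fields[2]!r}") from exc
            if a == b:
                continue
            if score < min_score:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)
    return InteractionNetwork(graph=g)


def write_edge_list(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v, score in sorted(network.edges()):
            fh.write(f"{u}\t{v}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# Ranked gene lists
# ---------------------------------------------------------------------------

@dataclass
class RankedGeneList:
    """An ordered candidate list: genes descending by differential score.

    Larger score means stronger evidence of differential expression.  The
    order must be consistent with the scores; construction re-checks this
    but does not silently reorder — use :meth:`from_pairs` to sort.
    """

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ConfigurationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ConfigurationError("ranked list scores must be non-increasing")
        self._score_of = dict(zip(self.genes, self.scores))
        self._pos_of = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "RankedGeneList":
        """Build a list sorted descending by score, ties lexicographic."""
        items = sorted(pairs, key=lambda gs: (-gs[1], gs[0]))
        return cls(genes=[g for g, _ in items],
                   scores=np.array([s for _, s in items], dtype=float))

    def score_of(self, gene: str) -> float:
        return self._score_of[gene]

    def position_of(self, gene: str) -> int:
        return self._pos_of[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._score_of

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, n: int) -> list[str]:
        return self.genes[:n]


def read_ranked_list(path, uppercase: bool = False) -> RankedGeneList:
    """Read a two-column TSV of (gene_id, score); re-sorted descending."""
    pairs: list[tuple[str, float]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            gene = fields[0].upper() if uppercase else fields[0]
            if gene in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            try:
                pairs.append((gene, float(fields[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad score {fields[1]!r}") from exc
    return RankedGeneList.from_pairs(pairs)


def write_ranked_list(ranked: RankedGeneList, path) -> None:
    with open(path, "w") as fh:
        for gene, score in zip(ranked.genes, ranked.scores):
            fh.write(f"{gene}\t{float(score)!r}\n")


def read_gene_list(path, uppercase: bool = False) -> list[str]:
    """One gene id per line; order preserved, duplicates an error."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            gene = raw.strip()
            if not gene or gene.startswith("#"):
                continue
            if uppercase:
                gene = gene.upper()
            if gene in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            genes.append(gene)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
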