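"""Co-expression machinery: similarity rankings, mutual rank, KNN networks.

The atlas is log-transformed (log2(TPM + offset)), pairwise similarity is
computed (Pearson by default, Spearman optionally), and each gene's
neighbours are fully ordered by descending similarity with deterministic
id-based tie-breaking.  From the full ordering come the directed
neighbourhood ranks r(A->B), the symmetric mutual rank
sqrt(r(A->B) * r(B->A)) — the established co-expression strength measure
— and the KNN network connecting each gene to its top-k most
co-expressing genes (k = 500 at atlas scale).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ExpressionAtlas

__all__ = [
    "PreprocessedMatrix",
    "SimilarityRanking",
    "KNNNetwork",
    "preprocess_atlas",
    "compute_similarity",
    "mutual_rank",
    "build_knn",
    "export_edges",
    "read_edges",
    "to_graphml",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PreprocessedMatrix:
    """log2-transformed expression with unrankable genes flagged.

    ``excluded`` maps gene id -> reason (zero variance, low expression);
    these genes carry through but never enter a ranking.
    """

    values: pd.DataFrame
    excluded: dict[str, str]

    @property
    def rankable_genes(self) -> list[str]:
        return [g for g in self.values.index if g not in self.excluded]


def preprocess_atlas(
    atlas: ExpressionAtlas,
    log_offset: float = 1.0,
    min_expression: float | None = None,
) -> PreprocessedMatrix:
    """log2(TPM + offset) transform; flag genes unusable for correlation.

    Genes whose maximum TPM falls below ``min_expression`` (when given)
    and genes with zero variance across samples (including all-zero
    genes) are flagged unrankable: their correlation is undefined or
    meaningless.  No filter is applied by default.
    """
    if not log_offset > 0:
        raise ValueError("log_offset must be positive")
    raw = atlas.values.to_numpy(dtype=float)
    transformed = np.log2(raw + log_offset)
    excluded: dict[str, str] = {}
    if min_expression is not None:
        low = raw.max(axis=1) < min_expression
        for gid in atlas.values.index[low]:
            excluded[gid] = f"max TPM below min_expression={min_expression}"
    variances = transformed.var(axis=1)
    for gid in atlas.values.index[variances == 0.0]:
        excluded.setdefault(gid, "zero variance across samples")
    if excluded:
        logger.warning(
            "%d gene(s) flagged unrankable (e.g. %s: %s)",
            len(excluded),
            next(iter(excluded)),
            excluded[next(iter(excluded))],
        )
    values = pd.DataFrame(
        transformed, index=atlas.values.index, columns=atlas.values.columns
    )
    return PreprocessedMatrix(values=values, excluded=excluded)


@dataclasses.dataclass
class SimilarityRanking:
    """Per-gene full ordering of all other rankable genes by co-expression.

    For each rankable gene A the neighbour ranks r(A->B) form a bijection
    onto 1..n-1 (descending similarity, ties broken by ascending gene
    id); A never appears in its own list.  Excluded (unrankable) genes
    are carried through for error reporting.
    """

    method: str
    gene_ids: list[str]  # rankable genes, atlas order
    similarity: np.ndarray  # (n, n) symmetric
    ranks: np.ndarray  # (n, n) int; ranks[i, j] = r(gene_i -> gene_j); diag 0
    order: np.ndarray  # (n, n-1) int; order[i] = neighbour indices by rank
    excluded: dict[str, str]

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def _idx(self, gene: str) -> int:
        if gene in self.excluded:
            raise ValueError(
                f"gene {gene!r} is unrankable ({self.excluded[gene]})"
            )
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in ranking") from None

    def rank(self, a: str, b: str) -> int:
        """Neighbourhood rank r(a->b), in 1..n-1."""
        ia, ib = self._idx(a), self._idx(b)
        if ia == ib:
            raise ValueError(f"rank undefined for a gene against itself: {a!r}")
        return int(self.ranks[ia, ib])

    def neighbors(self, gene: str, k: int | None = None) -> list[str]:
        """The gene's neighbours in rank order (all, or the top k)."""
        i = self._idx(gene)
        idx = self.order[i] if k is None else self.order[i, :k]
        return [self.gene_ids[j] for j in idx]

    def similarity_of(self, a: str, b: str) -> float:
        return float(self.similarity[self._idx(a), self._idx(b)])


def compute_similarity(
    pre: PreprocessedMatrix, method: str = "pearson"
) -> SimilarityRanking:
    """Rank every rankable gene's neighbours by co-expression.

    ``method`` is "pearson" (on the log2 matrix) or "spearman".  Requires
    at least 3 samples and at least 2 rankable genes.  Ties are broken by
    ascending gene id, which makes the ordering independent of the row
    order of the input.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown similarity method: {method!r}")
    genes = pre.rankable_genes
    if pre.values.shape[1] < 3:
        raise ValueError(
            f"need >= 3 samples for a stable correlation, got {pre.values.shape[1]}"
        )
    if len(genes) < 2:
        raise ValueError(f"need >= 2 rankable genes, got {len(genes)}")
    mat = pre.values.loc[genes].to_numpy(dtype=float)
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 1, mat)
    sim = np.corrcoef(mat)
    n = len(genes)
    # lexicographic id rank for deterministic, order-independent tie-breaking
    id_rank = np.argsort(np.argsort(np.array(genes, dtype=object)))
    order = np.empty((n, n - 1), dtype=np.int64)
    ranks = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        # primary: descending similarity; secondary: ascending gene id
        full = np.lexsort((id_rank, -sim[i]))
        full = full[full != i]
        order[i] = full
        ranks[i, full] = np.arange(1, n, dtype=np.int64)
    return SimilarityRanking(
        method=method,
        gene_ids=list(genes),
        similarity=sim,
        ranks=ranks,
        order=order,
        excluded=dict(pre.excluded),
    )


def mutual_rank(ranking: SimilarityRanking, a: str, b: str) -> float:
    """Mutual rank sqrt(r(a->b) * r(b->a)); symmetric, >= 1."""
    return math.sqrt(ranking.rank(a, b) * ranking.rank(b, a))


@dataclasses.dataclass
class KNNNetwork:
    """Top-k co-expression network.

    ``directed``: gene -> its top-k neighbours in rank order.
    ``edges``: undirected union-symmetrised edge set; each edge (a, b)
    with a < b carries (r(a->b), r(b->a), mutual_rank).
    """

    k: int
    directed: dict[str, list[str]]
    edges: dict[tuple[str, str], tuple[int, int, float]]
    ranking: SimilarityRanking

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.edges


def build_knn(ranking: SimilarityRanking, k: int) -> KNNNetwork:
    """Connect each gene to its top-k most co-expressing genes.

    The undirected edge set is the union symmetrisation: an edge exists
    when either gene lists the other in its top k.  Each edge records
    both directed ranks and the mutual rank.
    """
    n = ranking.n_genes
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    directed = {g: ranking.neighbors(g, k) for g in ranking.gene_ids}
    edges: dict[tuple[str, str], tuple[int, int, float]] = {}
    for a, neigh in directed.items():
        for b in neigh:
            key = (a, b) if a < b else (b, a)
            if key not in edges:
                r_ab = ranking.rank(key[0], key[1])
                r_ba = ranking.rank(key[1], key[0])
                edges[key] = (r_ab, r_ba, math.sqrt(r_ab * r_ba))
    return KNNNetwork(k=k, directed=directed, edges=edges, ranking=ranking)


def export_edges(network: KNNNetwork, path: str | Path) -> None:
    """Write the undirected edge list as TSV in deterministic order.

    Columns: gene_a, gene_b, rank_ab, rank_ba, mutual_rank; rows sorted
    lexicographically by (gene_a, gene_b) with gene_a < gene_b.
    """
    rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "rank_ab": r_ab,
            "rank_ba": r_ba,
            "mutual_rank": mr,
        }
        for (a, b), (r_ab, r_ba, mr) in sorted(network.edges.items())
    ]
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rank_ab", "rank_ba", "mutual_rank"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read an exported edge-list TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


def to_graphml(network: KNNNetwork, path: str | Path) -> None:
    """Export the undirected network as GraphML with mutual_rank edge attributes."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.ranking.gene_ids)
    for (a, b), (r_ab, r_ba, mr) in sorted(network.edges.items()):
        g.add_edge(a, b, rank_ab=int(r_ab), rank_ba=int(r_ba), mutual_rank=float(mr))
    nx.write_graphml(g, path)
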