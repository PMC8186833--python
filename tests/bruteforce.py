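"""Independent brute-force oracle for co-expression ranking and selection.

Pure-Python textbook implementations (no numpy) used only to cross-check
the package: pairwise Pearson/Spearman correlation, full neighbour
orderings with the id tie-break, mutual ranks, KNN adjacency and capped
candidate selection.
"""

from __future__ import annotations

import math


def pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _average_ranks(x: list[float]) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman(x: list[float], y: list[float]) -> float:
    return pearson(_average_ranks(x), _average_ranks(y))


def similarity_matrix(
    matrix: dict[str, list[float]], method: str = "pearson"
) -> dict[tuple[str, str], float]:
    corr = pearson if method == "pearson" else spearman
    genes = list(matrix)
    sim = {}
    for a in genes:
        for b in genes:
            sim[(a, b)] = 1.0 if a == b else corr(matrix[a], matrix[b])
    return sim


def rankings(
    matrix: dict[str, list[float]], method: str = "pearson"
) -> dict[str, list[str]]:
    """Gene -> all other genes ordered by descending similarity, ties by id."""
    sim = similarity_matrix(matrix, method)
    out = {}
    for a in matrix:
        others = [g for g in matrix if g != a]
        out[a] = sorted(others, key=lambda b: (-sim[(a, b)], b))
    return out


def rank(ordering: dict[str, list[str]], a: str, b: str) -> int:
    return ordering[a].index(b) + 1


def mutual_rank(ordering: dict[str, list[str]], a: str, b: str) -> float:
    return math.sqrt(rank(ordering, a, b) * rank(ordering, b, a))


def knn_directed(ordering: dict[str, list[str]], k: int) -> dict[str, list[str]]:
    return {g: neigh[:k] for g, neigh in ordering.items()}


def knn_undirected(ordering: dict[str, list[str]], k: int) -> set[tuple[str, str]]:
    edges = set()
    for a, neigh in knn_directed(ordering, k).items():
        for b in neigh:
            edges.add((a, b) if a < b else (b, a))
    return edges


def select(
    ordering: dict[str, list[str]],
    baits: list[str],
    regulators: set[str],
    k: int,
    cap: int,
) -> dict[tuple[str, str], int]:
    """(candidate, bait) -> rank, by exhaustive scan of each bait's ordering."""
    out = {}
    for bait in baits:
        kept = 0
        for pos, g in enumerate(ordering[bait][:k], start=1):
            if g in regulators:
                out[(g, bait)] = pos
                kept += 1
                if kept == cap:
                    break
    return out
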