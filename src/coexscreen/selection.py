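"""Bait-driven candidate regulator selection and screening-group design.

For each bait gene (a known pathway gene), the top-k most co-expressing
genes are intersected with an annotated regulator set (e.g. genes
carrying GO:0010468, "regulation of gene expression"); the best ``cap``
matches per bait are kept (by the bait's own neighbourhood rank, a
directed notion) and the per-bait lists are unioned into a candidate
table recording every surviving (candidate, bait, rank) triple.  With
44 baits and a cap of 10 the union is bounded by 440 candidates;
overlap between bait neighbourhoods shrinks it.

Candidates are then partitioned into screening groups of up to four for
combinatorial co-overexpression, greedily merging candidates whose
bait-association sets overlap (Jaccard similarity > 0).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coexpression import KNNNetwork, SimilarityRanking

__all__ = [
    "RegulatorAnnotation",
    "BaitPanel",
    "CandidateTable",
    "ScreeningGroups",
    "select_candidates",
    "relative_rank_matrix",
    "assign_groups",
]


@dataclasses.dataclass
class RegulatorAnnotation:
    """Genes annotated as regulators of gene expression."""

    gene_ids: Sequence[str]
    label: str = "GO:0010468"

    def __post_init__(self) -> None:
        ids = list(self.gene_ids)
        if not ids:
            raise ValueError("regulator annotation is empty")
        if len(set(ids)) != len(ids):
            dup = next(g for g in ids if ids.count(g) > 1)
            raise ValueError(f"duplicate regulator id: {dup!r}")
        self.gene_ids = ids

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)


@dataclasses.dataclass
class BaitPanel:
    """Ordered bait genes, optionally tagged with a pathway branch."""

    gene_ids: Sequence[str]
    branch: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.gene_ids)
        if not ids:
            raise ValueError("bait panel is empty")
        if len(set(ids)) != len(ids):
            dup = next(g for g in ids if ids.count(g) > 1)
            raise ValueError(f"duplicate bait id: {dup!r}")
        self.gene_ids = ids


@dataclasses.dataclass
class CandidateTable:
    """Candidates x baits with per-bait neighbourhood ranks.

    ``records`` holds one row per surviving (candidate, bait) pair with
    the bait's neighbourhood rank r(bait->candidate); a pair absent from
    the records means the candidate was not kept for that bait (which is
    different from rank 0).
    """

    records: pd.DataFrame  # columns: candidate, bait, rank
    k: int
    cap: int

    def __post_init__(self) -> None:
        need = {"candidate", "bait", "rank"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"candidate records need columns {sorted(need)}")
        per_bait = self.records.groupby("bait").size()
        over = per_bait[per_bait > self.cap]
        if len(over):
            raise ValueError(
                f"bait {over.index[0]!r} records {over.iloc[0]} candidates, "
                f"cap is {self.cap}"
            )

    @property
    def candidates(self) -> list[str]:
        return sorted(self.records["candidate"].unique())

    @property
    def baits(self) -> list[str]:
        return sorted(self.records["bait"].unique())

    def bait_sets(self) -> dict[str, frozenset[str]]:
        """Candidate -> the set of baits it was selected for."""
        return {
            cand: frozenset(sub["bait"])
            for cand, sub in self.records.groupby("candidate")
        }

    def write_tsv(self, path: str | Path) -> None:
        out = self.records.copy().sort_values(["candidate", "bait"])
        out["relative_rank"] = out["rank"] / self.k
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, k: int, cap: int) -> "CandidateTable":
        df = pd.read_csv(path, sep="\t")
        return cls(records=df[["candidate", "bait", "rank"]], k=k, cap=cap)


def select_candidates(
    source: KNNNetwork | SimilarityRanking,
    baits: BaitPanel,
    regulators: RegulatorAnnotation,
    k: int | None = None,
    cap: int = 10,
) -> CandidateTable:
    """Select candidate regulators from bait-gene KNN neighbourhoods.

    Per bait: walk its neighbours in rank order up to k, keep those in
    the regulator set, truncate to the best ``cap``.  The candidate set
    is the union over baits, with all surviving (candidate, bait, rank)
    triples recorded.  A bait never becomes its own candidate (it is
    absent from its own neighbour list), but baits that are annotated
    regulators may be selected as candidates for other baits.
    """
    if isinstance(source, KNNNetwork):
        ranking = source.ranking
        k = source.k if k is None else k
    else:
        ranking = source
        if k is None:
            raise ValueError("k is required when selecting from a raw ranking")
    if not 1 <= cap <= k:
        raise ValueError(f"need k >= cap >= 1, got k={k}, cap={cap}")
    known = set(ranking.gene_ids) | set(ranking.excluded)
    for bait in baits.gene_ids:
        if bait not in known:
            raise ValueError(f"bait gene {bait!r} absent from the atlas")
    regulator_set = set(regulators.gene_ids)

    rows = []
    for bait in baits.gene_ids:
        kept = 0
        for pos, neighbor in enumerate(ranking.neighbors(bait, k), start=1):
            if neighbor in regulator_set:
                rows.append({"candidate": neighbor, "bait": bait, "rank": pos})
                kept += 1
                if kept == cap:
                    break
    records = pd.DataFrame(rows, columns=["candidate", "bait", "rank"])
    return CandidateTable(records=records, k=k, cap=cap)


def relative_rank_matrix(table: CandidateTable) -> pd.DataFrame:
    """Baits x candidates matrix of relative ranks r/k in (0, 1].

    Pairs not recorded in the table are NaN (absence, never 0).  Rows are
    baits, columns candidates — the orientation of a selection heatmap.
    """
    if not len(table.records):
        return pd.DataFrame()
    mat = table.records.pivot_table(
        index="bait", columns="candidate", values="rank", aggfunc="min"
    )
    return (mat / table.k).sort_index(axis=0).sort_index(axis=1)


@dataclasses.dataclass
class ScreeningGroups:
    """Partition of candidates into co-overexpression groups (size <= max_size)."""

    groups: dict[str, list[str]]
    max_size: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            if not 1 <= len(members) <= self.max_size:
                raise ValueError(
                    f"group {label!r} has {len(members)} members, "
                    f"allowed 1..{self.max_size}"
                )
            overlap = seen & set(members)
            if overlap:
                raise ValueError(
                    f"candidate {sorted(overlap)[0]!r} assigned to two groups"
                )
            seen.update(members)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def members(self) -> list[str]:
        out: list[str] = []
        for label in self.groups:
            out.extend(self.groups[label])
        return out

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"group_id": label, "candidate": cand}
            for label, members in self.groups.items()
            for cand in members
        ]
        pd.DataFrame(rows, columns=["group_id", "candidate"]).to_csv(
            path, sep="\t", index=False
        )


def assign_groups(table: CandidateTable, max_size: int = 4) -> ScreeningGroups:
    """Greedy deterministic grouping by shared bait-association profiles.

    Candidates are represented by their bait sets and ordered by
    descending association count, ties by id.  Each group is seeded with
    the first unassigned candidate; remaining unassigned candidates join
    in descending Jaccard similarity of bait sets (only if > 0, ties by
    id) until the group reaches ``max_size``.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if not len(table.records):
        raise ValueError("candidate table is empty")
    bait_sets = table.bait_sets()
    pending = sorted(bait_sets, key=lambda c: (-len(bait_sets[c]), c))
    groups: dict[str, list[str]] = {}
    gi = 0
    while pending:
        seed = pending.pop(0)
        gi += 1
        members = [seed]
        seed_set = bait_sets[seed]
        scored = []
        for cand in pending:
            s = bait_sets[cand]
            jac = len(seed_set & s) / len(seed_set | s)
            if jac > 0:
                scored.append((-jac, cand))
        for _, cand in sorted(scored):
            if len(members) >= max_size:
                break
            members.append(cand)
            pending.remove(cand)
        groups[f"G{gi:02d}"] = members
    return ScreeningGroups(groups=groups, max_size=max_size)
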