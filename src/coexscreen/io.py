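"""Small text-format helpers: gene lists, sample metadata, truth files."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = ["read_gene_list", "write_gene_list", "write_planted_truth"]

logger = logging.getLogger(__name__)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line gene list; '#' comments and blanks skipped.

    Duplicates are dropped (first occurrence kept) with a warning; the
    original order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    out: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        gid = line.split("#", 1)[0].strip()
        if not gid:
            continue
        if gid in seen:
            logger.warning("duplicate gene id %r in %s (kept first)", gid, path)
            continue
        seen.add(gid)
        out.append(gid)
    return out


def write_gene_list(gene_ids, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def write_planted_truth(truth, path: str | Path) -> None:
    """Write planted ground truth as a flat TSV (gene_id, role, module)."""
    rows = []
    for mod in sorted(truth.pathway_genes):
        for g in truth.pathway_genes[mod]:
            rows.append({"gene_id": g, "role": "pathway", "module": mod})
    for mod in sorted(truth.regulator_genes):
        for g in truth.regulator_genes[mod]:
            rows.append({"gene_id": g, "role": "regulator", "module": mod})
    for g in truth.background_genes:
        rows.append({"gene_id": g, "role": "background", "module": ""})
    pd.DataFrame(rows, columns=["gene_id", "role", "module"]).to_csv(
        path, sep="\t", index=False
    )
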