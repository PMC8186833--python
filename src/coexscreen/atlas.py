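"""Expression atlas container.

The atlas is a genes x samples matrix of TPM (transcripts per million)
values together with per-sample metadata (organ, treatment).  It is the
substrate for all co-expression computation downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionAtlas", "read_expression_tsv", "write_expression_tsv"]


@dataclasses.dataclass
class ExpressionAtlas:
    """Genes x samples TPM matrix with optional sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative TPM values, index = gene ids, columns = sample ids.
    sample_meta : pandas.DataFrame, optional
        Per-sample labels (e.g. organ, treatment), indexed by sample id.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value for gene {v.index[gi]!r} "
                f"in sample {v.columns[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value for gene {v.index[gi]!r} "
                f"in sample {v.columns[si]!r}"
            )
        if self.sample_meta is not None:
            missing = v.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample metadata missing for: {list(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_expression_tsv(path: str | Path) -> ExpressionAtlas:
    """Read a genes x samples TSV (first column gene id, header = sample ids)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"no sample columns in {path}")
    # locate non-numeric cells with a line number for the error message
    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = non_numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at line {gi + 2} (gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}) in {path}"
        )
    if non_numeric.isna().to_numpy().any():
        gi, si = np.argwhere(non_numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at line {gi + 2} (gene {df.index[gi]!r}) in {path}"
        )
    df = non_numeric.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionAtlas(values=df)


def write_expression_tsv(atlas: ExpressionAtlas, path: str | Path) -> None:
    """Write the atlas as TSV (gene id first column, sample-id header)."""
    atlas.values.to_csv(path, sep="\t", index_label="gene_id")
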