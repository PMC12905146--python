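"""Normalized log2 gene-expression matrix keyed by sample reference names."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes × samples of normalized log2 expression.

    ``values`` is a DataFrame with gene symbols as the index and sample
    reference names (e.g. GEO GSM accessions) as columns.  ``batch_flag``
    marks samples recorded as carrying a batch factor; flagged samples are
    dropped, not adjusted, by the stimulated-gene analysis.
    """

    values: pd.DataFrame
    batch_flag: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample reference names: {dupes}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def is_batch(self, sample: str) -> bool:
        return bool(self.batch_flag.get(sample, False))

    def column(self, sample: str) -> np.ndarray:
        if sample not in self.values.columns:
            raise KeyError(f"sample reference {sample!r} not in expression matrix")
        return self.values[sample].to_numpy()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.values.copy()
        out.index.name = "gene_symbol"
        out.to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, batch_flag: dict[str, bool] | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(path, index_col=0)
        values.index = values.index.astype(str)
        return cls(values=values, batch_flag=dict(batch_flag or {}))
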