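"""Integer feature-by-sample count matrices.

The whole pipeline starts from quantified expression tables: rows are
features (mature miRNAs or genes), columns are tumor samples. This module
wraps a :class:`pandas.DataFrame` with the validation the downstream
stages rely on (integer non-negative counts, unique identifiers) and the
fixed TSV dialect used everywhere in the package (tab-separated, UTF-8,
'.' decimal, feature identifier in the first column).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer expression counts, features x samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("count matrix must have at least one feature and one sample")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise ValueError("counts must not contain missing values")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(values, np.floor(values)):
            raise ValueError("counts must be integral")
        # canonical dtype so serialization is bit-stable
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(feature_ids)])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(sample_ids)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", lineterminator="\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.data.equals(other.data)
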