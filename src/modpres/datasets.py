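"""Core data container for expression studies.

An :class:`ExpressionDataset` couples a genes x samples matrix of log2-scale
intensities with per-sample metadata (condition, batch, age, sex).  Every
pipeline stage consumes and returns this container, so validation lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("condition", "batch", "age", "sex")


class DatasetError(ValueError):
    """Raised when an expression dataset violates its structural contract."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index are unique gene ids,
        columns are unique sample ids.  Values are log2-scale intensities.
    metadata
        DataFrame indexed by sample id, one row per sample, with at least the
        columns ``condition``, ``batch``, ``age`` and ``sex`` (sex coded 0/1).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {
                    "condition": "unknown",
                    "batch": "b0",
                    "age": np.nan,
                    "sex": np.nan,
                },
                index=self.values.columns,
            )
        self.validate()

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise DatasetError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise DatasetError("duplicate sample ids")
        if not self.values.columns.equals(self.metadata.index):
            raise DatasetError("metadata rows do not match sample ids one-to-one")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise DatasetError(f"metadata missing columns: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        """Expression values as a float ndarray (genes x samples)."""
        return self.values.to_numpy(dtype=float)

    # ------------------------------------------------------------------ #

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[gene_ids], self.metadata.copy())

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[:, sample_ids], self.metadata.loc[sample_ids]
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.metadata.copy())

    # ------------------------------------------------------------------ #
    # TSV round trip.  Expression: first column gene id, one column per
    # sample.  Metadata: sample id, condition, batch, age, sex.

    def to_tsv(self, expr_path, meta_path=None) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(expr_path, sep="\t", float_format="%.10g")
        if meta_path is not None:
            meta = self.metadata.copy()
            meta.index.name = "sample_id"
            meta.to_csv(meta_path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, expr_path, meta_path=None) -> "ExpressionDataset":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
        return cls(values, meta)
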