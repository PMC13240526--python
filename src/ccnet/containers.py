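"""Shared in-memory containers for bulk expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_SAMPLE_COLUMNS = ("species", "day", "replicate")


@dataclass
class ExpressionMatrix:
    """Normalized expression values (genes x samples) plus sample metadata.

    ``values`` has gene symbols as its index and sample identifiers as columns;
    ``samples`` is indexed by the same sample identifiers and carries at least
    ``species``, ``day`` (numeric) and ``replicate`` columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            raise ValueError("sample metadata is required")
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if list(self.values.columns) != list(self.samples.index):
            # allow any order but require the same sample set
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample metadata disagree")
            self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def day(self) -> pd.Series:
        """Numeric day per sample, aligned to the expression columns."""
        return self.samples["day"].astype(float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])
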