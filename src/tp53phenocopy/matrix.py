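"""Gene-by-sample expression container with batch labels and a processing-state flag.

The matrix moves through exactly one state path: ``raw`` -> ``ranked`` ->
``corrected``.  Each harmonization operation checks the flag so that, e.g.,
batch correction cannot be applied to un-ranked data and ranking cannot be
applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

STATES = ("raw", "ranked", "corrected")

#: literal used for missing values in all TSV interfaces
NA_TOKEN = "NA"


@dataclass
class ExpressionMatrix:
    """Expression values (genes x samples) plus per-sample batch labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    batches
        Series mapping sample id -> batch/cohort label; must cover every
        sample column.
    state
        Processing state, one of ``raw``, ``ranked``, ``corrected``.
    """

    values: pd.DataFrame
    batches: pd.Series
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.batches.index]
        if missing:
            raise ValidationError(f"samples without a batch label: {missing[:5]}...")
        # keep batch labels aligned to the sample columns, in column order
        object.__setattr__(self, "batches", self.batches.reindex(self.values.columns))

    # -- basic views ------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def batch_ids(self) -> list:
        return list(pd.unique(self.batches))

    def with_values(self, values: pd.DataFrame, state: str | None = None) -> "ExpressionMatrix":
        """Return a copy with replaced values (and optionally a new state)."""
        return ExpressionMatrix(values=values, batches=self.batches.copy(),
                                state=state if state is not None else self.state)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, samples], self.batches.loc[samples], self.state)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batches.copy(), self.state)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, expression_path: str | Path, batches_path: str | Path | None = None) -> None:
        """Write the expression TSV (first column ``gene``) and, optionally,
        the two-column (sample, batch) assignment TSV."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(expression_path, sep="\t", na_rep=NA_TOKEN)
        if batches_path is not None:
            pd.DataFrame({"sample": self.batches.index, "batch": self.batches.values}).to_csv(
                batches_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expression_path: str | Path, batches_path: str | Path | None = None,
                 batches: pd.Series | None = None, state: str = "raw") -> "ExpressionMatrix":
        values = pd.read_csv(expression_path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                             keep_default_na=False)
        values = values.astype(float) if values.shape[1] else values
        values.index.name = None
        values.columns.name = None
        if batches_path is not None:
            tab = pd.read_csv(batches_path, sep="\t")
            batches = pd.Series(tab["batch"].values, index=tab["sample"].values)
        if batches is None:
            batches = pd.Series("batch1", index=values.columns)
        return cls(values=values, batches=batches, state=state)
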