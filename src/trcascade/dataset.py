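"""Time-series expression dataset container.

The expression input is a gene x sample matrix together with a *design*
that assigns every sample to one time point and one replicate.  Values are
non-negative expression levels in arbitrary units (normalized counts, TPM,
microarray intensities); the cascade algorithm only relies on within-gene
profile shape, so no normalization is imposed on input data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "normalize_symbol"]


def normalize_symbol(name: str) -> str:
    """Canonical gene-symbol form used for matching across inputs.

    HGNC symbols are conventionally upper-case; matching between the
    expression matrix, the regulatory network and the annotation map is
    done on the trimmed, upper-cased symbol.
    """
    return str(name).strip().upper()


@dataclass(frozen=True)
class ExpressionDataset:
    """Gene x sample expression matrix with a time/replicate design.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
        All entries must be finite and >= 0.
    design
        DataFrame indexed by sample label with columns ``time`` (numeric
        time value or ordinal), ``time_index`` (0-based rank of the time
        point) and ``replicate`` (0-based index within the time point).
    display_names
        Optional map from normalized gene symbol to the symbol as it
        appeared in the input file.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol after normalization: {dup!r}")
        arr = vals.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {vals.index[g]!r}, "
                f"sample {vals.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {vals.index[g]!r}, "
                f"sample {vals.columns[s]!r}"
            )
        missing = [c for c in vals.columns if c not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        if len(set(self.design.index)) != len(self.design.index):
            raise ValueError("design assigns a sample more than once")
        times = self.time_points
        if len(times) < 2:
            raise ValueError(
                f"need >= 2 distinct time points, got {len(times)}"
            )
        # time_index must rank the numeric times in strictly increasing order
        by_index = (
            self.design.drop_duplicates("time_index")
            .sort_values("time_index")["time"]
            .to_numpy()
        )
        if not np.all(np.diff(by_index) > 0):
            raise ValueError("time points are not strictly increasing")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def time_points(self) -> list[float]:
        """Distinct time values in ascending order."""
        return sorted(set(self.design["time"]))

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    # ------------------------------------------------------------------
    def collapse(self) -> pd.DataFrame:
        """Replicate-mean gene x time-point matrix.

        Columns are time-point indices 0..T-1 in time order; the value is
        the arithmetic mean over that time point's replicates.
        """
        idx = self.design.loc[self.values.columns, "time_index"].to_numpy()
        out = {}
        for t in range(self.n_timepoints):
            cols = self.values.columns[idx == t]
            out[t] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)

    def max_per_gene(self) -> pd.Series:
        """Maximum raw value per gene over all replicates and time points.

        This is the quantity the minE expression floor is tested against:
        a gene must exceed minE *somewhere* in the uncollapsed matrix.
        """
        return self.values.max(axis=1)

    def replace_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Same design, new matrix (used by the null-model shuffles)."""
        return ExpressionDataset(values, self.design, self.display_names)

    def display(self, gene: str) -> str:
        return self.display_names.get(gene, gene)
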