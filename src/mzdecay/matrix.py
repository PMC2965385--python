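"""Expression-matrix container shared by all pipeline stages.

The matrix holds log2 expression for genes (rows) across hybridized samples
(columns); the accompanying design table maps every sample to a series
(``U`` = unfertilized eggs, ``E`` = embryos), a time point (1-3) and a
replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SERIES = ("U", "E")
TIMEPOINTS = (1, 2, 3)

#: All six sampling conditions in canonical order: U1..U3 then E1..E3.
CONDITIONS = [(s, t) for s in SERIES for t in TIMEPOINTS]


def condition_label(series: str, timepoint: int) -> str:
    return f"{series}{timepoint}"


@dataclass
class ExpressionMatrix:
    """Log2 expression values plus the per-sample design.

    Parameters
    ----------
    values
        genes x samples DataFrame of log2 expression, indexed by gene id.
    design
        DataFrame indexed by sample id with columns ``series``,
        ``timepoint`` and ``replicate``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(vals).any():
            bad = self.values.columns[self.values.isna().any(axis=0)]
            raise ValueError(f"missing values in samples: {list(bad)}")
        design = self.design.loc[list(self.values.columns)]
        for series, tp in CONDITIONS:
            if not ((design["series"] == series) & (design["timepoint"] == tp)).any():
                raise ValueError(f"no samples for condition {condition_label(series, tp)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_samples(self, series: str, timepoint: int) -> list[str]:
        """Sample ids belonging to one (series, timepoint) condition."""
        design = self.design.loc[list(self.values.columns)]
        mask = (design["series"] == series) & (design["timepoint"] == timepoint)
        return list(design.index[mask])

    def condition_values(self, series: str, timepoint: int) -> pd.DataFrame:
        return self.values[self.condition_samples(series, timepoint)]
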