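"""Shared in-memory containers for the pipeline.

The central object is :class:`OmicsMatrix`, a labelled numeric matrix
(genes or probes in rows, samples in columns) carrying a tumor/normal
group assignment per sample and, optionally, a tumor/normal pair id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class OmicsMatrix:
    """Row-feature x sample matrix with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame, rows are gene or probe ids, columns are sample ids.
    groups
        Mapping sample id -> ``"tumor"`` or ``"normal"``, covering every
        column of ``values``.
    pairs
        Optional mapping sample id -> pair id linking a tumor column to
        its matched normal. Recorded for provenance; the differential
        tests are unpaired.
    """

    values: pd.DataFrame
    groups: pd.Series
    pairs: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row ids in matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)[:5]}")
        bad = set(self.groups.loc[list(self.values.columns)]) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def group_columns(self, group: str) -> list[str]:
        labels = self.groups.loc[list(self.values.columns)]
        return [s for s in self.values.columns if labels[s] == group]

    @property
    def tumor(self) -> pd.DataFrame:
        return self.values[self.group_columns(TUMOR)]

    @property
    def normal(self) -> pd.DataFrame:
        return self.values[self.group_columns(NORMAL)]

    def subset_features(self, ids) -> "OmicsMatrix":
        keep = [i for i in ids if i in self.values.index]
        return OmicsMatrix(self.values.loc[keep], self.groups, self.pairs)

    def validate_beta(self) -> None:
        arr = self.values.to_numpy(float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values outside [0, 1]")

    def validate_expression(self) -> None:
        arr = self.values.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite expression values")
        if arr.min() < 0:
            raise ValueError("negative expression values")
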