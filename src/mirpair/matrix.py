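"""Count-matrix container shared by the expression stages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CONTROL = "control"
TUMOUR = "tumour"


@dataclass
class CountMatrix:
    """Features x samples integer read counts with two-group sample labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = feature ids (unique),
        columns = sample ids.
    groups
        Per-sample label, ``"control"`` or ``"tumour"``, indexed by sample id
        in the same order as ``counts.columns``.
    tumour_type
        Cohort tag (e.g. ``"LUAD"``).
    """

    counts: pd.DataFrame
    groups: pd.Series
    tumour_type: str = ""

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("feature ids must be unique")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValueError("counts must be non-negative")
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.counts.columns):
            self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.counts.columns[self.groups.isna()].tolist()
            raise ValueError(f"samples missing a group label: {missing}")
        bad = set(self.groups.unique()) - {CONTROL, TUMOUR}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_features(self, features) -> "CountMatrix":
        return CountMatrix(self.counts.loc[features], self.groups.copy(), self.tumour_type)

    def __eq__(self, other) -> bool:  # round-trip checks
        return (
            isinstance(other, CountMatrix)
            and self.tumour_type == other.tumour_type
            and self.counts.equals(other.counts)
            and self.groups.equals(other.groups)
        )
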