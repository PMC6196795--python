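"""Replicated feature-by-sample expression container with condition labels.

The pipeline operates on log2-scale intensity matrices from a two-condition
(treated vs. control) design with biological replicates.  Matrices are stored
features x samples; a per-sample condition label distinguishes the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATED = "treated"
CONTROL = "control"


class ExpressionError(ValueError):
    """Raised for malformed expression matrices."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of (log2) intensities.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    conditions
        Series mapping each sample id to its condition label
        (``"treated"`` or ``"control"``).
    """

    values: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.values.isna().any().any():
            raise ExpressionError("missing values in expression matrix")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ExpressionError(f"samples without condition label: {missing}")
        self.conditions = self.conditions.loc[self.values.columns]
        bad = set(self.conditions.unique()) - {TREATED, CONTROL}
        if bad:
            raise ExpressionError(f"unknown condition labels: {sorted(bad)}")
        counts = self.conditions.value_counts()
        if counts.get(TREATED, 0) < 2 or counts.get(CONTROL, 0) < 2:
            raise ExpressionError("need >= 2 samples per condition")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.conditions == condition).to_numpy()

    def group_values(self, condition: str) -> np.ndarray:
        """Values restricted to one condition, features x replicates."""
        return self.values.loc[:, self.condition_mask(condition)].to_numpy()

    def with_values(self, values: np.ndarray | pd.DataFrame) -> "ExpressionMatrix":
        """Same samples/conditions, new value matrix of identical shape."""
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.values.index,
            columns=self.values.columns,
        )
        return ExpressionMatrix(frame, self.conditions.copy())

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path, conditions_path=None) -> None:
        """Write matrix as TSV (feature id first column) plus a sidecar
        two-column sample->condition map."""
        frame = self.values.copy()
        frame.index.name = "feature_id"
        frame.to_csv(path, sep="\t", float_format="%.17g")
        if conditions_path is not None:
            cond = self.conditions.rename("condition")
            cond.index.name = "sample_id"
            cond.to_csv(conditions_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, conditions_path) -> "ExpressionMatrix":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ExpressionError(f"cannot parse matrix TSV {path}: {exc}") from exc
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0)["condition"]
        return cls(frame.astype(float), cond)
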