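"""In-memory containers for omics views.

Views are pandas DataFrames at heart: rows are samples (indexed by sample
ID), columns are named features. ``OmicsMatrix`` adds optional per-sample
labels and light validation; ``LongitudinalPhenotype`` is an ordered list of
views sharing sample order and feature names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass
class OmicsMatrix:
    """A samples x features real matrix with sample IDs and feature names.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric matrix; index holds sample IDs, columns hold feature names.
    labels : pandas.Series, optional
        Per-sample categorical labels (e.g. diagnostic groups), aligned with
        ``data.index``.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("OmicsMatrix requires a 2-D table")
        if self.labels is not None:
            self.labels = pd.Series(np.asarray(self.labels), index=self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(self, idx: Sequence[int]) -> "OmicsMatrix":
        """Row-subset by positional indices, keeping labels aligned."""
        sub = self.data.iloc[list(idx)]
        lab = self.labels.iloc[list(idx)] if self.labels is not None else None
        return OmicsMatrix(sub, lab)

    def standardized(self, drop_constant: bool = True) -> "OmicsMatrix":
        """Return a column-standardized copy (zero mean, unit variance).

        Constant columns carry no association signal and make the scale
        constraints degenerate; they are dropped when ``drop_constant``.
        """
        vals = self.values
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)
        keep = sd > 0
        if not drop_constant and not keep.all():
            raise ValueError("constant feature columns present")
        out = (vals[:, keep] - mu[keep]) / sd[keep]
        df = pd.DataFrame(out, index=self.data.index, columns=self.data.columns[keep])
        return OmicsMatrix(df, self.labels)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, labels: pd.Series | None = None) -> "OmicsMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError("first column must be 'sample_id'")
        df = df.set_index("sample_id")
        return cls(df, labels)


@dataclass
class LongitudinalPhenotype:
    """An ordered sequence of T phenotype views sharing samples and features."""

    views: list[OmicsMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("at least one time point required")
        ref = self.views[0]
        for t, v in enumerate(self.views[1:], start=2):
            if not v.sample_ids.equals(ref.sample_ids):
                raise ValueError(f"time point {t} has mismatched sample IDs")
            if not v.feature_names.equals(ref.feature_names):
                raise ValueError(f"time point {t} has mismatched feature names")

    def __len__(self) -> int:
        return len(self.views)

    def __iter__(self) -> Iterator[OmicsMatrix]:
        return iter(self.views)

    def __getitem__(self, t: int) -> OmicsMatrix:
        return self.views[t]

    @property
    def n_timepoints(self) -> int:
        return len(self.views)

    @property
    def sample_ids(self) -> pd.Index:
        return self.views[0].sample_ids

    @property
    def feature_names(self) -> pd.Index:
        return self.views[0].feature_names

    def arrays(self) -> list[np.ndarray]:
        return [v.values for v in self.views]

    def subset(self, idx: Sequence[int]) -> "LongitudinalPhenotype":
        return LongitudinalPhenotype([v.subset(idx) for v in self.views])

    def standardized(self) -> "LongitudinalPhenotype":
        """Standardize each time point; keep only features nonconstant at every t."""
        stds = [v.values.std(axis=0) > 0 for v in self.views]
        keep = np.logical_and.reduce(stds)
        views = []
        for v in self.views:
            vals = v.values[:, keep]
            vals = (vals - vals.mean(axis=0)) / vals.std(axis=0)
            views.append(
                OmicsMatrix(
                    pd.DataFrame(vals, index=v.sample_ids, columns=v.feature_names[keep]),
                    v.labels,
                )
            )
        return LongitudinalPhenotype(views)
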