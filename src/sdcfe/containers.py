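"""Core data containers shared across the package.

The central object is :class:`OmicsMatrix`, a thin wrapper around a pandas
DataFrame holding a samples-by-features real-valued table.  Samples are
always rows and features always columns; identifiers must be unique on both
axes.  Missing values (``NaN``) are permitted until imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

OMICS_TAGS = ("rna", "methylation", "fused", "other")


@dataclass
class OmicsMatrix:
    """A samples × features omics table.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and feature ids as columns.
        Float-valued; NaN marks a missing measurement.
    omics_tag
        One of ``rna``, ``methylation``, ``fused``, ``other``.
    """

    values: pd.DataFrame
    omics_tag: str = "other"

    def __post_init__(self) -> None:
        if self.omics_tag not in OMICS_TAGS:
            raise ValueError(
                f"omics_tag must be one of {OMICS_TAGS}, got {self.omics_tag!r}"
            )
        if not self.values.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("feature ids must be unique")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = None
        self.values.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        """Return a copy carrying ``values`` but the same omics tag."""
        return OmicsMatrix(values=values, omics_tag=self.omics_tag)

    def copy(self) -> "OmicsMatrix":
        return self.with_values(self.values.copy())


@dataclass
class ClinicalTable:
    """Maps sample id to a categorical class or stage label."""

    table: pd.DataFrame  # columns: sample_id, label

    def __post_init__(self) -> None:
        missing = {"sample_id", "label"} - set(self.table.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        self.table["label"] = self.table["label"].astype(str)
        if self.table["sample_id"].duplicated().any():
            raise ValueError("clinical sample_id values must be unique")
        if (self.table["label"].str.len() == 0).any():
            raise ValueError("clinical labels must be non-empty")

    def label_map(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["label"]))


@dataclass(frozen=True)
class ScalingStats:
    """Per-feature mean / standard deviation learned on a training matrix.

    Standard deviations use the population convention (ddof=0); a feature
    with sd = 0 is mapped to 0 when the stats are applied.
    """

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must cover the same features")
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.mean.index)

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            str(f): {"mean": float(self.mean[f]), "sd": float(self.sd[f])}
            for f in self.mean.index
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "ScalingStats":
        feats = list(d)
        mean = pd.Series({f: float(d[f]["mean"]) for f in feats})
        sd = pd.Series({f: float(d[f]["sd"]) for f in feats})
        return cls(mean=mean, sd=sd)


@dataclass
class FeatureSet:
    """An ordered collection of unique selected-feature identifiers."""

    name: str
    features: list[str]
    provenance: str = "manual"  # sdcfe | importance | manual

    def __post_init__(self) -> None:
        if self.provenance not in ("sdcfe", "importance", "manual"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.features = [str(f) for f in self.features]
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"feature set {self.name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __contains__(self, item: str) -> bool:
        return item in set(self.features)
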