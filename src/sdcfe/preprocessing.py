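"""Cleaning, filtering, imputation, transformation and scaling of omics matrices.

The preprocessing chain mirrors common practice for expression matrices:
missingness audit → high-missingness feature drop → KNN imputation →
zero-variance filter → log2 transform → z-score scaling → clinical matching.
Each step is an independent, composable function on :class:`OmicsMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import ClinicalTable, OmicsMatrix, ScalingStats


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable constants for the preprocessing chain.

    knn_k : neighbours used by KNN imputation (default 5).
    log_offset : pseudocount added before the log2 transform (default 1.0).
    max_feature_missing_rate : features missing in more than this fraction of
        samples are dropped before imputation (default 0.5).
    scaling : ``zscore`` or ``none``.
    """

    knn_k: int = 5
    log_offset: float = 1.0
    max_feature_missing_rate: float = 0.5
    scaling: str = "zscore"

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.log_offset < 0:
            raise ValueError("log_offset must be non-negative")
        if not 0.0 <= self.max_feature_missing_rate <= 1.0:
            raise ValueError("max_feature_missing_rate must lie in [0, 1]")
        if self.scaling not in ("zscore", "none"):
            raise ValueError("scaling must be 'zscore' or 'none'")


def compute_missingness(m: OmicsMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-feature and per-sample missing-value fractions.

    Returns
    -------
    (feature_fractions, sample_fractions)
        ``feature_fractions[f]`` is the share of samples in which feature
        ``f`` is missing; symmetrically for samples.
    """
    if m.n_samples == 0 or m.n_features == 0:
        raise ValueError("cannot compute missingness of an empty matrix")
    isna = m.values.isna()
    return isna.mean(axis=0), isna.mean(axis=1)


def drop_high_missing_features(m: OmicsMatrix, max_rate: float) -> OmicsMatrix:
    """Drop features whose missing fraction exceeds ``max_rate``."""
    feat_frac, _ = compute_missingness(m)
    keep = feat_frac[feat_frac <= max_rate].index
    return m.with_values(m.values[keep])


def drop_zero_variance(m: OmicsMatrix) -> OmicsMatrix:
    """Remove features constant across all samples.

    Variance is the population variance over observed (non-missing) values
    and compared exactly against zero; feature order is preserved.
    """
    var = m.values.var(axis=0, ddof=0, skipna=True)
    # a feature with a single observed value has variance 0 -> dropped
    keep = var.index[(var > 0).to_numpy()]
    if len(keep) == 0:
        raise ValueError("no informative features: all features are constant")
    return m.with_values(m.values[keep])


def knn_impute(m: OmicsMatrix, k: int = 5) -> OmicsMatrix:
    """Fill missing entries from the ``k`` nearest samples.

    Distances are Euclidean over mutually observed features, rescaled by the
    fraction of usable coordinates so that sample pairs with different
    missingness patterns remain comparable; an imputed cell takes the mean of
    the feature over the k nearest samples.  Observed cells are untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= m.n_samples:
        raise ValueError(
            f"k={k} must be smaller than the number of samples ({m.n_samples})"
        )
    fully_missing = m.values.columns[m.values.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(
            f"features fully missing cannot be imputed: {list(fully_missing)[:5]}"
        )
    if not m.has_missing:
        return m.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    filled = imputer.fit_transform(m.values.to_numpy())
    out = pd.DataFrame(filled, index=m.values.index, columns=m.values.columns)
    # observed entries are returned bit-exact, not through the imputer
    out = out.where(m.values.isna(), m.values)
    return m.with_values(out)


def log2_transform(m: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """Elementwise ``log2(x + offset)``; requires non-negative values."""
    mins = m.values.min(axis=0, skipna=True)
    bad = mins.index[(mins < 0).to_numpy()]
    if len(bad):
        raise ValueError(
            f"log2 transform requires non-negative values; negative entries in "
            f"feature(s) {list(bad)[:5]}"
        )
    return m.with_values(np.log2(m.values + offset))


def inverse_log2_transform(m: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """Invert :func:`log2_transform`: ``2**x - offset``."""
    return m.with_values(np.exp2(m.values) - offset)


def zscore_scale(
    m: OmicsMatrix, stats: ScalingStats | None = None
) -> tuple[OmicsMatrix, ScalingStats]:
    """Standardize each feature to zero mean and unit population sd.

    When ``stats`` is given (train/test discipline) those statistics are
    applied as-is; otherwise they are computed from ``m`` and returned.
    Features with sd = 0 map to 0.
    """
    if m.has_missing:
        raise ValueError("z-score scaling requires an imputed matrix")
    if stats is None:
        mean = m.values.mean(axis=0)
        sd = m.values.std(axis=0, ddof=0)
        stats = ScalingStats(mean=mean, sd=sd)
    else:
        if set(stats.feature_ids) != set(m.feature_ids):
            raise ValueError("scaling stats feature set does not match the matrix")
    mean = stats.mean.reindex(m.values.columns)
    sd = stats.sd.reindex(m.values.columns)
    safe_sd = sd.replace(0.0, np.nan)
    scaled = (m.values - mean) / safe_sd
    scaled = scaled.fillna(0.0)
    return m.with_values(scaled), stats


def match_clinical(
    m: OmicsMatrix, clinical: ClinicalTable, keep_labels: set[str] | None = None
) -> tuple[OmicsMatrix, pd.Series]:
    """Restrict to samples with a clinical label in ``keep_labels``.

    Returns the filtered matrix and the labels aligned to its row order.
    """
    labels = clinical.label_map()
    keep = [
        s
        for s in m.sample_ids
        if s in labels and (keep_labels is None or labels[s] in keep_labels)
    ]
    if not keep:
        raise ValueError("no samples match the clinical table and label filter")
    sub = m.with_values(m.values.loc[keep])
    y = pd.Series([labels[s] for s in keep], index=keep, name="label")
    return sub, y


def align_to_feature_list(
    m: OmicsMatrix, trained_features: list[str], fill: float = 0.0
) -> tuple[OmicsMatrix, int]:
    """Reindex columns to a fixed trained feature list.

    Features absent from ``m`` become constant ``fill`` columns (so a model
    trained on the full list can still be applied); extra features are
    dropped.  Returns the aligned matrix and the number of filled features.
    """
    trained = [str(f) for f in trained_features]
    present = set(m.feature_ids)
    n_filled = sum(1 for f in trained if f not in present)
    if n_filled == len(trained):
        warnings.warn(
            "none of the trained features are present; output is all fill values",
            stacklevel=2,
        )
    aligned = m.values.reindex(columns=trained, fill_value=fill)
    return m.with_values(aligned), n_filled


def preprocess(
    m: OmicsMatrix,
    config: PreprocessConfig | None = None,
    stats: ScalingStats | None = None,
) -> tuple[OmicsMatrix, ScalingStats | None]:
    """Run the full chain: missingness filter → impute → variance filter →
    log2 → scale.  Returns the processed matrix and the scaling statistics
    (None when scaling is disabled)."""
    cfg = config or PreprocessConfig()
    out = drop_high_missing_features(m, cfg.max_feature_missing_rate)
    if out.has_missing:
        out = knn_impute(out, cfg.knn_k)
    out = drop_zero_variance(out)
    out = log2_transform(out, cfg.log_offset)
    if cfg.scaling == "zscore":
        out, stats = zscore_scale(out, stats)
        return out, stats
    return out, None
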