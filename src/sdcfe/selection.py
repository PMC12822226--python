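"""Feature-selection set algebra, importance ranking and multiomics fusion.

The package's own computations here are the positive-importance retention
rule, deterministic set operations (intersection with Venn accounting,
non-redundant union) and the late-fusion step that concatenates per-omics
selected feature columns over the matched samples.  The gradient-boosted
learner producing the importances is an external dependency reached through
a thin adapter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureSet, OmicsMatrix

_TAG_PREFIX = {"rna": "rna", "methylation": "meth", "fused": "fused", "other": "x"}


@dataclass(frozen=True)
class BoosterConfig:
    """Hyperparameters for the gradient-boosted importance ranker."""

    n_estimators: int = 200
    max_depth: int = 5
    learning_rate: float = 0.1
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    seed: int = 42
    objective: str = "multiclass_softprob"  # or binary_logistic
    eval_metric: str = "logloss"

    def __post_init__(self) -> None:
        if min(self.n_estimators, self.max_depth) < 1:
            raise ValueError("n_estimators and max_depth must be positive")
        if not (0 < self.learning_rate and 0 < self.subsample <= 1
                and 0 < self.colsample_bytree <= 1):
            raise ValueError("learning_rate/subsample/colsample must be positive")
        if self.objective not in ("multiclass_softprob", "binary_logistic"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass(frozen=True)
class VennCounts:
    """Two-set overlap accounting: union = only_A + only_B + shared."""

    only_a: int
    only_b: int
    shared: int

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.shared

    def to_dict(self) -> dict[str, int]:
        return {
            "only_A": self.only_a,
            "only_B": self.only_b,
            "shared": self.shared,
            "union": self.union,
        }


@dataclass
class FusionResult:
    """Late-fused matrix plus per-omics bookkeeping."""

    matrix: OmicsMatrix
    counts: dict[str, int]  # per-omics selected feature counts
    matched_samples: list[str]


def importance_rank(
    m: OmicsMatrix, y: pd.Series | np.ndarray, cfg: BoosterConfig | None = None
) -> FeatureSet:
    """Rank features by gradient-boosted-tree importance; keep importance > 0.

    Importance is total gain.  The returned set is ordered by descending
    importance (ties broken by feature id) and is deterministic for a fixed
    seed.  Requires the optional ``xgboost`` dependency.
    """
    try:
        import xgboost as xgb
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "importance_rank requires the optional xgboost dependency; "
            "install it with: pip install 'sdcfe[boost]'"
        ) from exc

    cfg = cfg or BoosterConfig()
    labels = pd.Series(np.asarray(y, dtype=object)).astype(str)
    codes, _ = pd.factorize(labels, sort=True)
    if cfg.objective == "binary_logistic":
        objective = "binary:logistic"
    else:
        objective = "multi:softprob"
    clf = xgb.XGBClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        subsample=cfg.subsample,
        colsample_bytree=cfg.colsample_bytree,
        random_state=cfg.seed,
        objective=objective,
        eval_metric=cfg.eval_metric,
        importance_type="total_gain",
        n_jobs=1,
    )
    clf.fit(m.values.to_numpy(), codes)
    imp = pd.Series(clf.feature_importances_, index=m.feature_ids)
    kept = imp[imp > 0]
    order = kept.to_frame("imp").reset_index(names="feature_id")
    order = order.sort_values(
        ["imp", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return FeatureSet(
        name="importance_positive",
        features=list(order["feature_id"]),
        provenance="importance",
    )


def intersect_sets(a: FeatureSet, b: FeatureSet) -> tuple[FeatureSet, VennCounts]:
    """Shared features (in ``a``'s order) plus Venn counts."""
    sb = set(b.features)
    shared = [f for f in a.features if f in sb]
    counts = VennCounts(
        only_a=len(a) - len(shared),
        only_b=len(b) - len(shared),
        shared=len(shared),
    )
    out = FeatureSet(
        name=f"{a.name}&{b.name}", features=shared, provenance="manual"
    )
    return out, counts


def nonredundant_union(a: FeatureSet, b: FeatureSet) -> FeatureSet:
    """Union with duplicates removed: ``a``'s order, then ``b``'s novel ids."""
    sa = set(a.features)
    merged = list(a.features) + [f for f in b.features if f not in sa]
    return FeatureSet(name=f"{a.name}|{b.name}", features=merged, provenance="manual")


def late_fusion(
    a: OmicsMatrix,
    feats_a: FeatureSet,
    b: OmicsMatrix,
    feats_b: FeatureSet,
) -> FusionResult:
    """Concatenate selected feature columns of two omics over shared samples.

    Columns are ``feats_a`` then ``feats_b``, each prefixed with its omics
    tag so identical ids across omics stay distinct; rows are the samples
    present in both matrices, in ``a``'s order.
    """
    for fs, mat, side in ((feats_a, a, "first"), (feats_b, b, "second")):
        missing = [f for f in fs.features if f not in set(mat.feature_ids)]
        if missing:
            raise KeyError(
                f"selected feature(s) absent from the {side} matrix: {missing[:5]}"
            )
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not shared:
        raise ValueError("late fusion requires at least one shared sample id")
    pa = _TAG_PREFIX.get(a.omics_tag, a.omics_tag)
    pb = _TAG_PREFIX.get(b.omics_tag, b.omics_tag)
    if pa == pb:
        pa, pb = pa + "1", pb + "2"
    left = a.values.loc[shared, feats_a.features]
    left.columns = [f"{pa}:{f}" for f in feats_a.features]
    right = b.values.loc[shared, feats_b.features]
    right.columns = [f"{pb}:{f}" for f in feats_b.features]
    fused = pd.concat([left, right], axis=1)
    return FusionResult(
        matrix=OmicsMatrix(values=fused, omics_tag="fused"),
        counts={a.omics_tag: len(feats_a), b.omics_tag: len(feats_b)},
        matched_samples=shared,
    )
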