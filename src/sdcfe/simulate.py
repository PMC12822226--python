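"""Synthetic multi-class omics cohorts for testing the scoring pipeline.

The generator emulates the statistical structure the method assumes:
log-scale expression around a common baseline, a small block of informative
genes whose mean is shifted in one class (marker-gene style), an optional
disjoint block of genes shifted along latent subtypes orthogonal to the
class labels (so the unsupervised cluster-separation component has signal
the labels do not carry), MCAR missingness, and paired two-omics cohorts
with partially overlapping samples.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

BASELINE_MEAN = 6.0  # typical log2 expression level


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort recipe.

    effect_size and subtype_effect are class- and subtype-mean shifts in
    units of the noise standard deviation.  ``n_subtype_genes`` defaults to
    ``n_informative`` when subtypes are requested.
    """

    n_classes: int = 4
    n_per_class: int = 50
    n_genes: int = 1000
    n_informative: int = 30
    effect_size: float = 2.0
    n_subtypes: int = 0
    subtype_effect: float = 0.0
    n_subtype_genes: int | None = None
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_per_class < 1 or self.n_genes < 1:
            raise ValueError("n_classes >= 2, n_per_class >= 1, n_genes >= 1 required")
        if self.n_informative + self.resolved_subtype_genes > self.n_genes:
            raise ValueError("informative + subtype gene blocks exceed n_genes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def resolved_subtype_genes(self) -> int:
        if self.n_subtype_genes is not None:
            return self.n_subtype_genes
        return self.n_informative if self.n_subtypes else 0


def _class_conditioned_matrix(
    cfg: SimulationConfig, class_codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Baseline Gaussians plus one-class mean shifts for the planted block."""
    n = len(class_codes)
    X = rng.normal(BASELINE_MEAN, cfg.noise_sd, size=(n, cfg.n_genes))
    up_class = rng.integers(0, cfg.n_classes, size=cfg.n_informative)
    shift = cfg.effect_size * cfg.noise_sd
    for j, c in enumerate(up_class):
        X[class_codes == c, j] += shift
    return X


def planted_gene_ids(cfg: SimulationConfig) -> list[str]:
    """Ids of the class-informative gene block for a given config."""
    return [f"G{j:05d}" for j in range(cfg.n_informative)]


def subtype_gene_ids(cfg: SimulationConfig) -> list[str]:
    """Ids of the latent-subtype gene block for a given config."""
    start = cfg.n_informative
    return [f"G{j:05d}" for j in range(start, start + cfg.resolved_subtype_genes)]


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[OmicsMatrix, pd.Series, list[str], pd.Series]:
    """Generate one expression cohort.

    Returns ``(matrix, class_labels, planted_gene_ids, subtype_labels)``.
    Informative genes get a mean shift of ``effect_size·noise_sd`` in one
    randomly assigned class; subtype-block genes get the analogous shift in
    one latent subtype, with subtype membership drawn independently of
    class.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_classes * cfg.n_per_class
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{j:05d}" for j in range(cfg.n_genes)]
    class_codes = np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)
    y = pd.Series(
        [f"class{c}" for c in class_codes], index=sample_ids, name="label"
    )
    X = _class_conditioned_matrix(cfg, class_codes, rng)

    n_sub_genes = cfg.resolved_subtype_genes
    if cfg.n_subtypes and n_sub_genes:
        subtype_codes = rng.integers(0, cfg.n_subtypes, size=n)
        sub_shift = cfg.subtype_effect * cfg.noise_sd
        up_subtype = rng.integers(0, cfg.n_subtypes, size=n_sub_genes)
        start = cfg.n_informative
        for k, s in enumerate(up_subtype):
            X[subtype_codes == s, start + k] += sub_shift
        subtype = pd.Series(subtype_codes, index=sample_ids, name="subtype")
    else:
        subtype = pd.Series(0, index=sample_ids, name="subtype")

    m = OmicsMatrix(
        values=pd.DataFrame(X, index=sample_ids, columns=gene_ids), omics_tag="rna"
    )
    if cfg.missing_rate > 0:
        m = inject_missing(m, cfg.missing_rate, seed=cfg.seed + 1)
    return m, y, planted_gene_ids(cfg), subtype


def inject_missing(m: OmicsMatrix, rate: float, seed: int = 0) -> OmicsMatrix:
    """Mask each cell independently (MCAR) with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return m.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(m.values.shape) < rate
    vals = m.values.mask(mask)
    return m.with_values(vals)


def simulate_paired_omics(
    cfg_a: SimulationConfig,
    cfg_b: SimulationConfig,
    overlap_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, pd.Series, OmicsMatrix, pd.Series]:
    """Two cohorts on partially overlapping samples with consistent labels.

    A pooled patient cohort is drawn first; the expression matrix covers
    one subset, the methylation matrix another, and their intersection has
    size ``round(overlap_fraction · min(n_a, n_b))``.  Both matrices are
    generated conditional on the same pooled class labels, so a shared
    sample keeps its id and label across omics.  Methylation-like values
    are a logistic squash of latent Gaussians, strictly inside (0, 1).

    Returns ``(rna_matrix, rna_labels, meth_matrix, meth_labels)``.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]; zero overlap "
                         "cannot produce a fusable pair")
    cfg_b = replace(cfg_b, n_classes=cfg_a.n_classes)
    n_a = cfg_a.n_classes * cfg_a.n_per_class
    n_b = cfg_b.n_classes * cfg_b.n_per_class
    n_overlap = max(1, round(overlap_fraction * min(n_a, n_b)))
    n_pool = n_a + n_b - n_overlap

    rng = np.random.default_rng(seed)
    pool_ids = [f"P{i:04d}" for i in range(n_pool)]
    pool_codes = rng.integers(0, cfg_a.n_classes, size=n_pool)

    # first n_a pool members form the RNA cohort; the RNA tail of length
    # n_overlap is shared with the methylation cohort, which adds the rest
    idx_a = np.arange(n_a)
    idx_b = np.concatenate([np.arange(n_a - n_overlap, n_a),
                            np.arange(n_a, n_pool)])

    Xa = _class_conditioned_matrix(cfg_a, pool_codes[idx_a], rng)
    ma = OmicsMatrix(
        values=pd.DataFrame(
            Xa,
            index=[pool_ids[i] for i in idx_a],
            columns=[f"G{j:05d}" for j in range(cfg_a.n_genes)],
        ),
        omics_tag="rna",
    )
    ya = pd.Series([f"class{pool_codes[i]}" for i in idx_a],
                   index=ma.sample_ids, name="label")

    Xb = _class_conditioned_matrix(cfg_b, pool_codes[idx_b], rng)
    latent = (Xb - BASELINE_MEAN) / cfg_b.noise_sd
    mb = OmicsMatrix(
        values=pd.DataFrame(
            1.0 / (1.0 + np.exp(-latent)),
            index=[pool_ids[i] for i in idx_b],
            columns=[f"CpG{j:05d}" for j in range(cfg_b.n_genes)],
        ),
        omics_tag="methylation",
    )
    yb = pd.Series([f"class{pool_codes[i]}" for i in idx_b],
                   index=mb.sample_ids, name="label")
    return ma, ya, mb, yb
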