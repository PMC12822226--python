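"""Biomarker novelty tiering from a binary gene-by-resource evidence table.

Candidate genes are screened against six resources: four curated
biomarker/driver databases (COSMIC Cancer Gene Census, OncoKB, CIViC,
ONGene) and two cancer-association resources (Human Protein Atlas pathology
data, DisGeNET).  Presence is encoded 0/1 and genes fall into three tiers by
a categorical rule:

* **established** — present in at least one curated database;
* **emerging** — absent from all curated databases but present in at least
  one association resource;
* **novel** — absent from all six resources.

The mean presence score across the six columns is reported alongside (a
gene is novel exactly when its mean is 0).  The evidence table is a
user-supplied offline input; no database is queried.
"""

from __future__ import annotations

import pandas as pd

CURATED_RESOURCES = ("COSMIC", "OncoKB", "CIViC", "ONGene")
ASSOCIATION_RESOURCES = ("HPA", "DisGeNET")
ALL_RESOURCES = CURATED_RESOURCES + ASSOCIATION_RESOURCES

TIERS = ("novel", "emerging", "established")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(ALL_RESOURCES) - set(table.columns)
    if missing:
        raise ValueError(f"evidence table missing resource columns: {sorted(missing)}")
    ev = table[list(ALL_RESOURCES)]
    if not ev.isin([0, 1]).all().all():
        raise ValueError("evidence entries must be binary (0 or 1)")
    return ev.astype(int)


def mean_presence(table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the six binary presence indicators per gene."""
    ev = _validate(table)
    out = ev.mean(axis=1)
    out.name = "mean_presence"
    return out


def classify_tiers(table: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene a tier and its mean presence score.

    Expects a DataFrame indexed by gene id (or with a ``gene`` column) whose
    columns include the six resource names.  The categorical rule takes
    precedence over the score: any curated presence → established; else any
    presence → emerging; else novel.
    """
    if "gene" in table.columns:
        table = table.set_index("gene")
    ev = _validate(table)
    curated_any = ev[list(CURATED_RESOURCES)].any(axis=1)
    assoc_any = ev[list(ASSOCIATION_RESOURCES)].any(axis=1)
    tier = pd.Series("novel", index=ev.index, name="tier")
    tier[assoc_any] = "emerging"
    tier[curated_any] = "established"
    return pd.DataFrame(
        {"mean_presence": ev.mean(axis=1), "tier": tier}
    ).rename_axis("gene")


def tier_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of genes per tier; values always sum to the number of genes."""
    if len(table) == 0:
        return {t: 0 for t in TIERS}
    tiers = classify_tiers(table)["tier"]
    counts = tiers.value_counts()
    return {t: int(counts.get(t, 0)) for t in TIERS}
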