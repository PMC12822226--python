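"""Reading and writing the delimited-text formats used by the CLI.

Matrices travel as TSV/CSV with sample ids in the first column and a header
row of feature ids (``transpose=True`` for feature-by-sample files);
missing values are empty fields or ``NA``.  Feature sets are one id per
line; scaling statistics, Venn counts and metric reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ClinicalTable, FeatureSet, OmicsMatrix, ScalingStats

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(
    path: str | Path, omics_tag: str = "other", transpose: bool = False
) -> OmicsMatrix:
    """Load a delimited matrix; first column holds row ids."""
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=_NA_VALUES,
        keep_default_na=False,
    )
    if transpose:
        df = df.T
    return OmicsMatrix(values=df, omics_tag=omics_tag)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep=_sep(path), index_label="sample_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    return ClinicalTable(table=df)


def read_labels(path: str | Path) -> pd.Series:
    """Labels as a Series indexed by sample id (columns sample_id, label)."""
    c = read_clinical(path)
    return pd.Series(c.label_map(), name="label")


def write_labels(y: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": y.index.astype(str), "label": y.values})
    df.to_csv(path, sep=_sep(path), index=False)


def read_feature_set(path: str | Path, name: str | None = None) -> FeatureSet:
    """One feature id per line, order preserved; or JSON with provenance."""
    p = Path(path)
    if p.suffix == ".json":
        d = json.loads(p.read_text())
        return FeatureSet(
            name=d.get("name", p.stem),
            features=d["features"],
            provenance=d.get("provenance", "manual"),
        )
    feats = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
    return FeatureSet(name=name or p.stem, features=feats)


def write_feature_set(fs: FeatureSet, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(
            {"name": fs.name, "provenance": fs.provenance,
             "features": list(fs.features)}, indent=2) + "\n")
    else:
        p.write_text("\n".join(fs.features) + ("\n" if fs.features else ""))


def read_scaling_stats(path: str | Path) -> ScalingStats:
    return ScalingStats.from_dict(json.loads(Path(path).read_text()))


def write_scaling_stats(stats: ScalingStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
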