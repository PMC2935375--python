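"""Readers and writers for the package's delimited file formats.

Conventions: expression matrices are TSV with probesets as rows and a
``probeset`` index column; sample sheets, qPCR tables and swim records are
CSV; reports are JSON. All text is UTF-8 with '.' as decimal separator.
Probeset ids are opaque strings (Affymetrix-style ids pass through
unparsed). Every writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import validate_sheet
from .errors import SchemaError
from .pipeline_de import ExpressionMatrix


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "probeset":
        raise SchemaError(f"{path}: first column must be 'probeset', "
                          f"got {df.index.name!r}")
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "probeset"
    df.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample": str, "animal": str, "batch": str})
    return validate_sheet(sheet)


def write_samples(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_qpcr_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"assay": str, "sample": str})
    required = {"assay", "sample", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: qPCR measurements missing columns "
                          f"{sorted(missing)}")
    return df


def read_dilutions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"assay": str})
    missing = {"assay", "copies", "ct"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: dilution series missing columns "
                          f"{sorted(missing)}")
    return df


def read_swim(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str, "line": str})
    missing = {"animal", "line", "cohort", "immobility_s"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: swim records missing columns "
                          f"{sorted(missing)}")
    return df


def read_detable(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probeset": str})
    missing = {"probeset", "p_cohort1", "p_cohort2"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: DETable missing columns {sorted(missing)}")
    return df


def write_detable(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (pd.Index, np.ndarray)):
            return list(o)
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_JSONEncoder) + "\n")
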