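"""Reading and writing the package's TSV tables, plus provenance sidecars.

Every table is UTF-8 tab-separated text with a mandatory header row; one
record per line.  Unknown columns are preserved.  A cohort table carries the
required record columns followed by one column per analyte; the reported
race/ethnicity set is serialised pipe-joined (empty string = empty set).
Each artifact written by the pipeline is accompanied by a ``.provenance.json``
sidecar recording the config hash, seed and library versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RECORD_COLUMNS

__all__ = [
    "SchemaError",
    "read_records",
    "write_records",
    "write_table",
    "read_table",
    "write_provenance",
    "config_hash",
]

_NUMERIC_COLUMNS = ["aabc", "ga", "bw"]


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


def read_records(path) -> pd.DataFrame:
    """Read a cohort table, validating schema and numeric fields.

    Raises :class:`SchemaError` naming any absent required column, or a
    :class:`SchemaError` with 1-based file line numbers for rows whose
    numeric fields do not parse.  A header-only file yields an empty frame.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    metabolite_cols = [c for c in df.columns if c not in RECORD_COLUMNS]
    bad_lines = []
    for col in _NUMERIC_COLUMNS + metabolite_cols:
        vals = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = vals.isna() & df[col].ne("")
        # header is line 1, first data row line 2
        bad_lines.extend((int(i) + 2, col) for i in df.index[bad])
    if bad_lines:
        desc = "; ".join(f"line {ln}: non-numeric {col!r}" for ln, col in sorted(bad_lines)[:10])
        raise SchemaError(f"{path}: malformed rows — {desc}")
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    # fractional collection ages are floored to integer hours on ingest
    df["aabc"] = np.floor(df["aabc"])
    for col in metabolite_cols:
        df[col] = pd.to_numeric(df[col])
    return df


def write_records(records: pd.DataFrame, path) -> None:
    """Write a cohort table as TSV (see :func:`read_records` for the dialect)."""
    write_table(records, path)


def write_table(obj, path) -> None:
    """Write a DataFrame (or object with ``to_frame``) as a UTF-8 TSV."""
    df = obj.to_frame() if hasattr(obj, "to_frame") and not isinstance(obj, pd.DataFrame) else obj
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None,
              lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Read a generic TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def config_hash(config_dict: dict) -> str:
    """SHA-256 of the canonical JSON form of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def write_provenance(artifact_path, *, seed: int | None = None,
                     config_dict: dict | None = None, extra: dict | None = None) -> Path:
    """Write the ``.provenance.json`` sidecar next to an artifact.

    Deliberately excludes wall-clock time so re-runs are byte-identical.
    """
    import scipy
    import statsmodels

    from . import __version__

    artifact_path = Path(artifact_path)
    sidecar = artifact_path.with_suffix(artifact_path.suffix + ".provenance.json")
    payload = {
        "artifact": artifact_path.name,
        "seed": seed,
        "config_sha256": config_hash(config_dict) if config_dict is not None else None,
        "versions": {
            "nbstiming": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        payload.update(extra)
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar
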