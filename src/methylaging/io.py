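"""Plain-text I/O for methylation analysis artifacts.

All tables are tab-separated text.  A beta matrix is stored probes x samples
with the probe id in the first column, matching the layout of public
methylation-array deposits.  Missing beta values are empty cells (read back
as NaN).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

INTERCEPT_KEY = "(Intercept)"


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix from TSV.

    The first column holds probe ids and becomes the index; remaining
    columns are samples.  Values are floats in [0, 1]; empty cells are NaN.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df.astype(float)


def write_beta_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (columns: sample_id, age, optional sex/tissue)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "age" not in meta.columns:
        raise ValueError("sample metadata must have 'sample_id' and 'age' columns")
    if meta["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    meta["age"] = meta["age"].astype(float)
    if (meta["age"] < 0).any():
        raise ValueError("ages must be non-negative")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_blacklist(path: str | Path) -> list[str]:
    """Read a probe blacklist: one probe id per line, ``#`` starts a comment."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


def read_probe_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column probe -> gene map (TSV, header ``probe_id\\tgene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    df = df.rename(columns={cols[0]: "probe_id", cols[1]: "gene_id"})
    return df[["probe_id", "gene_id"]]


def read_clock_table(path: str | Path) -> tuple[float, pd.Series]:
    """Read a linear-clock coefficient table.

    Rows are ``marker_id\\tcoefficient``; the reserved ``(Intercept)`` row
    carries the intercept (0 if absent).  Returns (intercept, coefficients).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["marker_id", "coefficient"][: len(df.columns)]
    df["coefficient"] = df["coefficient"].astype(float)
    mask = df["marker_id"] == INTERCEPT_KEY
    intercept = float(df.loc[mask, "coefficient"].iloc[0]) if mask.any() else 0.0
    coefs = df.loc[~mask].set_index("marker_id")["coefficient"]
    if coefs.index.duplicated().any():
        raise ValueError("duplicate marker ids in clock table")
    return intercept, coefs


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
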