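"""Reading and writing the package's CSV/JSON interchange formats.

All tables are plain UTF-8 CSV with a mandatory header row; sample
identifiers are opaque strings. The three inputs are:

* abundance matrix — sample IDs in the first column, taxon names in the
  header, nonnegative integer counts;
* metadata — columns sample_id, site_pair, reach_type, biotope, replicate;
* fuzzy trait table (long) — columns taxon, rank, grouping_feature,
  trait_code, affinity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "read_abundance_table",
    "read_metadata",
    "read_trait_table",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_json",
]

REACH_TYPES = ("control", "restored")


def read_abundance_table(path) -> pd.DataFrame:
    """Read a sample x taxon count matrix, validating cell by cell.

    Raises ``ValueError`` with row/column coordinates for non-numeric or
    negative cells, and on duplicate sample IDs.
    """
    frame = pd.read_csv(path, index_col=0, dtype=str)
    dupes = frame.index[frame.index.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate sample ID(s): {list(dupes)}")
    out = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at sample {frame.index[i]!r}, taxon {col!r}: {raw!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"negative count at sample {frame.index[i]!r}, taxon {col!r}: {value}"
                )
            if value != int(value):
                raise ValueError(
                    f"non-integer count at sample {frame.index[i]!r}, taxon {col!r}: {value}"
                )
            out[i, j] = int(value)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table, indexed by sample_id."""
    frame = pd.read_csv(path)
    required = {"sample_id", "site_pair", "reach_type", "biotope", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        dupes = list(frame.loc[frame["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample ID(s) in metadata: {dupes}")
    bad = set(frame["reach_type"]) - set(REACH_TYPES)
    if bad:
        raise ValueError(f"unknown reach_type value(s): {sorted(bad)}")
    return frame.set_index("sample_id")


def read_trait_table(path) -> pd.DataFrame:
    """Read a long fuzzy-coded trait table."""
    frame = pd.read_csv(path)
    required = {"taxon", "trait_code", "affinity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    return frame


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a square distance matrix CSV with sample IDs on both margins."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, index_label="sample_id"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, index_col=0)
    return DistanceMatrix(frame.to_numpy(dtype=float), ids=list(frame.index))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
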