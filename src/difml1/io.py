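"""CSV input and TSV/JSON output for response data and results.

The interchange format is a plain CSV with a header: one 0/1 group column
(reference = 0, focal = 1) and one 0/1 column per item.  Missing values are
rejected rather than imputed — the marginal likelihood assumes complete data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ResponseData

__all__ = ["read_responses_csv", "write_responses_csv"]


def read_responses_csv(path, group_col: str = "group") -> ResponseData:
    """Read and validate a response CSV into a :class:`ResponseData`.

    Every cell must be exactly 0 or 1; the first offending cell is named in
    the error.  Item column names are preserved for reporting.
    """
    df = pd.read_csv(path)
    if group_col not in df.columns:
        raise ValueError(f"missing group column {group_col!r} in {path}")
    item_cols = [c for c in df.columns if c != group_col]
    if not item_cols:
        raise ValueError("no item columns found")
    for col in [group_col] + item_cols:
        vals = df[col]
        bad = ~vals.isin([0, 1]) | vals.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-binary or missing value in column {col!r}, row {row + 2} "
                f"(1-based, counting the header): {vals.iloc[row]!r}")
    return ResponseData(
        responses=df[item_cols].to_numpy(),
        groups=df[group_col].to_numpy(),
        item_names=tuple(item_cols),
    )


def write_responses_csv(data: ResponseData, path,
                        group_col: str = "group") -> None:
    """Write a :class:`ResponseData` to CSV (inverse of read_responses_csv)."""
    names = data.item_names or tuple(f"item{j + 1}" for j in range(data.n_items))
    df = pd.DataFrame(data.responses, columns=list(names))
    df.insert(0, group_col, data.groups)
    df.to_csv(path, index=False)
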