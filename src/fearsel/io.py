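"""Delimited-text table I/O (tab-separated, pandas-backed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_contingency_table(path: str | Path) -> pd.DataFrame:
    """Counts table with row labels in the first column, columns in the header."""
    return pd.read_csv(path, sep="\t", index_col=0)
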