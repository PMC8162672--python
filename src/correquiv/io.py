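"""Reading raw paired observations from delimited text files."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["CorrelationSample", "read_paired_data"]

logger = logging.getLogger(__name__)

_DELIMITERS = ",\t;"


@dataclass(frozen=True)
class CorrelationSample:
    """A Pearson correlation with the sample size it was computed from."""

    r: float
    n: int
    n_dropped: int = 0
    source: Optional[str] = None


def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=_DELIMITERS).delimiter
    except csv.Error:
        return ","


def read_paired_data(
    path: Union[str, Path], delimiter: Optional[str] = None
) -> CorrelationSample:
    """Compute (r, N) from a two-column delimited text file.

    The delimiter is sniffed from comma/tab/semicolon unless given; a
    header row is detected and skipped.  Rows with a missing value in
    either column are dropped (complete-case) with the count logged and
    reported.  Decimal commas are not guessed at — cells must parse as
    ordinary floats.

    Raises
    ------
    ValueError
        On non-numeric cells, fewer than two columns, fewer than 4 complete
        rows, or zero variance in either column (r undefined).
    """
    path = Path(path)
    text = path.read_text()
    sep = delimiter or _sniff_delimiter(text)
    try:
        has_header = csv.Sniffer().has_header(text)
    except csv.Error:
        has_header = False
    df = pd.read_csv(
        path, sep=sep, header=0 if has_header else None, skip_blank_lines=True
    )
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: expected two delimited numeric columns, found {df.shape[1]}"
        )
    if df.shape[1] > 2:
        logger.warning("%s: %d columns found; using the first two", path, df.shape[1])
    pair = df.iloc[:, :2].apply(pd.to_numeric, errors="raise")
    complete = pair.dropna()
    n_dropped = len(pair) - len(complete)
    if n_dropped:
        logger.info("%s: dropped %d incomplete row(s)", path, n_dropped)
    if len(complete) < 4:
        raise ValueError(
            f"{path}: need at least 4 complete rows, found {len(complete)}"
        )
    x = complete.iloc[:, 0].to_numpy(dtype=float)
    y = complete.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError(f"{path}: a column has zero variance; r is undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationSample(r=r, n=len(complete), n_dropped=n_dropped, source=str(path))
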