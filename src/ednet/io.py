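"""CSV/JSON ingestion and export for subscale matrices and results."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import CANONICAL_LABELS, SubscaleMatrix

__all__ = ["read_subscale_csv", "write_subscale_csv"]

logger = logging.getLogger(__name__)


def read_subscale_csv(path, labels=CANONICAL_LABELS) -> SubscaleMatrix:
    """Read a subject-by-subscale CSV into canonical column order.

    The header must contain every canonical label (any order) plus an
    optional ``group`` column.  Rows with missing cells are dropped listwise
    with a logged count; non-numeric cells raise with their location.
    """
    df = pd.read_csv(path)
    labels = list(labels)
    missing = [l for l in labels if l not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in labels and c != "group"]
    if unknown:
        raise ValueError(f"unknown column(s): {', '.join(unknown)}")

    for col in labels:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        df[col] = coerced

    complete = df[labels].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing cells", n_dropped)
    df = df.loc[complete]
    group = df["group"].to_numpy(dtype=object) if "group" in df.columns else None
    return SubscaleMatrix(
        values=df[labels].to_numpy(dtype=float), node_labels=labels, group=group
    )


def write_subscale_csv(data: SubscaleMatrix, path) -> None:
    """Write a SubscaleMatrix as UTF-8 CSV (labels header, optional group column)."""
    data.to_dataframe().to_csv(path, index=False)
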