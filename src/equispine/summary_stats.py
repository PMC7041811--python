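"""Percentile summaries of measurement means per path-surface condition.

For every kinematic parameter the 5th percentile, median and 95th
percentile are computed over all horses and all available repetitions,
pooled within each of the four conditions (hard straight, soft straight,
soft left lunge, soft right lunge).  Input is a measurement-mean table —
one value per trot-up — not per-stride data.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io_markers import CONDITIONS, parameter_columns

__all__ = ["percentile_summary"]


def percentile_summary(
    records: pd.DataFrame,
    params: Sequence[str] | None = None,
    probs: Sequence[float] = (0.05, 0.50, 0.95),
    method: str = "linear",
) -> pd.DataFrame:
    """Per-condition percentiles of measurement means.

    Parameters
    ----------
    records
        Measurement-mean table with a ``condition`` column (see
        :func:`equispine.io_markers.read_measurement_table`).
    params
        Parameter columns to summarise; defaults to every non-identifier
        column.
    probs
        Quantile probabilities, default (0.05, 0.50, 0.95).
    method
        Quantile interpolation rule passed to :func:`numpy.quantile`
        (default ``"linear"``, the usual type-7 linear interpolation of
        order statistics).

    Returns
    -------
    Tidy frame with columns ``parameter``, ``condition``, ``n`` and one
    column per probability (``p5``, ``median``, ``p95`` for the defaults).
    Conditions with no records are omitted with a warning.
    """
    if "condition" not in records.columns:
        raise ValueError("records must carry a 'condition' column")
    if params is None:
        params = parameter_columns(records)
    probs = list(probs)
    if sorted(probs) != probs:
        raise ValueError("probs must be sorted ascending")

    def colname(p: float) -> str:
        if p == 0.5:
            return "median"
        return f"p{100 * p:g}"

    rows = []
    for cond in CONDITIONS:
        sub = records[records["condition"] == cond]
        if sub.empty:
            warnings.warn(f"condition {cond!r} has no records; omitted",
                          stacklevel=2)
            continue
        for param in params:
            vals = sub[param].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                warnings.warn(
                    f"parameter {param!r} empty in condition {cond!r}; omitted",
                    stacklevel=2)
                continue
            q = np.quantile(vals, probs, method=method)
            row = {"parameter": param, "condition": cond, "n": vals.size}
            row.update({colname(p): float(v) for p, v in zip(probs, q)})
            rows.append(row)
    return pd.DataFrame(rows)
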