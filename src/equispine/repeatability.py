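"""Repeatability of measurement means: one-way intraclass correlation.

For each parameter and each path-surface condition, the measurement means
(non offset-adjusted) are modelled as ``value = intercept + horse + error``
with a random horse intercept (REML), and the ICC(1) is

    ICC = sigma2_horse / (sigma2_horse + sigma2_resid)

— the proportion of total variance attributable to differences between
horses.  An ICC near 1 means repeated trot-ups of a horse land almost on
top of each other relative to the spread between horses.  On balanced data
the REML estimate coincides with the classical one-way ANOVA estimator
ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW).

Estimates that would be negative are truncated to zero and flagged; the
ICC is unitless and invariant to affine rescaling of the parameter.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .io_markers import CONDITIONS, parameter_columns
from .variability_model import _fit_mixedlm

__all__ = ["icc_per_condition", "icc_pivot"]

#: Random-intercept variances below this fraction of the total are treated
#: as the boundary (zero) solution, i.e. a truncated negative estimate.
_BOUNDARY_FRAC = 1e-8


def _icc_one_cell(values: np.ndarray, horses: np.ndarray,
                  reml: bool = True) -> tuple[float, float, float, bool]:
    d = pd.DataFrame({"value": values, "horse": horses})
    model = MixedLM.from_formula("value ~ 1", groups="horse", data=d)
    res = _fit_mixedlm(model, reml=reml)
    var_h = float(np.squeeze(res.cov_re))
    var_r = float(res.scale)
    total = var_h + var_r
    truncated = total > 0 and var_h / total < _BOUNDARY_FRAC
    icc = 0.0 if truncated or total == 0 else var_h / total
    return float(np.clip(icc, 0.0, 1.0)), var_h, var_r, truncated


def icc_per_condition(
    records: pd.DataFrame,
    params: Sequence[str] | None = None,
    reml: bool = True,
    min_horses: int = 2,
    min_reps: int = 2,
) -> pd.DataFrame:
    """ICC(1) per parameter per path-surface condition.

    A cell needs at least ``min_horses`` horses with at least ``min_reps``
    repetitions each; otherwise the entry is marked unavailable
    (``available = False``, ICC = NaN) rather than raising.

    Returns a tidy frame with columns ``parameter``, ``condition``, ``icc``,
    ``var_horse``, ``var_resid``, ``truncated`` and ``available``.
    """
    if "condition" not in records.columns:
        raise ValueError("records must carry a 'condition' column")
    if params is None:
        params = parameter_columns(records)
    rows = []
    for cond in CONDITIONS:
        sub = records[records["condition"] == cond]
        for param in params:
            cell = sub.dropna(subset=[param])
            reps = cell.groupby("horse")[param].size()
            enough = (reps >= min_reps).sum() >= min_horses
            if not enough:
                rows.append({"parameter": param, "condition": cond,
                             "icc": np.nan, "var_horse": np.nan,
                             "var_resid": np.nan, "truncated": False,
                             "available": False})
                continue
            icc, vh, vr, trunc = _icc_one_cell(
                cell[param].to_numpy(float), cell["horse"].to_numpy(), reml)
            rows.append({"parameter": param, "condition": cond, "icc": icc,
                         "var_horse": vh, "var_resid": vr,
                         "truncated": trunc, "available": True})
    return pd.DataFrame(rows)


def icc_pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Wide parameter x condition ICC table with a column-mean footer row.

    Column means are the arithmetic means of the available entries, matching
    how a summary row under each condition column is usually reported.
    """
    wide = table.pivot(index="parameter", columns="condition", values="icc")
    wide = wide.reindex(columns=[c for c in CONDITIONS if c in wide.columns])
    means = wide.mean(axis=0, skipna=True)
    wide.loc["column_mean"] = means
    return wide
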