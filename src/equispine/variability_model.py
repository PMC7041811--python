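"""Between-measurement variability via an offset-adjusted mixed model.

The question this model answers: how much does a repeated trot-up of the
*same* horse under the *same* condition vary?  The procedure:

1. **Offset adjustment.**  For every horse x path x surface cell, subtract
   the mean of all that horse's measurements (M1-M12) from each measurement
   mean, centring each cell at zero.  What remains is pure
   between-measurement deviation ``d``.
2. **Transform.**  The outcome is ``y = sqrt(|d|)`` — absolute deviations
   are heavily right-skewed and the square root symmetrises the residuals.
3. **Mixed model.**  ``y`` is modelled with fixed effects for day (3-level
   factor, reference day one), within-day repetition index (numeric 1-5,
   capturing the tendency of variation to shrink over repetitions), path
   (reference straight) and surface (reference soft), with a random
   intercept per horse, fitted by REML.  No interactions (circles were
   never measured on the hard surface, so the design cannot support them)
   and no model reduction.  Speed can be added as a linear covariate.
4. **Prediction limits.**  A 95 % prediction upper limit per condition:
   ``limit_y = x'beta + z_0.975 * sqrt(sigma2_horse + sigma2_resid)`` on the
   sqrt scale — ``x`` encodes the condition at reference day one and the
   mean repetition index — back-transformed as ``limit = limit_y**2`` to
   the original units.  Deviations are zero-centred, so intervals are
   symmetric and only the upper limit is reported, plus the arithmetic mean
   over the four conditions ("mean variation").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .io_markers import CONDITIONS, condition_label, parameter_columns

__all__ = [
    "repetition_index",
    "offset_adjust",
    "VariabilityFit",
    "fit_variability_model",
    "fixed_effect_tests",
    "prediction_upper_limits",
]

_REFERENCE = {"day": "day1", "path": "straight", "surface": "soft"}

_CONDITION_FACTORS = {
    "hard_straight": {"path": "straight", "surface": "hard"},
    "soft_straight": {"path": "straight", "surface": "soft"},
    "soft_left": {"path": "lunge_left", "surface": "soft"},
    "soft_right": {"path": "lunge_right", "surface": "soft"},
}


def repetition_index(measurement_no: int | np.ndarray | pd.Series):
    """Within-day repetition index: M1-5 -> 1-5, M6-10 -> 1-5, M11-12 -> 1-2."""
    m = np.asarray(measurement_no, dtype=int)
    out = np.where(m <= 10, (m - 1) % 5 + 1, m - 10)
    if np.any((m < 1) | (m > 12)):
        raise ValueError("measurement_no must be in 1..12")
    return out if out.ndim else int(out)


def offset_adjust(
    records: pd.DataFrame,
    params: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Offset-adjusted long table of deviations.

    For each parameter, subtracts the horse x path x surface cell mean from
    every measurement mean, then attaches ``y = sqrt(|deviation|)``.
    Idempotent: adjusting already-adjusted deviations changes nothing.

    Returns a long frame with the identifier columns, ``rep_index``,
    ``condition``, ``parameter``, ``value``, ``deviation`` and ``y``; the
    raw measurement speed (if present) is carried along as a ``speed``
    covariate column for every parameter.
    """
    if params is None:
        params = parameter_columns(records)
    base_cols = ["horse", "day", "measurement_no", "path", "surface"]
    missing = [c for c in base_cols if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    df = records.copy()
    if "condition" not in df.columns:
        df["condition"] = [condition_label(p, s)
                           for p, s in zip(df["path"], df["surface"])]
    df["rep_index"] = repetition_index(df["measurement_no"])

    keep = base_cols + ["rep_index", "condition"]
    # speed is both a parameter and the optional covariate; carry the
    # covariate under a scratch name so melting keeps the outcome rows
    if "speed" in df.columns:
        df["_speed_cov"] = df["speed"]
        keep = keep + ["_speed_cov"]
    out = df.melt(id_vars=keep, value_vars=list(params),
                  var_name="parameter", value_name="value")
    if "_speed_cov" in out.columns:
        out = out.rename(columns={"_speed_cov": "speed"})
    out = out.dropna(subset=["value"])
    cell = out.groupby(["horse", "path", "surface", "parameter"])["value"]
    out["deviation"] = out["value"] - cell.transform("mean")
    out["y"] = np.sqrt(np.abs(out["deviation"]))
    return out.reset_index(drop=True)


@dataclass
class VariabilityFit:
    """REML fit of the variability model for one parameter."""

    parameter: str
    formula: str
    params: pd.Series          # fixed-effect estimates (sqrt scale)
    bse: pd.Series             # standard errors
    var_horse: float           # random-intercept variance (sqrt scale)
    var_resid: float           # residual variance (sqrt scale)
    n_obs: int
    n_horses: int
    rank: int
    rep_index_mean: float
    with_speed: bool
    speed_mean: float | None
    speed_mean_by_condition: Mapping[str, float] | None = None
    dropped_terms: tuple[str, ...] = ()
    df_method: str = "between-within"  # degrees-of-freedom approximation
    result: object = None      # statsmodels MixedLMResults

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (S-table style) for CSV/JSON export."""
        tests = fixed_effect_tests(self)
        tests.insert(0, "parameter", self.parameter)
        return tests


def _fit_mixedlm(model: MixedLM, reml: bool = True):
    """Fit a MixedLM robustly, keeping the best (restricted) likelihood.

    Near the zero-variance boundary (common here: offset adjustment removes
    most horse-level signal) statsmodels' default L-BFGS can either raise a
    singular-matrix error or silently converge to a spurious boundary point,
    so two optimizers are run and the fit with the higher criterion wins;
    derivative-free Powell is the fallback when both fail.
    """
    candidates = []
    last: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method)
            if np.isfinite(res.llf):
                candidates.append(res)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
        if len(candidates) >= 2:
            break
    if not candidates:
        raise last  # pragma: no cover - all optimizers failed
    return max(candidates, key=lambda r: r.llf)


def _aliased_columns(exog: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of linearly dependent design columns (QR with pivoting)."""
    from scipy.linalg import qr
    _, r, piv = qr(exog, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(exog.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_variability_model(
    devs: pd.DataFrame,
    parameter: str,
    with_speed: bool = False,
    reml: bool = True,
) -> VariabilityFit:
    """Fit the variability mixed model for one parameter.

    ``devs`` is the long output of :func:`offset_adjust`.  Fixed effects:
    day, repetition index, path, surface (+ optional linear speed); random
    intercept per horse; REML estimation.  Factors that do not vary in the
    data are dropped (recorded in ``dropped_terms``) so reduced designs —
    e.g. a single condition — remain fittable.  A rank-deficient design
    raises ``ValueError`` naming the aliased columns.
    """
    d = devs[devs["parameter"] == parameter].copy()
    if d.empty:
        raise ValueError(f"no records for parameter {parameter!r}")
    if d["horse"].nunique() < 2:
        raise ValueError("need at least 2 horses")

    terms: list[str] = []
    dropped: list[str] = []
    for factor in ("day", "path", "surface"):
        if d[factor].nunique() > 1:
            terms.append(f"C({factor}, Treatment('{_REFERENCE[factor]}'))")
        else:
            dropped.append(factor)
    if d["rep_index"].nunique() > 1:
        terms.append("rep_index")
    else:
        dropped.append("rep_index")
    speed_mean = None
    speed_by_cond = None
    if with_speed and parameter != "speed":
        if "speed" not in d.columns:
            raise ValueError("with_speed=True but records have no 'speed' column")
        terms.append("speed")
        speed_mean = float(d["speed"].mean())
        cond = [condition_label(p, s) for p, s in zip(d["path"], d["surface"])]
        speed_by_cond = d.groupby(cond)["speed"].mean().to_dict()
    formula = "y ~ " + (" + ".join(terms) if terms else "1")

    model = MixedLM.from_formula(formula, groups="horse", data=d)
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        aliased = _aliased_columns(exog, list(model.exog_names))
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")
    if float(np.var(d["y"])) < 1e-14:
        # Degenerate outcome (all deviations identical): both variance
        # components are exactly zero and the mixed model's GLS weighting is
        # undefined; plain least squares gives the exact fixed effects.
        import statsmodels.formula.api as smf
        result = smf.ols(formula, data=d).fit()
        return VariabilityFit(
            parameter=parameter, formula=formula,
            params=result.params, bse=result.bse * 0.0,
            var_horse=0.0, var_resid=0.0,
            n_obs=len(d), n_horses=d["horse"].nunique(),
            rank=exog.shape[1], rep_index_mean=float(d["rep_index"].mean()),
            with_speed=bool(speed_mean is not None), speed_mean=speed_mean,
            speed_mean_by_condition=speed_by_cond,
            dropped_terms=tuple(dropped), df_method="between-within",
            result=result)
    result = _fit_mixedlm(model, reml=reml)

    return VariabilityFit(
        parameter=parameter,
        formula=formula,
        params=result.fe_params,
        bse=result.bse_fe,
        var_horse=float(np.squeeze(result.cov_re)),
        var_resid=float(result.scale),
        n_obs=len(d),
        n_horses=d["horse"].nunique(),
        rank=exog.shape[1],
        rep_index_mean=float(d["rep_index"].mean()),
        with_speed=bool(speed_mean is not None),
        speed_mean=speed_mean,
        speed_mean_by_condition=speed_by_cond,
        dropped_terms=tuple(dropped),
        df_method="between-within",
        result=result,
    )


def fixed_effect_tests(fit: VariabilityFit, alpha: float = 0.05) -> pd.DataFrame:
    """Wald t-tests of the fixed effects.

    Denominator degrees of freedom use the between-within (containment)
    approximation ``df = n_obs - n_horses - (rank - 1)`` — every covariate in
    this design varies within horse.  This is a deliberate, flagged
    approximation standing in for a Satterthwaite calculation (``df_method``
    in the output); with the sizes typical here the two are close.
    Two-sided p-values; significance at ``alpha`` (default 0.05).
    """
    df = max(fit.n_obs - fit.n_horses - (fit.rank - 1), 1)
    t = fit.params / fit.bse
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({
        "term": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": t.to_numpy(),
        "df": df,
        "p": p,
        "significant": p < alpha,
        "df_method": fit.df_method,
    })


def prediction_upper_limits(
    fit: VariabilityFit,
    level: float = 0.95,
    use_t: bool = False,
) -> pd.DataFrame:
    """95 % prediction upper limit of |deviation| per condition.

    Computed on the sqrt scale as ``x'beta + q * sqrt(var_horse +
    var_resid)`` with ``x`` encoding each path-surface condition at the
    reference day (day one) and the mean repetition index (and mean speed
    when the model includes it), then squared back to the original units.
    ``q`` is the standard-normal quantile by default (``use_t=True``
    switches to a t quantile with the between-within df).  The arithmetic
    mean over the four conditions is appended as row ``mean_variation``.
    """
    rows = []
    for cond in CONDITIONS:
        row = {
            "day": _REFERENCE["day"],
            "rep_index": fit.rep_index_mean,
            **_CONDITION_FACTORS[cond],
        }
        if fit.with_speed:
            # evaluate at the condition's own typical speed: circles are
            # ridden slower than straights, so a common overall mean would
            # push the speed term into the condition contrasts
            by_cond = fit.speed_mean_by_condition or {}
            row["speed"] = by_cond.get(cond, fit.speed_mean)
        rows.append(row)
    newdata = pd.DataFrame(rows, index=list(CONDITIONS))
    mean_y = np.asarray(fit.result.predict(exog=newdata))

    q_prob = 1.0 - (1.0 - level) / 2.0
    if use_t:
        dof = max(fit.n_obs - fit.n_horses - (fit.rank - 1), 1)
        q = stats.t.ppf(q_prob, dof)
    else:
        q = stats.norm.ppf(q_prob)
    sd_tot = np.sqrt(fit.var_horse + fit.var_resid)
    limit_y = np.clip(mean_y + q * sd_tot, 0.0, None)
    limits = limit_y**2

    out = pd.DataFrame({"condition": list(CONDITIONS),
                        "limit_sqrt_scale": limit_y,
                        "upper_limit": limits})
    mean_row = pd.DataFrame({"condition": ["mean_variation"],
                             "limit_sqrt_scale": [np.nan],
                             "upper_limit": [float(np.mean(limits))]})
    return pd.concat([out, mean_row], ignore_index=True)
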