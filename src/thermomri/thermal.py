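"""Linear brain-temperature models of quantitative MRI parameters.

Each region x parameter is modelled as y = a + b*x with x the brain
temperature (deg C) and y the subject's region-mean parameter value, fitted
by OLS once including and once excluding the in vivo subjects.  The two
percentage-difference statistics quantify non-temperature effects:

* delta_star: measured mean in vivo value vs the value at 36.5 deg C
  predicted by the post-mortem-only fit, as a percentage of the in vivo
  mean.  Large values flag physiological post mortem changes (e.g. the
  perfusion-driven MD drop) that no temperature correction can explain.
* delta_double_star: model value at 4 deg C vs at 36.5 deg C from the
  post-mortem-only fit, as a percentage of the 36.5 deg C value — the pure
  temperature contribution over the attainable post mortem range.

The fitted slopes double as a temperature-correction rule: transport a
measured value along the line to a reference temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coefficients import PARAMETERS, REGIONS, get_row
from .synth import IN_VIVO_TEMPERATURE

__all__ = [
    "LinearTempModel",
    "DeltaStats",
    "fit_linear_model",
    "predict_at",
    "delta_star",
    "delta_double_star",
    "correct_to_temperature",
    "compare_fit_variants",
    "fit_all_models",
    "model_from_coefficients",
]

REFERENCE_COLD_TEMPERATURE = 4.0  # deg C, cooling-chamber temperature


@dataclass(frozen=True)
class LinearTempModel:
    """OLS fit y = a + b*temperature for one region x parameter."""

    intercept_a: float
    slope_b: float
    ci_a: float  # 95% half-width
    ci_b: float  # 95% half-width
    r2_adj: float
    p_value: float  # two-sided slope test (= Pearson correlation test)
    n_subjects: int
    includes_invivo: bool
    region: str = ""
    parameter_kind: str = ""

    def __post_init__(self):
        if self.ci_a < 0 or self.ci_b < 0:
            raise ValueError("CI half-widths must be non-negative")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.r2_adj > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


@dataclass(frozen=True)
class DeltaStats:
    """The percentage-difference statistics for one region x parameter."""

    delta_star: float  # %
    delta_double_star: float  # %


def fit_linear_model(values, temperatures, includes_invivo: bool,
                     region: str = "", parameter_kind: str = "") -> LinearTempModel:
    """Fit y = a + b*x by OLS with t-based 95% CIs.

    ``values`` are per-subject region means (one point per subject);
    ``temperatures`` the matching brain temperatures.  The p value is the
    two-sided t test of the slope, equivalent to the Pearson correlation
    test; r2_adj = 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(temperatures, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and temperatures must be 1D and equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all temperatures identical")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return LinearTempModel(
        intercept_a=float(res.params[0]),
        slope_b=float(res.params[1]),
        ci_a=float(res.params[0] - ci[0, 0]),
        ci_b=float(res.params[1] - ci[1, 0]),
        r2_adj=float(res.rsquared_adj),
        p_value=float(res.pvalues[1]),
        n_subjects=n,
        includes_invivo=includes_invivo,
        region=region,
        parameter_kind=parameter_kind,
    )


def model_from_coefficients(region: str, parameter: str, variant: str = "without_invivo",
                            table=None) -> LinearTempModel:
    """Wrap a packaged coefficient row as a :class:`LinearTempModel`.

    n_subjects reflects the study cohort (16 post mortem, +4 in vivo for
    the with-invivo variant)."""
    row = get_row(region, parameter, variant, table)
    return LinearTempModel(
        intercept_a=float(row["a"]),
        slope_b=float(row["b"]),
        ci_a=float(row["ci_a"]),
        ci_b=float(row["ci_b"]),
        r2_adj=float(row["r2_adj"]),
        p_value=float(row["p_value"]),
        n_subjects=20 if variant == "with_invivo" else 16,
        includes_invivo=(variant == "with_invivo"),
        region=region,
        parameter_kind=parameter,
    )


def predict_at(model: LinearTempModel, temperature: float) -> float:
    """Evaluate the fitted line a + b*temperature."""
    return float(model.intercept_a + model.slope_b * float(temperature))


def delta_star(model_without_invivo: LinearTempModel, measured_invivo_mean: float) -> float:
    """Percentage difference of the post-mortem-only prediction at
    36.5 deg C from the measured in vivo mean (in vivo mean = 100%).

    Positive when the post mortem extrapolation exceeds the in vivo value.
    """
    if model_without_invivo.includes_invivo:
        raise ValueError("delta_star is defined on the post-mortem-only fit")
    if measured_invivo_mean == 0:
        raise ValueError("measured in vivo mean must be nonzero")
    pred = predict_at(model_without_invivo, IN_VIVO_TEMPERATURE)
    return 100.0 * (pred - measured_invivo_mean) / measured_invivo_mean


def delta_double_star(model_without_invivo: LinearTempModel,
                      cold_temperature: float = REFERENCE_COLD_TEMPERATURE) -> float:
    """Percentage difference of the model value at 4 deg C from the value
    at 36.5 deg C (36.5 deg C value = 100%), post-mortem-only fit.

    Scale-invariant in the parameter's units (a ratio of line values).
    """
    if model_without_invivo.includes_invivo:
        raise ValueError("delta_double_star is defined on the post-mortem-only fit")
    ref = predict_at(model_without_invivo, IN_VIVO_TEMPERATURE)
    if ref == 0:
        raise ValueError("prediction at 36.5 deg C is zero; statistic undefined")
    cold = predict_at(model_without_invivo, cold_temperature)
    return 100.0 * (cold - ref) / ref


def correct_to_temperature(value: float, measured_temp: float, reference_temp: float,
                           model: LinearTempModel) -> float:
    """Transport a measured value along the fitted line to a reference
    temperature: value + b*(T_ref - T_meas).

    Exactly invertible (swap the temperatures) and additive in temperature.
    """
    if not np.isfinite(model.slope_b):
        raise ValueError("model slope must be finite")
    if not 0.0 <= reference_temp <= 40.0:
        import warnings

        warnings.warn("reference temperature outside [0, 40] deg C")
    return float(value + model.slope_b * (reference_temp - measured_temp))


def compare_fit_variants(model_with: LinearTempModel, model_without: LinearTempModel,
                         measured_invivo_mean: float | None = None) -> dict:
    """Contrast the with- and without-invivo fits at in vivo temperature.

    A discrepancy at 36.5 deg C indicates non-temperature physiological
    effects.  Returns predictions at 36.5 deg C, their difference (absolute
    and as % of the with-invivo prediction), whether the slope CIs overlap,
    and delta_star when the measured in vivo mean is supplied.
    """
    if model_with.region != model_without.region or \
            model_with.parameter_kind != model_without.parameter_kind:
        raise ValueError("models must describe the same region and parameter")
    pred_w = predict_at(model_with, IN_VIVO_TEMPERATURE)
    pred_wo = predict_at(model_without, IN_VIVO_TEMPERATURE)
    lo_w, hi_w = model_with.slope_b - model_with.ci_b, model_with.slope_b + model_with.ci_b
    lo_o, hi_o = model_without.slope_b - model_without.ci_b, model_without.slope_b + model_without.ci_b
    report = {
        "region": model_with.region,
        "parameter": model_with.parameter_kind,
        "prediction_with_invivo": pred_w,
        "prediction_without_invivo": pred_wo,
        "difference": pred_wo - pred_w,
        "difference_pct_of_with": 100.0 * (pred_wo - pred_w) / pred_w if pred_w != 0 else np.nan,
        "slope_cis_overlap": bool(max(lo_w, lo_o) <= min(hi_w, hi_o)),
    }
    if measured_invivo_mean is not None:
        report["delta_star"] = delta_star(model_without, measured_invivo_mean)
    return report


def fit_all_models(summaries: pd.DataFrame, regions=REGIONS, parameters=PARAMETERS) -> pd.DataFrame:
    """Fit both variants for every region x parameter in a cohort table.

    ``summaries`` is the tidy cohort schema (subject_id, cohort,
    temperature_C, region, parameter, mean, ...).  Returns one row per
    region x parameter x variant with coefficients, CIs, r2_adj, p, and the
    delta statistics (delta_star needs >= 1 in vivo subject).
    """
    rows = []
    for region in regions:
        for parameter in parameters:
            sub = summaries[(summaries["region"] == region)
                            & (summaries["parameter"] == parameter)]
            if sub.empty:
                continue
            pm = sub[sub["cohort"] == "post_mortem"]
            models = {}
            for variant, data in (("with_invivo", sub), ("without_invivo", pm)):
                if variant == "with_invivo" and (sub["cohort"] == "in_vivo").sum() == 0:
                    continue
                if len(data) < 3:
                    continue
                models[variant] = fit_linear_model(
                    data["mean"].to_numpy(), data["temperature_C"].to_numpy(),
                    includes_invivo=(variant == "with_invivo"),
                    region=region, parameter_kind=parameter)
            iv = sub[sub["cohort"] == "in_vivo"]
            invivo_mean = float(iv["mean"].mean()) if len(iv) else np.nan
            for variant, m in models.items():
                row = {
                    "region": region, "parameter": parameter, "variant": variant,
                    "a": m.intercept_a, "ci_a": m.ci_a, "b": m.slope_b, "ci_b": m.ci_b,
                    "r2_adj": m.r2_adj, "p_value": m.p_value, "n_subjects": m.n_subjects,
                }
                if variant == "without_invivo":
                    row["delta_double_star_pct"] = delta_double_star(m)
                    if np.isfinite(invivo_mean) and invivo_mean != 0:
                        row["delta_star_pct"] = delta_star(m, invivo_mean)
                rows.append(row)
    return pd.DataFrame(rows)
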