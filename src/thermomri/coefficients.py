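"""Packaged linear temperature-model coefficients.

The package ships a transcription of the study's fitted linear models
y = a + b*x (x = brain temperature in deg C) for every combination of brain
region (white matter, cerebral cortex, deep gray matter and its four
segmented subregions), MRI parameter (T1, T2, T2* in ms; MD in mm^2/s;
FA dimensionless) and fit variant (with / without the in vivo subjects).
Each row carries 95% CI half-widths on a and b, the adjusted R^2, the
Pearson p value, and the printed percentage-difference statistics
(delta_star on with-invivo rows, delta_double_star on without-invivo rows).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "PARAMETERS",
    "VARIANTS",
    "DEEP_GRAY_SUBREGIONS",
    "load_coefficient_table",
    "get_row",
    "ground_truth_value",
]

REGIONS = (
    "white_matter",
    "cerebral_cortex",
    "deep_gray_matter",
    "globus_pallidus",
    "putamen",
    "caudate_nucleus",
    "thalamus",
)
DEEP_GRAY_SUBREGIONS = ("globus_pallidus", "putamen", "caudate_nucleus", "thalamus")
PARAMETERS = ("T1", "T2", "T2star", "MD", "FA")
VARIANTS = ("with_invivo", "without_invivo")

_TABLE_CACHE: pd.DataFrame | None = None


def load_coefficient_table() -> pd.DataFrame:
    """Load the packaged coefficient table as a DataFrame.

    Columns: region, parameter, variant, a, ci_a, b, ci_b, r2_adj, p_value,
    p_is_upper_bound, delta_star_pct, delta_double_star_pct.
    """
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        with resources.files("thermomri.data").joinpath("temperature_models.csv").open() as fh:
            df = pd.read_csv(fh)
        df["p_is_upper_bound"] = df["p_is_upper_bound"].astype(bool)
        expected = len(REGIONS) * len(PARAMETERS) * len(VARIANTS)
        if len(df) != expected:
            raise RuntimeError(f"coefficient table incomplete: {len(df)} rows, expected {expected}")
        _TABLE_CACHE = df
    return _TABLE_CACHE.copy()


def get_row(region: str, parameter: str, variant: str = "without_invivo",
            table: pd.DataFrame | None = None) -> pd.Series:
    """Return the coefficient row for (region, parameter, variant)."""
    if table is None:
        table = load_coefficient_table()
    sel = table[
        (table["region"] == region)
        & (table["parameter"] == parameter)
        & (table["variant"] == variant)
    ]
    if len(sel) != 1:
        raise KeyError(f"no unique row for ({region!r}, {parameter!r}, {variant!r})")
    return sel.iloc[0]


def ground_truth_value(region: str, parameter: str, temperature: float,
                       table: pd.DataFrame | None = None,
                       variant: str = "without_invivo") -> float:
    """Evaluate the linear model a + b * temperature for the selected row.

    This is the generating value used by the phantom and cohort simulators:
    the expected region mean of ``parameter`` at the given brain temperature
    (deg C) under the chosen fit variant.
    """
    row = get_row(region, parameter, variant, table)
    return float(row["a"] + row["b"] * float(temperature))


def table_as_array(table: pd.DataFrame | None = None) -> np.ndarray:
    """(a, b) pairs for all rows, mainly for vectorized checks."""
    if table is None:
        table = load_coefficient_table()
    return table[["a", "b"]].to_numpy(dtype=float)
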