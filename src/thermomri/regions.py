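"""Region-wise aggregation with partial-volume control.

Voxels whose tissue partial-volume fraction falls below 1 are excluded;
residual contamination on parameter maps is then removed by Otsu
thresholding (maximizing between-class variance) applied per region per
map.  Remaining voxels are averaged into per-subject region summaries, the
unit of the downstream temperature analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .coefficients import PARAMETERS, REGIONS
from .synth import LabelVolume, SubjectSpec

__all__ = [
    "RegionSummary",
    "exclude_partial_volume",
    "otsu_threshold",
    "apply_otsu_exclusion",
    "summarize_region",
    "summarize_subject",
]


@dataclass(frozen=True)
class RegionSummary:
    """Per-subject, per-region, per-parameter aggregate."""

    subject_id: str
    region: str
    parameter_kind: str
    mean: float
    sd: float
    n_voxels: int
    temperature: float  # deg C

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("reported summaries need n_voxels >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def exclude_partial_volume(pv_map, threshold: float = 1.0) -> np.ndarray:
    """Mask of voxels free of partial-volume effects: pv >= threshold.

    The default keeps only voxels with fraction exactly 1 ("values below 1
    in the partial volume maps" are excluded); a lower threshold relaxes
    the rule.
    """
    pv = np.asarray(pv_map, dtype=float)
    if pv.size and (pv.min() < 0 or pv.max() > 1 + 1e-9):
        raise ValueError("partial-volume fractions must lie in [0, 1]")
    return pv >= threshold


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance (Otsu).

    Candidate thresholds are the interior bin edges of an ``n_bins``
    histogram; the returned edge maximizes
    sigma_b^2(k) = w1 w2 (mu1 - mu2)^2.  Between well-separated modes the
    objective is exactly flat (empty bins), so ties are broken at the
    midpoint of the maximal plateau, placing the threshold mid-gap.
    Deterministic; raises on constant input, for which no two classes
    exist.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    hist, edges = np.histogram(v, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w1 = np.cumsum(hist)[:-1].astype(float)  # split k: bins [0,k) vs [k,n)
    w2 = v.size - w1
    csum = np.cumsum(hist * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = csum[:-1] / w1
        mu2 = (csum[-1] - csum[:-1]) / w2
        var_between = w1 * w2 * (mu1 - mu2) ** 2
    var_between = np.where((w1 > 0) & (w2 > 0), var_between, -np.inf)
    ties = np.flatnonzero(var_between == var_between.max())
    k = ties[ties.size // 2] + 1  # threshold at edge between bins k-1 and k
    return float(edges[k])


def _separability(values: np.ndarray, thr: float) -> float:
    """Otsu separability: between-class variance / total variance."""
    lo = values <= thr
    w1 = lo.mean()
    w2 = 1.0 - w1
    if w1 == 0 or w2 == 0:
        return 0.0
    mu1 = values[lo].mean()
    mu2 = values[~lo].mean()
    total = values.var()
    if total == 0:
        return 0.0
    return float(w1 * w2 * (mu1 - mu2) ** 2 / total)


def apply_otsu_exclusion(map_values, mask, keep_rule: str = "majority",
                         n_bins: int = 256, max_discard_frac: float = 0.5,
                         min_separability: float = 0.7) -> np.ndarray:
    """Refine a region mask by dropping the Otsu-rejected class.

    ``keep_rule`` selects which side of the threshold survives:
    "majority" (default) keeps the larger class, "lower"/"upper" force a
    side.  Two guards protect unimodal maps, where Otsu has nothing to
    separate: if the threshold would discard more than
    ``max_discard_frac`` of the region, or the between-class variance
    explains less than ``min_separability`` of the total variance, the
    original mask is kept unchanged (with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(map_values, dtype=float)[mask]
    finite = np.isfinite(vals)
    if finite.sum() < 2 or np.unique(vals[finite]).size < 2:
        return mask.copy()
    vf = vals[finite]
    thr = otsu_threshold(vf, n_bins=n_bins)
    if _separability(vf, thr) < min_separability:
        warnings.warn("Otsu separability too low (unimodal map); mask kept unchanged")
        return mask.copy()
    low_frac = float((vf <= thr).mean())
    if keep_rule == "majority":
        keep_low = low_frac >= 0.5
    elif keep_rule == "lower":
        keep_low = True
    elif keep_rule == "upper":
        keep_low = False
    else:
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    discard_frac = (1.0 - low_frac) if keep_low else low_frac
    if discard_frac > max_discard_frac:
        warnings.warn("Otsu threshold would discard most of the region; mask kept unchanged")
        return mask.copy()
    refined = mask.copy()
    with np.errstate(invalid="ignore"):
        side = (np.asarray(map_values, dtype=float) <= thr) if keep_low else \
               (np.asarray(map_values, dtype=float) > thr)
    refined &= side
    refined &= np.isfinite(np.asarray(map_values, dtype=float))
    return refined


def summarize_region(map_values, mask, region: str, subject: SubjectSpec,
                     parameter_kind: str) -> RegionSummary:
    """Arithmetic mean and SD of a parameter map over retained voxels.

    Invalid (NaN) voxels are excluded; the mask must retain at least one
    finite voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(map_values, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no valid voxels for region {region!r}")
    return RegionSummary(
        subject_id=subject.subject_id,
        region=region,
        parameter_kind=parameter_kind,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)) if vals.size > 1 else 0.0,
        n_voxels=int(vals.size),
        temperature=subject.brain_temperature,
    )


def summarize_subject(maps: dict, label_vol: LabelVolume, subject: SubjectSpec,
                      pv_threshold: float = 1.0, use_otsu: bool = True,
                      keep_rule: str = "majority", regions=REGIONS,
                      parameters=PARAMETERS) -> tuple:
    """Aggregate all regions x parameters for one subject.

    ``maps`` maps parameter kind -> :class:`~thermomri.relaxfit.VoxelMap`
    (or bare array).  Returns ``(DataFrame, exclusion_log)`` where the log
    records voxel counts removed by each exclusion rule per region/map.
    """
    rows = []
    log = []
    for region in regions:
        region_mask = label_vol.region_mask(region)
        pv = label_vol.region_pv(region)
        pv_mask = region_mask & exclude_partial_volume(pv, pv_threshold)
        if not pv_mask.any():
            continue
        for parameter in parameters:
            if parameter not in maps:
                continue
            vm = maps[parameter]
            values = vm.values if hasattr(vm, "values") else np.asarray(vm, dtype=float)
            mask = pv_mask
            n_pv_excluded = int(region_mask.sum() - pv_mask.sum())
            n_otsu_excluded = 0
            if use_otsu:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    refined = apply_otsu_exclusion(values, mask, keep_rule=keep_rule)
                n_otsu_excluded = int(mask.sum() - refined.sum())
                mask = refined
            try:
                summary = summarize_region(values, mask, region, subject, parameter)
            except ValueError:
                continue
            rows.append(asdict(summary))
            log.append({
                "subject_id": subject.subject_id,
                "region": region,
                "parameter": parameter,
                "n_region": int(region_mask.sum()),
                "n_pv_excluded": n_pv_excluded,
                "n_otsu_excluded": n_otsu_excluded,
                "n_retained": int(summary.n_voxels),
            })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.rename(columns={"parameter_kind": "parameter", "temperature": "temperature_C"})
        df["cohort"] = subject.cohort
    return df, pd.DataFrame(log)
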