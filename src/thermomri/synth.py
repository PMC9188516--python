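"""Synthetic data generation: forward signal models, Rician noise, a labeled
brain phantom, and cohort-level region-mean datasets.

The phantom is a set of nested geometric compartments (not anatomical): a
cortical shell around a white-matter sphere containing four deep-gray nuclei
and a central CSF cavity.  Every labeled voxel carries ground-truth T1, T2,
T2*, M0, inversion-efficiency p and a diffusion tensor; quantitative values
derive from the packaged linear temperature models evaluated at the
subject's brain temperature, plus configurable within-region variation.

Cohorts emulate the study population: 16 post mortem subjects whose brain
temperatures follow a truncated normal (mean 12.7, SD 5.7, range
5.6-28.1 deg C) plus 4 in vivo subjects fixed at 36.5 deg C, with region
means scattered around the generating lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coefficients import (
    DEEP_GRAY_SUBREGIONS,
    PARAMETERS,
    REGIONS,
    ground_truth_value,
    load_coefficient_table,
    get_row,
)
from .protocol import AcquisitionProtocol

__all__ = [
    "LABEL_CODES",
    "SubjectSpec",
    "LabelVolume",
    "GroundTruthMaps",
    "simulate_ir_se_signal",
    "simulate_monoexp_signal",
    "simulate_dwi_signal",
    "add_rician_noise",
    "tensor_from_md_fa",
    "generate_phantom",
    "simulate_subject_signals",
    "sample_post_mortem_temperatures",
    "residual_sd_from_ci",
    "generate_cohort",
    "IN_VIVO_TEMPERATURE",
]

IN_VIVO_TEMPERATURE = 36.5  # deg C, assumed brain temperature of living subjects

# fixed region vocabulary; 0 is background
LABEL_CODES = {
    "background": 0,
    "white_matter": 1,
    "cerebral_cortex": 2,
    "globus_pallidus": 3,
    "putamen": 4,
    "caudate_nucleus": 5,
    "thalamus": 6,
    "csf": 7,
}
CODE_TO_REGION = {v: k for k, v in LABEL_CODES.items()}

# Nominal CSF properties (CSF is excluded from the temperature analysis; the
# phantom needs plausible values only so that partial-volume contamination
# has somewhere to come from).  T1/T2/T2* ms, MD mm^2/s.
CSF_VALUES = {"T1": 4000.0, "T2": 1800.0, "T2star": 160.0, "MD": 2.0e-3, "FA": 0.02}

# proton-density-like M0 weights per tissue (arbitrary units)
M0_VALUES = {
    "white_matter": 700.0,
    "cerebral_cortex": 850.0,
    "globus_pallidus": 800.0,
    "putamen": 820.0,
    "caudate_nucleus": 830.0,
    "thalamus": 810.0,
    "csf": 1000.0,
}

# principal diffusion axis per tissue (WM is coherently oriented; gray
# matter tensors are nearly isotropic so the axis matters little)
_PRINCIPAL_AXES = {
    "white_matter": (1.0, 0.0, 0.0),
    "cerebral_cortex": (0.0, 1.0, 0.0),
    "globus_pallidus": (0.0, 0.0, 1.0),
    "putamen": (1.0, 0.0, 0.0),
    "caudate_nucleus": (0.0, 1.0, 0.0),
    "thalamus": (0.0, 0.0, 1.0),
    "csf": (1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject: identity, cohort arm and brain temperature."""

    subject_id: str
    cohort: str  # "post_mortem" | "in_vivo"
    brain_temperature: float  # deg C
    seed: int = 0

    def __post_init__(self):
        if self.cohort not in ("post_mortem", "in_vivo"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "in_vivo" and self.brain_temperature != IN_VIVO_TEMPERATURE:
            raise ValueError("in vivo subjects are assigned 36.5 deg C exactly")
        if not 0.0 < self.brain_temperature < 45.0:
            raise ValueError("brain temperature out of plausible range")


@dataclass
class LabelVolume:
    """Integer region labels plus per-tissue partial-volume fraction maps."""

    labels: np.ndarray  # 3D int array of LABEL_CODES values
    voxel_size: tuple = (1.0, 1.0, 1.0)  # mm
    pv_maps: dict = field(default_factory=dict)  # region name -> float map in [0,1]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - set(LABEL_CODES.values())
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")
        if self.pv_maps:
            total = np.zeros(self.labels.shape, dtype=float)
            for name, pv in self.pv_maps.items():
                pv = np.asarray(pv, dtype=float)
                if pv.min() < 0 or pv.max() > 1:
                    raise ValueError(f"pv map {name!r} outside [0, 1]")
                total += pv
            if total.max() > 1.0 + 1e-6:
                raise ValueError("per-voxel partial-volume fractions exceed 1")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of a region; deep_gray_matter is the union of its
        segmented subregions."""
        if region == "deep_gray_matter":
            codes = [LABEL_CODES[r] for r in DEEP_GRAY_SUBREGIONS]
            return np.isin(self.labels, codes)
        return self.labels == LABEL_CODES[region]

    def region_pv(self, region: str) -> np.ndarray:
        if region == "deep_gray_matter":
            return sum(self.pv_maps[r] for r in DEEP_GRAY_SUBREGIONS)
        return self.pv_maps[region]


@dataclass
class GroundTruthMaps:
    """Voxel-wise generating parameters of the phantom."""

    t1_map: np.ndarray  # ms
    t2_map: np.ndarray  # ms
    t2s_map: np.ndarray  # ms
    tensor_map: np.ndarray  # (..., 3, 3) mm^2/s, symmetric PSD
    m0_map: np.ndarray  # a.u.
    p_map: np.ndarray  # dimensionless, in (0, 2]

    def md_map(self) -> np.ndarray:
        return np.trace(self.tensor_map, axis1=-2, axis2=-1) / 3.0

    def fa_map(self) -> np.ndarray:
        from .dtifit import fa_from_eigenvalues

        evals = np.linalg.eigvalsh(self.tensor_map)
        return fa_from_eigenvalues(evals[..., ::-1])


# ---------------------------------------------------------------------------
# forward signal models
# ---------------------------------------------------------------------------

def simulate_ir_se_signal(m0, p_factor, t1, t2, ti, te, tr):
    """Signed IR-SE signal S = M0 exp(-TE/T2) (1 - p exp(-TI/T1) + exp(-TR/T1)).

    The factor p absorbs B1 errors from imperfect 180 deg inversion pulses
    (p = 2 is perfect inversion, p = 0 removes the inversion term).  Inputs
    broadcast; times in ms.  Returns the noiseless signed model value.
    """
    m0 = np.asarray(m0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    for name, v in (("t1", t1), ("t2", t2)):
        if np.any(v <= 0):
            raise ValueError(f"{name} must be strictly positive")
    for name, v in (("ti", ti), ("te", te), ("tr", tr)):
        if np.any(np.asarray(v, dtype=float) <= 0):
            raise ValueError(f"{name} must be strictly positive")
    if np.any(m0 < 0):
        raise ValueError("m0 must be non-negative")
    ti = np.asarray(ti, dtype=float)
    recovery = 1.0 - np.asarray(p_factor, dtype=float) * np.exp(-ti / t1) + np.exp(-tr / t1)
    out = m0 * np.exp(-np.asarray(te, dtype=float) / t2) * recovery
    return out if out.ndim else float(out)


def simulate_monoexp_signal(s0, t2_or_t2s, te):
    """Mono-exponential decay S = S0 exp(-TE/T2); forward model of the
    two-parameter T2 / T2* fits."""
    s0 = np.asarray(s0, dtype=float)
    t2 = np.asarray(t2_or_t2s, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("s0 must be non-negative")
    if np.any(t2 <= 0):
        raise ValueError("decay constant must be strictly positive")
    if np.any(te < 0):
        raise ValueError("te must be non-negative")
    out = s0 * np.exp(-te / t2)
    return out if out.ndim else float(out)


def simulate_dwi_signal(s0, tensor, b_value, direction):
    """Diffusion tensor signal S = S0 exp(-b g^T D g) for unit direction g."""
    tensor = np.asarray(tensor, dtype=float)
    g = np.asarray(direction, dtype=float)
    if tensor.shape[-2:] != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(tensor, np.swapaxes(tensor, -1, -2), atol=1e-12):
        raise ValueError("tensor must be symmetric")
    if abs(np.linalg.norm(g) - 1.0) > 1e-6 and b_value != 0:
        raise ValueError("direction must be unit-norm")
    adc = np.einsum("i,...ij,j->...", g, tensor, g)
    out = np.asarray(s0, dtype=float) * np.exp(-float(b_value) * adc)
    return out if np.ndim(out) else float(out)


def add_rician_noise(signal, sigma, rng=None):
    """Magnitude of (signal + n1 + i n2) with iid N(0, sigma^2) noise.

    This is the noise model of MRI magnitude images; sigma = 0 returns the
    magnitude of the noiseless signal.  ``rng`` may be a seed or Generator.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        out = np.abs(signal)
        return out if out.ndim else float(out)
    rng = np.random.default_rng(rng)
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    out = np.hypot(re, im)
    return out if out.ndim else float(out)


def tensor_from_md_fa(md, fa, axis=(1.0, 0.0, 0.0)):
    """Axially symmetric (prolate) tensor with the requested MD and FA.

    Eigenvalues are md*(1+2*delta) along ``axis`` and md*(1-delta)
    transverse, with delta = fa*sqrt(3/(9-6*fa^2)); fa=0 gives md*I, fa=1 a
    stick tensor.  Requires 0 <= fa <= 1 and md >= 0.
    """
    md = float(md)
    fa = float(fa)
    if md < 0:
        raise ValueError("md must be non-negative")
    if not 0.0 <= fa <= 1.0:
        raise ValueError("fa must lie in [0, 1]")
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa * fa))
    lam_par = md * (1.0 + 2.0 * delta)
    lam_perp = md * (1.0 - delta)
    e1 = np.asarray(axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(e1, e1)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

def _default_layout() -> dict:
    """Normalized-coordinate layout of the nested-compartment phantom."""
    return {
        "cortex_outer": 0.95,
        "cortex_inner": 0.70,
        "csf_radius": 0.15,
        "nucleus_radius": 0.22,
        "nucleus_centers": {
            "globus_pallidus": (0.42, 0.0, 0.0),
            "putamen": (-0.42, 0.0, 0.0),
            "caudate_nucleus": (0.0, 0.42, 0.0),
            "thalamus": (0.0, -0.42, 0.0),
        },
    }


def _build_labels(shape, layout) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    labels = np.zeros(shape, dtype=np.int16)
    labels[(r <= layout["cortex_outer"]) & (r > layout["cortex_inner"])] = LABEL_CODES["cerebral_cortex"]
    labels[r <= layout["cortex_inner"]] = LABEL_CODES["white_matter"]
    for region, c in layout["nucleus_centers"].items():
        d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        labels[d <= layout["nucleus_radius"]] = LABEL_CODES[region]
    labels[r <= layout["csf_radius"]] = LABEL_CODES["csf"]
    return labels


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-neighbor of a different label."""
    boundary = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        diff = np.diff(labels, axis=ax) != 0
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        boundary[tuple(sl_lo)] |= diff
        boundary[tuple(sl_hi)] |= diff
    return boundary


def generate_phantom(shape=(32, 32, 32), region_layout=None, subject: SubjectSpec | None = None,
                     coefficient_table: pd.DataFrame | None = None,
                     variant: str = "without_invivo", cv: float = 0.03,
                     boundary_pv: float = 0.6, voxel_size=(1.0, 1.0, 1.0),
                     rng=None):
    """Build a labeled phantom and its ground-truth parameter maps.

    Every labeled voxel takes its region's linear-model value at the
    subject's brain temperature, perturbed by multiplicative Gaussian
    within-region variation of coefficient-of-variation ``cv``.  Voxels on
    compartment boundaries receive partial-volume fraction ``boundary_pv``
    (< 1) for their own tissue; interior voxels have fraction 1.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError("phantom shape must be 3D with >= 16 voxels per axis")
    if subject is None:
        subject = SubjectSpec("phantom", "post_mortem", 12.7, seed=0)
    if coefficient_table is None:
        coefficient_table = load_coefficient_table()
    layout = region_layout or _default_layout()
    rng = np.random.default_rng(subject.seed if rng is None else rng)

    labels = _build_labels(shape, layout)
    boundary = _boundary_mask(labels)

    # partial-volume fraction maps per tissue
    pv_maps = {}
    remainder = 1.0 - boundary_pv
    for name, code in LABEL_CODES.items():
        if name == "background":
            continue
        own = labels == code
        pv = np.zeros(shape, dtype=float)
        pv[own & ~boundary] = 1.0
        pv[own & boundary] = boundary_pv
        pv_maps[name] = pv
    # split the remainder of boundary voxels across neighboring tissues is
    # not needed downstream; assign it to background-equivalent "mixture"
    # implicitly (fractions then sum to <= 1).
    label_vol = LabelVolume(labels=labels, voxel_size=tuple(voxel_size), pv_maps=pv_maps)

    def region_values(region, parameter, n):
        base = (CSF_VALUES[parameter] if region == "csf"
                else ground_truth_value(region, parameter, subject.brain_temperature,
                                        coefficient_table, variant))
        if cv > 0:
            vals = base * (1.0 + cv * rng.standard_normal(n))
        else:
            vals = np.full(n, base)
        return vals

    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    t2s = np.zeros(shape)
    m0 = np.zeros(shape)
    p = np.zeros(shape)
    tensors = np.zeros(shape + (3, 3))

    for name, code in LABEL_CODES.items():
        if name == "background":
            continue
        mask = labels == code
        n = int(mask.sum())
        if n == 0:
            continue
        t1[mask] = np.maximum(region_values(name, "T1", n), 1.0)
        t2[mask] = np.maximum(region_values(name, "T2", n), 1.0)
        t2s[mask] = np.maximum(region_values(name, "T2star", n), 1.0)
        m0[mask] = M0_VALUES[name] * (1.0 + (cv * rng.standard_normal(n) if cv > 0 else 0.0))
        p[mask] = 2.0
        md_vals = np.maximum(region_values(name, "MD", n), 1e-6)
        fa_vals = np.clip(region_values(name, "FA", n), 0.0, 0.99)
        axis = _PRINCIPAL_AXES[name]
        idx = np.argwhere(mask)
        for k in range(n):
            tensors[tuple(idx[k])] = tensor_from_md_fa(md_vals[k], fa_vals[k], axis)

    gt = GroundTruthMaps(t1_map=t1, t2_map=t2, t2s_map=t2s, tensor_map=tensors,
                         m0_map=m0, p_map=p)
    return label_vol, gt


def simulate_subject_signals(label_vol: LabelVolume, gt: GroundTruthMaps,
                             protocol: AcquisitionProtocol, noise_sigma: float = 0.0,
                             rng=None) -> dict:
    """Simulate the full multi-contrast acquisition for a phantom subject.

    Returns magnitude (Rician-noised) 4D arrays keyed by sequence:
    ``ir`` (n_TI), ``se`` (n_TE), ``gre`` (n_TE) and ``dwi``
    (n_b0 + n_directions volumes, b=0 first).  ``noise_sigma`` is in signal
    units (the phantom's M0 is ~1e3 a.u.).
    """
    rng = np.random.default_rng(rng)
    fg = label_vol.labels > 0
    shape = label_vol.labels.shape

    def noised(x):
        return add_rician_noise(x, noise_sigma, rng)

    ir = np.zeros(shape + (len(protocol.ti_list),))
    for j, ti in enumerate(protocol.ti_list):
        ir[fg, j] = simulate_ir_se_signal(gt.m0_map[fg], gt.p_map[fg], gt.t1_map[fg],
                                          gt.t2_map[fg], ti, protocol.ir_te, protocol.ir_tr)
    se = np.zeros(shape + (len(protocol.se_te_list),))
    for j, te in enumerate(protocol.se_te_list):
        se[fg, j] = simulate_monoexp_signal(gt.m0_map[fg], gt.t2_map[fg], te)
    gre = np.zeros(shape + (len(protocol.gre_te_list),))
    for j, te in enumerate(protocol.gre_te_list):
        gre[fg, j] = simulate_monoexp_signal(gt.m0_map[fg], gt.t2s_map[fg], te)

    n_vols = protocol.n_b0 + protocol.n_directions
    dwi = np.zeros(shape + (n_vols,))
    s0_dwi = gt.m0_map[fg] * np.exp(-protocol.dwi_te / np.maximum(gt.t2_map[fg], 1.0))
    for j in range(protocol.n_b0):
        dwi[fg, j] = s0_dwi
    tensors_fg = gt.tensor_map[fg]
    for j, g in enumerate(protocol.gradient_set):
        adc = np.einsum("i,nij,j->n", g, tensors_fg, g)
        dwi[fg, protocol.n_b0 + j] = s0_dwi * np.exp(-protocol.b_value * adc)

    return {"ir": noised(ir), "se": noised(se), "gre": noised(gre), "dwi": noised(dwi)}


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def sample_post_mortem_temperatures(n, mean=12.7, sd=5.7, low=5.6, high=28.1, rng=None):
    """Draw brain temperatures from a truncated normal on [low, high]."""
    if not (0.0 < low < high < 37.0):
        raise ValueError("temperature range must lie within (0, 37) deg C")
    if high < mean - 5 * sd or low > mean + 5 * sd:
        raise ValueError("truncation range excludes mean +/- 5 SD: infeasible")
    a, b = (low - mean) / sd, (high - mean) / sd
    rng = np.random.default_rng(rng)
    # inverse-CDF sampling (equivalent to truncnorm.rvs, much lower overhead)
    from scipy.special import ndtr, ndtri

    u = rng.uniform(ndtr(a), ndtr(b), size=n)
    return mean + sd * ndtri(u)


def residual_sd_from_ci(ci_b: float, n: int, sxx: float) -> float:
    """Back out the regression residual SD implied by a slope CI half-width.

    ci_b = t_{0.975, n-2} * s / sqrt(Sxx)  =>  s = ci_b * sqrt(Sxx) / t.
    Used to anchor cohort noise to the printed slope uncertainties.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    t_crit = stats.t.ppf(0.975, n - 2)
    return float(ci_b) * np.sqrt(sxx) / t_crit


def generate_cohort(n_post_mortem: int = 16, n_in_vivo: int = 4,
                    temp_mean: float = 12.7, temp_sd: float = 5.7,
                    temp_range: tuple = (5.6, 28.1),
                    residual_sd_table: dict | None = None,
                    coefficient_table: pd.DataFrame | None = None,
                    variant: str = "without_invivo",
                    invivo_scale=1.0,
                    n_voxels_nominal: int = 400,
                    seed: int = 0):
    """Generate a cohort of subjects with per-region parameter means.

    Region means are drawn as (linear-model value at the subject's
    temperature) + Gaussian residual.  Residual SDs come from
    ``residual_sd_table`` (keys (region, parameter)) when given, otherwise
    from the printed slope-CI half-widths via :func:`residual_sd_from_ci`.
    ``invivo_scale`` multiplies the in vivo generating values (a dict keyed
    by parameter, or a scalar); values != 1 emulate physiological
    post-mortem offsets such as the perfusion-driven MD drop.

    Returns ``(subjects, summaries)`` with ``summaries`` a tidy DataFrame
    (subject_id, cohort, temperature_C, region, parameter, mean, sd,
    n_voxels).  Generation is seed-reproducible and each subject's rows
    depend only on the master seed and the subject's index.
    """
    if n_post_mortem < 3:
        raise ValueError("need >= 3 post mortem subjects for downstream fitting")
    if coefficient_table is None:
        coefficient_table = load_coefficient_table()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_post_mortem + n_in_vivo)

    # temperatures: each post-mortem subject draws from its own stream so
    # the cohort is invariant to subject ordering
    temps = [
        float(sample_post_mortem_temperatures(
            1, temp_mean, temp_sd, temp_range[0], temp_range[1],
            rng=np.random.default_rng(children[i]))[0])
        for i in range(n_post_mortem)
    ] + [IN_VIVO_TEMPERATURE] * n_in_vivo

    pm_temps = np.asarray(temps[:n_post_mortem])
    sxx = float(np.sum((pm_temps - pm_temps.mean()) ** 2))

    # resolve generating coefficients and residual SDs once
    gen = {}
    for region in REGIONS:
        for parameter in PARAMETERS:
            row = get_row(region, parameter, variant, coefficient_table)
            if residual_sd_table is not None and (region, parameter) in residual_sd_table:
                sd = residual_sd_table[(region, parameter)]
            else:
                wo = (row if variant == "without_invivo"
                      else get_row(region, parameter, "without_invivo", coefficient_table))
                sd = residual_sd_from_ci(wo["ci_b"], n_post_mortem, sxx)
            gen[(region, parameter)] = (float(row["a"]), float(row["b"]), float(sd))

    def scale_for(parameter):
        if isinstance(invivo_scale, dict):
            return invivo_scale.get(parameter, 1.0)
        return float(invivo_scale)

    subjects = []
    rows = []
    for i in range(n_post_mortem + n_in_vivo):
        is_pm = i < n_post_mortem
        spec = SubjectSpec(
            subject_id=f"{'pm' if is_pm else 'iv'}{(i if is_pm else i - n_post_mortem) + 1:02d}",
            cohort="post_mortem" if is_pm else "in_vivo",
            brain_temperature=temps[i],
            seed=int(children[i].generate_state(1)[0] % (2**31)),
        )
        subjects.append(spec)
        rng_i = np.random.default_rng(children[i].spawn(1)[0])
        for region in REGIONS:
            for parameter in PARAMETERS:
                a, b, sd = gen[(region, parameter)]
                base = a + b * spec.brain_temperature
                if not is_pm:
                    base *= scale_for(parameter)
                mean = base + sd * rng_i.standard_normal()
                rows.append({
                    "subject_id": spec.subject_id,
                    "cohort": spec.cohort,
                    "temperature_C": spec.brain_temperature,
                    "region": region,
                    "parameter": parameter,
                    "mean": mean,
                    "sd": abs(sd),
                    "n_voxels": n_voxels_nominal,
                })
    return subjects, pd.DataFrame(rows)
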