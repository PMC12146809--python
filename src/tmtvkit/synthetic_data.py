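"""Synthetic PET phantoms and simulated patient cohorts.

The real trial dataset behind the TMTV analyses is not public, so this
module supplies two generators with *known ground truth*:

``generate_phantom``
    Voxelized digital phantoms (ellipsoid/box lesions and organs painted
    on a uniform background) emitted as activity volumes plus acquisition
    metadata, together with an exact per-lesion voxel-count oracle.  A
    voxel belongs to a shape iff its center lies inside, so the truth is
    brute-forceable and segmentation can be validated to the voxel.

``generate_cohort``
    Patient-level cohorts with the statistical structure the survival
    analyses assume: a two-piece lognormal TMTV distribution tuned to
    median 161 mL and IQR 50-388 mL, FLIPI2 risk factors at the published
    prevalences (~43% high risk), a change-point (step) hazard effect of
    TMTV above a true cutoff tau* (default 180 mL, HR 1.6), baseline
    hazards solved so that 5-year PFS is 67% and 5-year OS 93%, and
    uniform-accrual administrative censoring giving a median potential
    follow-up of 57 months.

``simulate_readers``
    Multiplicative lognormal inter-reader measurement noise with a stated
    coefficient of variation, for agreement (Bland-Altman) studies.

A single lognormal cannot match median 161 with quartiles 50 and 388
(the implied log-scale spreads differ: 1.73 below vs 1.30 above the
median), hence the two-piece construction, which reproduces all three
quantiles exactly and puts ~47% of patients above 180 mL and ~8.6% in
the 180-240 mL band, as observed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pet_suv import AcquisitionMeta, ActivityVolume, SuvVolume, decay_corrected_dose

# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

LESION_SITES = ("nodal", "extranodal", "spleen", "marrow")
ORGAN_NAMES = ("liver", "spleen", "marrow", "brain", "bladder", "heart")


@dataclasses.dataclass(frozen=True)
class ShapeSpec:
    """Ellipsoid (semi_axes_mm) or axis-aligned box (half_widths via kind)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    kind: str = "ellipsoid"  # or "box"

    def contains(self, coords: Sequence[np.ndarray]) -> np.ndarray:
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        if self.kind == "box":
            return ((np.abs(coords[0] - cx) <= ax)
                    & (np.abs(coords[1] - cy) <= ay)
                    & (np.abs(coords[2] - cz) <= az))
        return (((coords[0] - cx) / ax) ** 2 + ((coords[1] - cy) / ay) ** 2
                + ((coords[2] - cz) / az) ** 2) <= 1.0


@dataclasses.dataclass(frozen=True)
class OrganSpec:
    name: str
    shape: ShapeSpec
    suv: float
    uptake_pattern: str = "diffuse"  # or "focal"

    def __post_init__(self):
        if self.name not in ORGAN_NAMES:
            raise ValueError(f"unknown organ {self.name!r}")
        if self.suv < 0:
            raise ValueError("organ SUV must be >= 0")


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    shape: ShapeSpec
    suv: float
    site: str = "nodal"

    def __post_init__(self):
        if self.site not in LESION_SITES:
            raise ValueError(f"unknown lesion site {self.site!r}")
        if self.suv < 0:
            raise ValueError("lesion SUV must be >= 0")


def sphere(center_mm, radius_mm) -> ShapeSpec:
    return ShapeSpec(tuple(center_mm), (radius_mm,) * 3)


def box(center_mm, half_widths_mm) -> ShapeSpec:
    return ShapeSpec(tuple(center_mm), tuple(half_widths_mm), kind="box")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    organs: tuple[OrganSpec, ...] = ()
    lesions: tuple[LesionSpec, ...] = ()
    allow_overlap: bool = False
    blur_fwhm_mm: float = 0.0  # optional partial-volume blur, default off

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.background_suv < 0:
            raise ValueError("background SUV must be >= 0")
        extent = [n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm)]
        for les in self.lesions:
            c, a = les.shape.center_mm, les.shape.semi_axes_mm
            for ci, ai, ei in zip(c, a, extent):
                if ci - ai < 0 or ci + ai > ei:
                    raise ValueError("lesion geometry extends outside the grid")


@dataclasses.dataclass
class PhantomTruth:
    """Exact oracle for a noise-free phantom under a given threshold."""

    lesion_voxel_counts: list[int]
    lesion_volumes_ml: list[float]
    lesion_sites: list[str]
    true_tmtv_ml: float
    threshold: float
    voxel_volume_ml: float
    organ_masks: dict[str, np.ndarray]
    n_components_expected: int

    def to_json_dict(self) -> dict:
        return {
            "lesion_voxel_counts": self.lesion_voxel_counts,
            "lesion_volumes_ml": self.lesion_volumes_ml,
            "lesion_sites": self.lesion_sites,
            "true_tmtv_ml": self.true_tmtv_ml,
            "threshold": self.threshold,
            "voxel_volume_ml": self.voxel_volume_ml,
            "n_components_expected": self.n_components_expected,
        }


def _voxel_center_coords(shape, spacing):
    return np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                       indexing="ij")


DEFAULT_META = AcquisitionMeta(
    injected_dose_mbq=350.0,
    injection_time="2020-01-01T09:00:00",
    scan_time="2020-01-01T10:00:00",
    body_weight_kg=70.0,
)


def generate_phantom(spec: PhantomSpec, seed: int = 0,
                     meta: AcquisitionMeta | None = None,
                     threshold: float = 4.0,
                     ) -> tuple[ActivityVolume, AcquisitionMeta, PhantomTruth]:
    """Voxelize a phantom spec into an activity volume with exact truth.

    The emitted activity concentration is chosen so that converting back
    with the emitted metadata reproduces the specified SUVs voxel-wise.
    Overlapping shapes with conflicting SUVs are rejected unless the spec
    opts into max-SUV resolution.  Deterministic per (spec, seed); the
    seed currently only matters when partial-volume blur is enabled
    (reserved for future noise models).
    """
    meta = meta or DEFAULT_META
    coords = _voxel_center_coords(spec.grid_shape, spec.voxel_spacing_mm)
    suv = np.full(spec.grid_shape, float(spec.background_suv))
    claimed = np.zeros(spec.grid_shape, dtype=bool)
    organ_masks: dict[str, np.ndarray] = {}

    for organ in spec.organs:
        m = organ.shape.contains(coords)
        organ_masks[organ.name] = m
        conflict = claimed & m & (suv != organ.suv)
        if conflict.any() and not spec.allow_overlap:
            raise ValueError(f"organ {organ.name!r} overlaps a previous shape "
                             "with a different SUV (set allow_overlap for max-SUV)")
        if spec.allow_overlap:
            suv[m] = np.maximum(suv[m], organ.suv)
        else:
            suv[m] = organ.suv
        claimed |= m

    lesion_masks = []
    for i, les in enumerate(spec.lesions):
        m = les.shape.contains(coords)
        conflict = claimed & m
        if conflict.any() and not spec.allow_overlap:
            raise ValueError(f"lesion {i} overlaps a previous shape "
                             "(set allow_overlap for max-SUV resolution)")
        if spec.allow_overlap:
            suv[m] = np.maximum(suv[m], les.suv)
        else:
            suv[m] = les.suv
        claimed |= m
        lesion_masks.append(m)

    if spec.blur_fwhm_mm > 0:
        from scipy.ndimage import gaussian_filter
        sigma = [spec.blur_fwhm_mm / (2 * math.sqrt(2 * math.log(2))) / s
                 for s in spec.voxel_spacing_mm]
        suv = gaussian_filter(suv, sigma)

    counts, volumes, sites = [], [], []
    vv = float(np.prod(spec.voxel_spacing_mm)) / 1000.0
    union = np.zeros(spec.grid_shape, dtype=bool)
    for les, m in zip(spec.lesions, lesion_masks):
        if les.suv >= threshold:
            counts.append(int(m.sum()))
            volumes.append(int(m.sum()) * vv)
            sites.append(les.site)
            union |= m
    from skimage import measure as _measure
    n_comp = int(_measure.label(union, connectivity=3).max())

    truth = PhantomTruth(
        lesion_voxel_counts=counts,
        lesion_volumes_ml=volumes,
        lesion_sites=sites,
        true_tmtv_ml=float(sum(counts)) * vv,
        threshold=threshold,
        voxel_volume_ml=vv,
        organ_masks=organ_masks,
        n_components_expected=n_comp,
    )

    # activity concentration reproducing the SUV map under `meta`
    dose = decay_corrected_dose(meta)
    weight_g = meta.body_weight_kg * 1000.0
    activity = suv * dose / weight_g
    vol = ActivityVolume(activity, spec.voxel_spacing_mm)
    return vol, meta, truth


def random_lesion_phantom(seed: int, n_lesions: tuple[int, int] = (1, 6),
                          grid_shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0),
                          suv_range=(4.5, 12.0), radius_range_mm=(6.0, 24.0),
                          ) -> PhantomSpec:
    """Random non-overlapping spherical-lesion phantom spec (seeded)."""
    rng = np.random.default_rng(seed)
    extent = [n * s for n, s in zip(grid_shape, spacing)]
    n_les = int(rng.integers(n_lesions[0], n_lesions[1] + 1))
    lesions: list[LesionSpec] = []
    attempts = 0
    while len(lesions) < n_les and attempts < 500:
        attempts += 1
        r = float(rng.uniform(*radius_range_mm))
        c = [float(rng.uniform(r + s, e - r - s)) for e, s in zip(extent, spacing)]
        # keep lesions well separated so components stay distinct
        ok = all(math.dist(c, l.shape.center_mm) > r + l.shape.semi_axes_mm[0] + 3 * max(spacing)
                 for l in lesions)
        if ok:
            lesions.append(LesionSpec(sphere(c, r), float(rng.uniform(*suv_range))))
    return PhantomSpec(grid_shape=grid_shape, voxel_spacing_mm=spacing,
                       background_suv=1.0, lesions=tuple(lesions))


def write_phantom(path_prefix: str | Path, vol: ActivityVolume,
                  meta: AcquisitionMeta, truth: PhantomTruth) -> None:
    """Write phantom as NIfTI + JSON sidecar metadata + JSON truth."""
    from .pet_suv import write_volume
    prefix = Path(path_prefix)
    write_volume(vol, prefix.with_suffix(".nii.gz"), meta)
    prefix.with_name(prefix.name + "_truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=2))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: column dictionary for cohort CSV files
COHORT_COLUMNS = {
    "id": "subject identifier",
    "tmtv_ml": "baseline total metabolic tumor volume, mL",
    "age_gt60": "1 if age > 60 years",
    "sex_male": "1 if male",
    "hb_lt12": "1 if hemoglobin < 12 g/dL",
    "b2m_gt_uln": "1 if beta-2-microglobulin above upper limit of normal",
    "bm_involved": "1 if bone marrow involved",
    "lodlin_gt6": "1 if longest diameter of largest involved node > 6 cm",
    "ldh_gt_uln": "1 if LDH above upper limit of normal (FLIPI factor)",
    "stage_3_4": "1 if Ann Arbor stage III-IV (FLIPI factor)",
    "nodal_gt4": "1 if > 4 nodal areas involved (FLIPI factor)",
    "flipi2_score": "FLIPI2 score 0-5",
    "flipi2_high": "1 if FLIPI2 score >= 3",
    "arm": "randomization arm: standard | experimental",
    "regimen": "induction regimen: R-CHOP | R-B",
    "pfs_months": "observed progression-free survival time, months",
    "pfs_event": "1 = progression or death observed, 0 = censored",
    "os_months": "observed overall survival time, months",
    "os_event": "1 = death observed, 0 = censored",
}

FLIPI2_FACTORS = ("age_gt60", "hb_lt12", "b2m_gt_uln", "bm_involved", "lodlin_gt6")
FLIPI_FACTORS = ("age_gt60", "stage_3_4", "hb_lt12", "ldh_gt_uln", "nodal_gt4")

DEFAULT_PREVALENCE = {
    "age_gt60": 0.50,
    "sex_male": 0.46,
    "hb_lt12": 0.16,
    "b2m_gt_uln": 0.55,
    "bm_involved": 0.55,
    "lodlin_gt6": 0.55,
    "ldh_gt_uln": 0.25,
    "stage_3_4": 0.85,
    "nodal_gt4": 0.55,
    "arm_experimental": 0.52,
    "regimen_rb": 0.42,
}


@dataclasses.dataclass(frozen=True)
class HazardModel:
    """Change-point proportional-hazards model for event times.

    The hazard for subject i is ``rate * exp(lp_i)`` (exponential baseline;
    Weibull via ``shape != 1``), with linear predictor

        lp = log_hr_tmtv * 1{TMTV > tau_star}        (tmtv_form='step')
           = log_hr_tmtv * TMTV/500                  (tmtv_form='per500')
           + sum_c log_hr_covariates[c] * x_c

    ``rate=None`` means: solve the baseline rate so that the marginal
    survival at ``target_horizon_months`` equals ``target_survival``.
    """

    tau_star_ml: float = 180.0
    log_hr_tmtv: float = math.log(1.6)
    tmtv_form: str = "step"  # or "per500"
    log_hr_covariates: tuple[tuple[str, float], ...] = (
        ("flipi2_high", math.log(2.0)),
        ("sex_male", math.log(1.3)),
    )
    rate: float | None = None
    shape: float = 1.0  # Weibull shape; 1 = exponential
    target_survival: float = 0.67
    target_horizon_months: float = 60.0


@dataclasses.dataclass(frozen=True)
class CensoringSpec:
    """Uniform accrual + administrative cutoff.

    Potential follow-up is ``admin_cutoff - entry`` with entry uniform on
    [0, accrual]; the defaults give follow-up U(25, 89), median 57 months.
    """

    accrual_months: float = 64.0
    admin_cutoff_months: float = 89.0


@dataclasses.dataclass(frozen=True)
class ReaderNoiseSpec:
    k_readers: int = 2
    cv: float = 0.05

    def __post_init__(self):
        if self.k_readers < 2:
            raise ValueError("need at least 2 readers")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    n: int = 689
    tmtv_log_median: float = math.log(161.0)
    #: log-scale spread below / above the median (two-piece lognormal);
    #: equal values recover a plain lognormal
    tmtv_log_sd: tuple[float, float] = (
        math.log(161.0 / 50.0) / 0.6744897501960817,
        math.log(388.0 / 161.0) / 0.6744897501960817,
    )
    covariate_prevalence: tuple[tuple[str, float], ...] = tuple(DEFAULT_PREVALENCE.items())
    pfs_model: HazardModel = HazardModel()
    os_model: HazardModel = HazardModel(
        log_hr_tmtv=math.log(1.5),
        log_hr_covariates=(("flipi2_high", math.log(1.8)),),
        target_survival=0.93,
    )
    censoring: CensoringSpec = CensoringSpec()
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, p in self.covariate_prevalence:
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name} outside [0,1]")
        if any(s < 0 for s in self.tmtv_log_sd):
            raise ValueError("tmtv_log_sd must be >= 0")

    @property
    def prevalence(self) -> dict[str, float]:
        return dict(self.covariate_prevalence)


def _two_piece_lognormal(u: np.ndarray, log_median: float, sd: tuple[float, float]) -> np.ndarray:
    """Inverse-CDF sampler: quantile z mapped with the lower spread below
    the median and the upper spread above, so all quantiles are exact."""
    z = stats.norm.ppf(u)
    s = np.where(z < 0, sd[0], sd[1])
    return np.exp(log_median + s * z)


def flipi2_high_probability(prevalence: dict[str, float]) -> float:
    """P(FLIPI2 score >= 3) under independent factors (exact enumeration)."""
    ps = [prevalence[f] for f in FLIPI2_FACTORS]
    total = 0.0
    for combo in itertools.product((0, 1), repeat=5):
        if sum(combo) >= 3:
            pr = 1.0
            for c, p in zip(combo, ps):
                pr *= p if c else 1 - p
            total += pr
    return total


def _linear_predictor(model: HazardModel, tmtv: np.ndarray,
                      covariates: dict[str, np.ndarray]) -> np.ndarray:
    if model.tmtv_form == "step":
        lp = model.log_hr_tmtv * (tmtv > model.tau_star_ml).astype(float)
    elif model.tmtv_form == "per500":
        lp = model.log_hr_tmtv * tmtv / 500.0
    else:
        raise ValueError(f"unknown tmtv_form {model.tmtv_form!r}")
    for name, beta in model.log_hr_covariates:
        lp = lp + beta * covariates[name]
    return lp


def solve_baseline_rate(model: HazardModel, spec: CohortSpec) -> float:
    """Baseline rate such that the covariate-marginal survival at the
    target horizon equals the target (deterministic quadrature: TMTV on a
    quantile grid, binary covariates enumerated by prevalence)."""
    if model.rate is not None:
        return model.rate
    prev = spec.prevalence
    p_high = flipi2_high_probability(prev)
    # marginal distribution of the linear predictor
    qs = (np.arange(512) + 0.5) / 512
    tmtv_grid = _two_piece_lognormal(qs, spec.tmtv_log_median, spec.tmtv_log_sd)
    names = [n for n, _ in model.log_hr_covariates]
    probs = {"flipi2_high": p_high, **prev}
    lps = []
    ws = []
    for combo in itertools.product((0, 1), repeat=len(names)):
        w = 1.0
        cov = {}
        for name, c in zip(names, combo):
            p = probs[name]
            w *= p if c else 1 - p
            cov[name] = np.full_like(tmtv_grid, float(c))
        lps.append(_linear_predictor(model, tmtv_grid, cov))
        ws.append(w / len(tmtv_grid))
    lps = np.concatenate(lps)
    ws = np.repeat(ws, len(tmtv_grid))
    t0 = model.target_horizon_months

    def marginal_survival(rate):
        return float(np.sum(ws * np.exp(-((rate * t0) ** model.shape) * np.exp(lps)))) \
            - model.target_survival

    return float(optimize.brentq(marginal_survival, 1e-7, 1.0))


def _draw_event_times(rng: np.random.Generator, rate: float, shape: float,
                      lp: np.ndarray) -> np.ndarray:
    u = rng.uniform(size=lp.shape)
    # S(t) = exp(-((rate t)^shape) e^lp)  =>  inverse transform
    return (-np.log(u) / np.exp(lp)) ** (1.0 / shape) / rate


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort as a DataFrame with the ``COHORT_COLUMNS`` layout.

    Event times come from the spec's change-point proportional-hazards
    model by inverse-transform sampling; observed times are the minimum
    of the event time and the administrative censoring time.  PFS is
    generated directly as the composite endpoint (progression or death)
    and OS from its own marginal model; joint consistency of the two
    endpoints is not enforced (a marginal simulator, documented).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    prev = spec.prevalence

    tmtv = _two_piece_lognormal(rng.uniform(size=n), spec.tmtv_log_median,
                                spec.tmtv_log_sd)
    cols: dict[str, np.ndarray] = {"id": np.arange(1, n + 1), "tmtv_ml": tmtv}
    for name in ("age_gt60", "sex_male", "hb_lt12", "b2m_gt_uln", "bm_involved",
                 "lodlin_gt6", "ldh_gt_uln", "stage_3_4", "nodal_gt4"):
        cols[name] = (rng.uniform(size=n) < prev[name]).astype(int)
    score = sum(cols[f] for f in FLIPI2_FACTORS)
    cols["flipi2_score"] = score
    cols["flipi2_high"] = (score >= 3).astype(int)
    arm_exp = rng.uniform(size=n) < prev["arm_experimental"]
    cols["arm"] = np.where(arm_exp, "experimental", "standard")
    cols["regimen"] = np.where(rng.uniform(size=n) < prev["regimen_rb"], "R-B", "R-CHOP")

    covs = {k: np.asarray(v, dtype=float) for k, v in cols.items()
            if k not in ("id", "arm", "regimen", "tmtv_ml")}
    entry = rng.uniform(0.0, spec.censoring.accrual_months, size=n)
    censor = spec.censoring.admin_cutoff_months - entry

    for prefix, model in (("pfs", spec.pfs_model), ("os", spec.os_model)):
        rate = solve_baseline_rate(model, spec)
        lp = _linear_predictor(model, tmtv, covs)
        t_event = _draw_event_times(rng, rate, model.shape, lp)
        observed = np.minimum(t_event, censor)
        cols[f"{prefix}_months"] = np.maximum(observed, 1e-6)
        cols[f"{prefix}_event"] = (t_event <= censor).astype(int)

    return pd.DataFrame(cols, columns=list(COHORT_COLUMNS))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("tmtv_ml", "pfs_months", "pfs_event") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Reader noise
# ---------------------------------------------------------------------------

def simulate_readers(true_tmtv: Sequence[float], noise: ReaderNoiseSpec,
                     seed: int = 0) -> np.ndarray:
    """Reader-by-subject TMTV matrix with multiplicative lognormal noise.

    Noise factors have unit mean and coefficient of variation ``noise.cv``
    (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2); cv=0 reproduces the truth
    exactly for every reader.
    """
    truth = np.asarray(true_tmtv, dtype=float)
    if np.any(truth <= 0):
        raise ValueError("true TMTV values must be positive")
    rng = np.random.default_rng(seed)
    if noise.cv == 0:
        return np.tile(truth, (noise.k_readers, 1))
    sigma2 = math.log(1.0 + noise.cv ** 2)
    factors = rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2),
                            size=(noise.k_readers, truth.size))
    return truth[None, :] * factors
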