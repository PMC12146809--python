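"""Total metabolic tumor volume (TMTV) segmentation.

Lesions are segmented on the SUV volume with the standardized fixed
absolute threshold SUV >= 4 (inclusive), individual lesions are the
connected components of the thresholded mask, and TMTV is the sum of
their volumes in mL.  Operator-style rules are applied deterministically:

* components falling mostly inside a physiological-uptake exclusion mask
  (brain, bladder, heart, ...) are removed;
* the spleen contributes when involved — focal uptake inside the organ,
  or diffuse uptake whose organ-mean SUV exceeds 150% of the liver
  background (mean SUV over a liver VOI);
* bone marrow contributes only components flagged as focal; diffuse
  marrow uptake contributes nothing.

A legacy per-lesion 41%-of-SUVmax relative-threshold mode is provided for
comparison with historical cutoffs derived with that method.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .pet_suv import SuvVolume

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    """Configuration of the TMTV segmentation.

    method : 'fixed-suv4' (absolute threshold) or 'pct41' (legacy relative).
    threshold : absolute SUV threshold, inclusive (default 4.0).
    connectivity : 6, 18 or 26 neighborhood for lesion individuation.
    min_lesion_volume_ml : drop components smaller than this (default 0).
    exclusion_overlap : fraction of a component's voxels inside the
        exclusion mask above which it is removed (default 0.5, "majority").
    diffuse_spleen_whole_organ : if True (default) a diffusely involved
        spleen contributes its whole anatomical volume, otherwise only its
        thresholded voxels.
    """

    method: str = "fixed-suv4"
    threshold: float = 4.0
    connectivity: int = 26
    min_lesion_volume_ml: float = 0.0
    exclusion_overlap: float = 0.5
    diffuse_spleen_whole_organ: bool = True

    def __post_init__(self):
        if self.method not in ("fixed-suv4", "pct41"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.connectivity not in _CONNECTIVITY_TO_SKIMAGE:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_lesion_volume_ml < 0:
            raise ValueError("min_lesion_volume_ml must be >= 0")


@dataclasses.dataclass
class OrganContext:
    """Organ masks steering the exclusion and organ-specific rules.

    All masks are boolean arrays on the SUV grid.  ``marrow_focal_labels``
    lists the component labels (after labeling) the operator flags as
    focal marrow uptake; unflagged marrow components are discarded.
    """

    exclusion_mask: np.ndarray | None = None
    liver_voi: np.ndarray | None = None
    spleen_mask: np.ndarray | None = None
    marrow_mask: np.ndarray | None = None
    marrow_focal_labels: frozenset[int] = frozenset()

    def validate(self, shape: tuple[int, ...]) -> None:
        for name in ("exclusion_mask", "liver_voi", "spleen_mask", "marrow_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} does not match grid {shape}")


@dataclasses.dataclass
class Lesion:
    label: int
    voxel_count: int
    volume_ml: float
    suv_max: float
    site: str = "nodal"


@dataclasses.dataclass
class TmtvResult:
    lesions: list[Lesion]
    tmtv_ml: float
    global_suv_max: float
    config: SegmentationConfig
    audit: list[str]

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def to_json_dict(self) -> dict:
        return {
            "tmtv_ml": self.tmtv_ml,
            "global_suv_max": self.global_suv_max,
            "n_lesions": self.n_lesions,
            "lesions": [dataclasses.asdict(l) for l in self.lesions],
            "config": dataclasses.asdict(self.config),
            "audit": list(self.audit),
        }


def threshold_mask(suv: SuvVolume, threshold: float) -> np.ndarray:
    """Binary mask of voxels with SUV >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return suv.voxels >= threshold


def label_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components; deterministic lexicographic ordering.

    Labels are renumbered so component 1 contains the lexicographically
    first voxel, making the labeling independent of traversal order.
    """
    conn = _CONNECTIVITY_TO_SKIMAGE[connectivity]
    raw = measure.label(mask, connectivity=conn)
    n = raw.max()
    if n == 0:
        return raw
    # order components by their first voxel in C-order
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so the smallest index wins
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[raw]


def apply_exclusions(labeled: np.ndarray, ctx: OrganContext,
                     overlap_rule: float = 0.5,
                     audit: list[str] | None = None) -> np.ndarray:
    """Remove components whose overlap with the exclusion mask exceeds the rule.

    A component is removed when strictly more than ``overlap_rule`` of its
    voxels lie inside ``ctx.exclusion_mask``.
    """
    ctx.validate(labeled.shape)
    if ctx.exclusion_mask is None or labeled.max() == 0:
        return labeled
    out = labeled.copy()
    n = int(labeled.max())
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    overlap = np.bincount(labeled[ctx.exclusion_mask].ravel(), minlength=n + 1)
    for lab in range(1, n + 1):
        if counts[lab] and overlap[lab] / counts[lab] > overlap_rule:
            out[out == lab] = 0
            if audit is not None:
                audit.append(
                    f"component {lab} removed: {overlap[lab]}/{counts[lab]} voxels "
                    f"({overlap[lab] / counts[lab]:.0%}) inside exclusion mask"
                )
    return out


def liver_reference(suv: SuvVolume, liver_voi: np.ndarray) -> float:
    """Mean SUV over the liver VOI (the 'liver background')."""
    if liver_voi is None or not liver_voi.any():
        raise ValueError("liver VOI is empty")
    return float(suv.voxels[liver_voi].mean())


def sphere_voi(shape: tuple[int, int, int], spacing: Sequence[float],
               center_mm: Sequence[float], radius_mm: float = 15.0) -> np.ndarray:
    """Spherical VOI builder (default 3-cm sphere) for liver background."""
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm ** 2


def spleen_rule(suv: SuvVolume, spleen_mask: np.ndarray, liver_ref: float,
                labeled: np.ndarray, *, whole_organ_if_diffuse: bool = True,
                audit: list[str] | None = None) -> tuple[np.ndarray, bool]:
    """Spleen involvement: focal component inside the organ, or diffuse
    uptake with mean spleen SUV strictly above 1.5x the liver background.

    Returns (boolean contribution mask, involvement flag).  Focal
    involvement contributes the thresholded components inside the organ;
    diffuse involvement contributes the whole organ mask (configurable).
    """
    if spleen_mask is None:
        raise ValueError("spleen rule requested without a spleen mask")
    if spleen_mask.shape != labeled.shape:
        raise ValueError("spleen mask shape mismatch")
    focal = (labeled > 0) & spleen_mask
    contribution = np.zeros_like(spleen_mask, dtype=bool)
    if focal.any():
        contribution = focal
        if audit is not None:
            audit.append("spleen involved: focal uptake inside organ")
        return contribution, True
    mean_spleen = float(suv.voxels[spleen_mask].mean()) if spleen_mask.any() else 0.0
    if mean_spleen > 1.5 * liver_ref:
        contribution = spleen_mask.copy() if whole_organ_if_diffuse else focal
        if audit is not None:
            audit.append(
                f"spleen involved: diffuse uptake {mean_spleen:.2f} > 1.5 x liver "
                f"{liver_ref:.2f}; contributing "
                + ("whole organ" if whole_organ_if_diffuse else "thresholded voxels")
            )
        return contribution, True
    if audit is not None:
        audit.append(f"spleen not involved (mean {mean_spleen:.2f} <= 1.5 x liver {liver_ref:.2f})")
    return contribution, False


def marrow_rule(labeled: np.ndarray, marrow_mask: np.ndarray,
                focal_labels: Iterable[int],
                audit: list[str] | None = None) -> np.ndarray:
    """Marrow contribution: only components flagged focal are retained.

    Components lying (majority of voxels) inside the marrow mask and not
    flagged are treated as diffuse uptake and contribute nothing.
    """
    if marrow_mask is None:
        return np.zeros_like(labeled, dtype=bool)
    focal = set(int(l) for l in focal_labels)
    n = int(labeled.max())
    contribution = np.zeros_like(labeled, dtype=bool)
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    inside = np.bincount(labeled[marrow_mask].ravel(), minlength=n + 1)
    for lab in range(1, n + 1):
        if counts[lab] == 0 or inside[lab] * 2 <= counts[lab]:
            continue  # not a marrow component
        if lab in focal:
            contribution |= labeled == lab
            if audit is not None:
                audit.append(f"marrow component {lab} retained (focal)")
        else:
            if audit is not None:
                audit.append(f"marrow component {lab} excluded (diffuse uptake)")
    return contribution


def auto_flag_focal_marrow(labeled: np.ndarray, marrow_mask: np.ndarray,
                           max_fraction: float = 0.25) -> frozenset[int]:
    """Heuristic focality flagger for simulations: a marrow component is
    'focal' when its volume is below ``max_fraction`` of the marrow mask."""
    if marrow_mask is None or not marrow_mask.any():
        return frozenset()
    n = int(labeled.max())
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    inside = np.bincount(labeled[marrow_mask].ravel(), minlength=n + 1)
    total = int(marrow_mask.sum())
    flags = [lab for lab in range(1, n + 1)
             if counts[lab] and inside[lab] * 2 > counts[lab]
             and counts[lab] < max_fraction * total]
    return frozenset(flags)


def _lesion_table(labeled: np.ndarray, suv: SuvVolume,
                  site_of: Mapping[int, str] | None = None) -> list[Lesion]:
    n = int(labeled.max())
    if n == 0:
        return []
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    maxima = ndi.maximum(suv.voxels, labels=labeled, index=np.arange(1, n + 1))
    vv = suv.voxel_volume_ml
    lesions = []
    for lab in range(1, n + 1):
        if counts[lab] == 0:
            continue
        lesions.append(Lesion(
            label=lab,
            voxel_count=int(counts[lab]),
            volume_ml=float(counts[lab]) * vv,
            suv_max=float(np.atleast_1d(maxima)[lab - 1]),
            site=(site_of or {}).get(lab, "nodal"),
        ))
    return lesions


def compute_tmtv(suv: SuvVolume, config: SegmentationConfig | None = None,
                 ctx: OrganContext | None = None) -> TmtvResult:
    """Segment lesions and sum their volumes into TMTV (mL).

    Pipeline: absolute threshold -> connected components -> physiological
    exclusions -> marrow focality rule -> spleen involvement rule ->
    minimum-volume filter -> per-lesion table and TMTV.
    """
    config = config or SegmentationConfig()
    ctx = ctx or OrganContext()
    ctx.validate(suv.voxels.shape)
    audit: list[str] = [f"method={config.method} threshold={config.threshold} "
                        f"connectivity={config.connectivity}"]

    mask = threshold_mask(suv, config.threshold)
    labeled = label_components(mask, config.connectivity)
    labeled = apply_exclusions(labeled, ctx, config.exclusion_overlap, audit)

    site_of: dict[int, str] = {}
    if ctx.marrow_mask is not None:
        keep_marrow = marrow_rule(labeled, ctx.marrow_mask, ctx.marrow_focal_labels, audit)
        n = int(labeled.max())
        counts = np.bincount(labeled.ravel(), minlength=n + 1)
        inside = np.bincount(labeled[ctx.marrow_mask].ravel(), minlength=n + 1)
        for lab in range(1, n + 1):
            if counts[lab] and inside[lab] * 2 > counts[lab]:
                if keep_marrow[labeled == lab].any():
                    site_of[lab] = "marrow"
                else:
                    labeled = np.where(labeled == lab, 0, labeled)

    if ctx.spleen_mask is not None:
        if ctx.liver_voi is None:
            raise ValueError("spleen rule requires a liver VOI")
        liver_ref = liver_reference(suv, ctx.liver_voi)
        contribution, involved = spleen_rule(
            suv, ctx.spleen_mask, liver_ref, labeled,
            whole_organ_if_diffuse=config.diffuse_spleen_whole_organ, audit=audit)
        if involved and contribution.any() and not ((labeled > 0) & contribution).any():
            # diffuse involvement: add the organ as one synthetic component
            new_lab = int(labeled.max()) + 1
            labeled = labeled.copy()
            labeled[contribution & (labeled == 0)] = new_lab
            site_of[new_lab] = "spleen"
        elif involved:
            n = int(labeled.max())
            inside = np.bincount(labeled[ctx.spleen_mask].ravel(), minlength=n + 1)
            counts = np.bincount(labeled.ravel(), minlength=n + 1)
            for lab in range(1, n + 1):
                if counts[lab] and inside[lab] * 2 > counts[lab]:
                    site_of[lab] = "spleen"

    lesions = _lesion_table(labeled, suv, site_of)
    if config.min_lesion_volume_ml > 0:
        dropped = [l for l in lesions if l.volume_ml < config.min_lesion_volume_ml]
        for l in dropped:
            audit.append(f"component {l.label} dropped: {l.volume_ml:.3f} mL below minimum")
        lesions = [l for l in lesions if l.volume_ml >= config.min_lesion_volume_ml]

    # total voxel count x voxel volume: exactly reproducible regardless of
    # lesion ordering (float addition is not associative)
    tmtv = float(sum(l.voxel_count for l in lesions)) * suv.voxel_volume_ml
    gmax = float(max((l.suv_max for l in lesions), default=0.0))
    return TmtvResult(lesions=lesions, tmtv_ml=tmtv, global_suv_max=gmax,
                      config=config, audit=audit)


def pct41_segment(suv: SuvVolume, detection_threshold: float = 4.0,
                  connectivity: int = 26, margin_mm: float = 20.0,
                  ctx: OrganContext | None = None) -> TmtvResult:
    """Legacy 41%-of-SUVmax segmentation.

    Seed lesions are detected with the absolute threshold, then each lesion
    is regrown at ``0.41 * lesion SUVmax`` within its bounding region
    (bounding box dilated by ``margin_mm``), keeping the connected
    component that contains the lesion peak.
    """
    config = SegmentationConfig(method="pct41", threshold=detection_threshold,
                                connectivity=connectivity)
    ctx = ctx or OrganContext()
    mask = threshold_mask(suv, detection_threshold)
    labeled = label_components(mask, connectivity)
    labeled = apply_exclusions(labeled, ctx, config.exclusion_overlap, None)
    conn = _CONNECTIVITY_TO_SKIMAGE[connectivity]
    vv = suv.voxel_volume_ml
    audit = [f"method=pct41 detection_threshold={detection_threshold}"]

    out = np.zeros(suv.voxels.shape, dtype=np.int32)
    lesions: list[Lesion] = []
    margin = [int(np.ceil(margin_mm / s)) for s in suv.spacing]
    for lab in range(1, int(labeled.max()) + 1):
        comp = labeled == lab
        if not comp.any():
            continue
        idx = np.argwhere(comp)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + margin + 1, suv.voxels.shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = suv.voxels[box]
        peak_suv = float(suv.voxels[comp].max())
        thr = 0.41 * peak_suv
        grown = measure.label(sub >= thr, connectivity=conn)
        # component containing the lesion peak
        peak_local = np.unravel_index(np.argmax(np.where(comp[box], sub, -np.inf)), sub.shape)
        keep = grown == grown[peak_local]
        region = np.zeros_like(comp)
        region[box] = keep
        region &= out == 0  # no double counting across lesions
        out[region] = lab
        cnt = int(region.sum())
        lesions.append(Lesion(label=lab, voxel_count=cnt, volume_ml=cnt * vv,
                              suv_max=peak_suv))
        audit.append(f"lesion {lab}: per-lesion threshold {thr:.3f} "
                     f"(0.41 x {peak_suv:.2f}), {cnt} voxels")

    tmtv = float(sum(l.voxel_count for l in lesions)) * vv
    gmax = float(max((l.suv_max for l in lesions), default=0.0))
    return TmtvResult(lesions=lesions, tmtv_ml=tmtv, global_suv_max=gmax,
                      config=config, audit=audit)
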