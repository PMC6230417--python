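"""Whole-burden response metrics: lesion inventory, V, D, RECIST S, and deltas.

From a tumor mask and its CT volume the package derives:

* a :class:`LesionSet` — connected components with per-lesion volume (cm^3),
  mean HU and longest axial diameter (cm), plus the global totals
  ``V`` (total tumor volume, sum over lesions) and ``D`` (mean volumetric
  tumor density, the voxel-weighted mean HU over the union of all tumor
  voxels — not the mean of per-lesion means);
* RECIST 1.1 quantities — the sum ``S`` of the longest axial diameters of up
  to two target lesions of at least 10 mm, and the CR/PR/SD/PD category from
  the percent and absolute change in ``S``;
* the percent-change statistics dV, dD, dS and the combined d(V+D) = dV + dD.

The volumetric metrics deliberately use *all* lesions (even < 1 cm) while the
RECIST sum keeps its 10 mm measurability floor: the two metric families are
meant to be compared, not harmonized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import ContractError, HepavolError
from .io import BinaryMask, CTVolume
from .liver import _connectivity_structure

__all__ = [
    "Lesion",
    "LesionSet",
    "ResponseRecord",
    "label_lesions",
    "total_volume",
    "mean_density",
    "longest_axial_diameter",
    "recist_sum",
    "match_lesions",
    "percent_change",
    "combined_change",
    "recist_category",
    "response_record",
]

RECIST_MIN_DIAMETER_CM = 1.0
RECIST_MAX_TARGETS = 2
RECIST_PR_THRESHOLD_PCT = -30.0
RECIST_PD_THRESHOLD_PCT = 20.0
RECIST_PD_ABSOLUTE_MM = 5.0


@dataclass
class Lesion:
    label: int
    voxel_count: int
    volume_cm3: float
    mean_hu: float
    longest_axial_diameter_cm: float
    centroid_mm: tuple[float, float, float]


@dataclass
class LesionSet:
    """Labeled tumor components plus whole-burden summary metrics."""

    lesions: list[Lesion]
    total_volume_cm3: float
    mean_volumetric_density_hu: float | None  # None when there is no tumor voxel
    spacing: tuple[float, float, float]

    @property
    def lesion_count(self) -> int:
        return len(self.lesions)

    def diameters_cm(self) -> np.ndarray:
        return np.array([l.longest_axial_diameter_cm for l in self.lesions])


def longest_axial_diameter(voxels: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Longest in-plane Feret diameter over axial slices, in cm.

    ``voxels`` is an (n, 3) array of (z, y, x) indices.  For each axial slice
    the maximum center-to-center distance between in-plane voxel centers is
    taken (convex-hull accelerated); a single voxel has diameter 0.
    """
    voxels = np.atleast_2d(np.asarray(voxels))
    if voxels.size == 0:
        raise ContractError("lesion has no voxels")
    _, dy, dx = spacing
    best_mm = 0.0
    for z in np.unique(voxels[:, 0]):
        pts = voxels[voxels[:, 0] == z][:, 1:].astype(np.float64)
        pts = pts * np.array([dy, dx])
        if len(pts) == 1:
            continue
        if len(pts) > 16:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass  # collinear slices fall through to full pairwise
        best_mm = max(best_mm, float(pdist(pts).max()))
    return best_mm / 10.0


def label_lesions(
    mask: BinaryMask, volume: CTVolume, connectivity: int = 26
) -> LesionSet:
    """Connected-component lesion inventory with per-lesion and global metrics."""
    mask.check_aligned(volume)
    structure = _connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.data, structure=structure)
    voxel_vol = volume.voxel_volume_cm3
    dz, dy, dx = mask.spacing

    lesions: list[Lesion] = []
    if n > 0:
        idx = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(int)
        mean_hus = ndimage.mean(volume.data, labels, idx)
        centroids = ndimage.center_of_mass(mask.data, labels, idx)
        all_coords = np.argwhere(mask.data)
        lab_of = labels[all_coords[:, 0], all_coords[:, 1], all_coords[:, 2]]
        order = np.argsort(lab_of, kind="stable")
        all_coords = all_coords[order]
        lab_sorted = lab_of[order]
        starts = np.searchsorted(lab_sorted, idx)
        ends = np.searchsorted(lab_sorted, idx, side="right")
        for i, lab in enumerate(idx):
            vox = all_coords[starts[i] : ends[i]]
            cz, cy, cx = centroids[i]
            lesions.append(
                Lesion(
                    label=int(lab),
                    voxel_count=int(counts[i]),
                    volume_cm3=float(counts[i] * voxel_vol),
                    mean_hu=float(mean_hus[i]),
                    longest_axial_diameter_cm=longest_axial_diameter(vox, mask.spacing),
                    centroid_mm=(cz * dz, cy * dy, cx * dx),
                )
            )
    total = float(sum(l.volume_cm3 for l in lesions))
    if mask.data.any():
        density = float(volume.data[mask.data].mean())
    else:
        density = None
    return LesionSet(
        lesions=lesions,
        total_volume_cm3=total,
        mean_volumetric_density_hu=density,
        spacing=mask.spacing,
    )


def total_volume(lesions: LesionSet) -> float:
    """Total tumor volume V in cm^3 (sum over all lesions)."""
    return lesions.total_volume_cm3


def mean_density(lesions: LesionSet) -> float:
    """Mean volumetric tumor density D in HU; error on an empty lesion set."""
    if lesions.mean_volumetric_density_hu is None:
        raise HepavolError("mean density is undefined for an empty tumor mask")
    return lesions.mean_volumetric_density_hu


def recist_sum(
    lesions: LesionSet,
    max_targets: int = RECIST_MAX_TARGETS,
    min_diameter_cm: float = RECIST_MIN_DIAMETER_CM,
    target_labels: list[int] | None = None,
) -> tuple[float, list[int]] | None:
    """Sum of the longest axial diameters of the RECIST target lesions.

    At baseline the targets are the up-to-``max_targets`` largest-diameter
    lesions measuring at least ``min_diameter_cm``; at follow-up pass the
    baseline ``target_labels`` (after :func:`match_lesions`) so the same
    lesion identities are re-measured.  Returns ``(sum_cm, labels)`` or
    ``None`` when no lesion is measurable.
    """
    if target_labels is not None:
        by_label = {l.label: l for l in lesions.lesions}
        missing = [lab for lab in target_labels if lab not in by_label]
        if missing:
            raise ContractError(f"target labels {missing} not present in lesion set")
        chosen = [by_label[lab] for lab in target_labels]
    else:
        eligible = [l for l in lesions.lesions if l.longest_axial_diameter_cm >= min_diameter_cm]
        if not eligible:
            return None
        eligible.sort(key=lambda l: (-l.longest_axial_diameter_cm, l.label))
        chosen = eligible[:max_targets]
    return (
        float(sum(l.longest_axial_diameter_cm for l in chosen)),
        [l.label for l in chosen],
    )


def match_lesions(baseline: LesionSet, followup: LesionSet, labels: list[int]) -> list[int]:
    """Map baseline target labels to follow-up labels by nearest centroid."""
    if not followup.lesions:
        raise ContractError("follow-up lesion set is empty")
    fu_centroids = np.array([l.centroid_mm for l in followup.lesions])
    fu_labels = [l.label for l in followup.lesions]
    by_label = {l.label: l for l in baseline.lesions}
    out = []
    for lab in labels:
        c = np.asarray(by_label[lab].centroid_mm)
        out.append(fu_labels[int(np.argmin(np.linalg.norm(fu_centroids - c, axis=1)))])
    return out


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre; baseline-referenced, requires pre > 0."""
    if not pre > 0:
        raise ContractError(f"percent change needs a positive baseline, got {pre}")
    return 100.0 * (post - pre) / pre


def combined_change(delta_v: float, delta_d: float) -> float:
    """The combined statistic d(V+D): the signed sum of dV and dD percents."""
    if not (np.isfinite(delta_v) and np.isfinite(delta_d)):
        raise ContractError("combined change requires finite inputs")
    return float(delta_v) + float(delta_d)


def recist_category(
    delta_s_pct: float, absolute_increase_mm: float = 0.0, all_targets_gone: bool = False
) -> str:
    """RECIST 1.1 category from the diameter-sum change.

    CR: all target lesions gone.  PR: at least a 30% decrease in the sum.
    PD: at least a 20% increase AND an absolute increase of at least 5 mm.
    SD otherwise.
    """
    if all_targets_gone:
        return "CR"
    if delta_s_pct <= RECIST_PR_THRESHOLD_PCT:
        return "PR"
    if delta_s_pct >= RECIST_PD_THRESHOLD_PCT and absolute_increase_mm >= RECIST_PD_ABSOLUTE_MM:
        return "PD"
    return "SD"


@dataclass
class ResponseRecord:
    """Per-patient response summary: the four delta statistics plus RECIST."""

    delta_volume_pct: float
    delta_density_pct: float
    delta_size_pct: float | None
    combined_pct: float
    recist_category: str | None
    progression_group: str | None = field(default=None)
    pre_volume_cm3: float = float("nan")
    post_volume_cm3: float = float("nan")
    pre_density_hu: float = float("nan")
    post_density_hu: float = float("nan")
    pre_recist_sum_cm: float | None = None
    post_recist_sum_cm: float | None = None

    def __post_init__(self):
        if self.recist_category is not None and self.progression_group is None:
            self.progression_group = (
                "progression" if self.recist_category == "PD" else "nonprogression"
            )

    def to_dict(self) -> dict:
        return {
            "delta_volume_pct": self.delta_volume_pct,
            "delta_density_pct": self.delta_density_pct,
            "delta_size_pct": self.delta_size_pct,
            "combined_pct": self.combined_pct,
            "recist_category": self.recist_category,
            "progression_group": self.progression_group,
            "pre_volume_cm3": self.pre_volume_cm3,
            "post_volume_cm3": self.post_volume_cm3,
            "pre_density_hu": self.pre_density_hu,
            "post_density_hu": self.post_density_hu,
            "pre_recist_sum_cm": self.pre_recist_sum_cm,
            "post_recist_sum_cm": self.post_recist_sum_cm,
        }


def response_record(
    pre_lesions: LesionSet, post_lesions: LesionSet
) -> ResponseRecord:
    """All four delta statistics from paired pre/post lesion inventories.

    Both time points must have at least one tumor voxel (the deltas are
    baseline-referenced percentages).  RECIST targets are chosen at baseline
    and re-measured on the centroid-matched follow-up lesions; when no
    baseline lesion is measurable the size change and category are absent.
    """
    v_pre, v_post = total_volume(pre_lesions), total_volume(post_lesions)
    d_pre, d_post = mean_density(pre_lesions), mean_density(post_lesions)
    dv = percent_change(v_pre, v_post)
    dd = percent_change(d_pre, d_post)

    ds = None
    cat = None
    s_pre = s_post = None
    base = recist_sum(pre_lesions)
    if base is not None:
        s_pre, labels = base
        matched = match_lesions(pre_lesions, post_lesions, labels)
        s_post, _ = recist_sum(post_lesions, target_labels=matched)
        ds = percent_change(s_pre, s_post)
        cat = recist_category(ds, absolute_increase_mm=(s_post - s_pre) * 10.0)
    return ResponseRecord(
        delta_volume_pct=dv,
        delta_density_pct=dd,
        delta_size_pct=ds,
        combined_pct=combined_change(dv, dd),
        recist_category=cat,
        pre_volume_cm3=v_pre,
        post_volume_cm3=v_post,
        pre_density_hu=d_pre,
        post_density_hu=d_post,
        pre_recist_sum_cm=s_pre,
        post_recist_sum_cm=s_post,
    )
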