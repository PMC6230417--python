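"""Liver segmentation by a two-component Gaussian-mixture intensity model.

The liver is bright and fairly homogeneous on portal-venous CT (~100 HU),
surrounded by darker fat/lung/air and similar-intensity soft tissue.  The
segmentation follows a classic intensity-threshold recipe:

1. fit a 1-D two-component Gaussian mixture by EM to every intensity of a
   radiologist-chosen axial slice (one component captures liver parenchyma,
   the other everything else);
2. identify the liver component as the one whose mean is nearest the mean HU
   inside the manual seed region, and threshold the whole volume to
   ``[mu_L - k*sigma_L, mu_L + k*sigma_L]``;
3. keep the largest 26-connected component and close small holes with a ball
   structuring element.

The mixture is fitted on the *full* seed slice, not only inside the manual
mask: a two-component model needs to see both classes to separate them.  The
manual mask's mean HU is used only to pick the liver component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError, DegenerateDataError, EmptySegmentationError
from .io import BinaryMask, CTVolume

__all__ = [
    "GaussianMixtureModel",
    "IntensityRange",
    "fit_gmm_em",
    "estimate_liver_range",
    "segment_liver",
    "closing_ball",
]

VARIANCE_FLOOR = 1e-3  # HU^2; prevents singular components


@dataclass
class GaussianMixtureModel:
    """A fitted 1-D two-component Gaussian mixture.

    ``weights`` sum to one, ``variances`` are bounded below by
    :data:`VARIANCE_FLOOR`, and ``log_likelihood_trace`` holds the total
    log-likelihood after each EM iteration (non-decreasing by construction).
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood_trace: np.ndarray = field(repr=False)
    n_iter: int = 0

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities for each sample, shape (n, 2)."""
        log_p = _log_component_densities(np.asarray(x, float), self.weights, self.means, self.variances)
        log_norm = np.logaddexp(log_p[:, 0], log_p[:, 1])
        return np.exp(log_p - log_norm[:, None])


@dataclass
class IntensityRange:
    """HU interval attributed to liver parenchyma."""

    lo: float
    hi: float
    liver_component_index: int

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ContractError(f"require lo < hi, got [{self.lo}, {self.hi}]")


def _log_component_densities(x, weights, means, variances):
    # (n, 2) array of log(w_k * N(x | mu_k, var_k))
    x = x[:, None]
    return (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x - means[None, :]) ** 2 / variances[None, :]
    )


def fit_gmm_em(
    samples: np.ndarray,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GaussianMixtureModel:
    """Fit a two-component 1-D Gaussian mixture by expectation-maximization.

    Initialization splits the samples at their median and takes each half's
    moments, so the fit is fully deterministic; ``seed`` is accepted for API
    uniformity but does not influence the result.  Iterations stop when the
    relative log-likelihood improvement falls below ``tol`` or after
    ``max_iter`` iterations.

    Raises
    ------
    DegenerateDataError
        If fewer than 2 distinct sample values are supplied.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if max_iter < 1:
        raise ContractError("max_iter must be >= 1")
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDataError("need at least 2 distinct samples to fit a 2-component mixture")

    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    if upper.size == 0:  # heavy ties at the median
        lower, upper = x[x < med], x[x >= med]
    means = np.array([lower.mean(), upper.mean()])
    variances = np.maximum(np.array([lower.var(), upper.var()]), VARIANCE_FLOOR)
    weights = np.array([lower.size, upper.size], dtype=float) / x.size
    weights = np.clip(weights, 1e-6, None)
    weights /= weights.sum()

    trace = []
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_p = _log_component_densities(x, weights, means, variances)
        log_norm = np.logaddexp(log_p[:, 0], log_p[:, 1])
        resp = np.exp(log_p - log_norm[:, None])
        ll = float(log_norm.sum())
        trace.append(ll)
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(variances < VARIANCE_FLOOR):
            warnings.warn(
                f"variance collapse clamped to floor {VARIANCE_FLOOR} HU^2", stacklevel=2
            )
            variances = np.maximum(variances, VARIANCE_FLOOR)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            break
        ll_prev = ll

    return GaussianMixtureModel(
        weights=weights,
        means=means,
        variances=variances,
        log_likelihood_trace=np.asarray(trace),
        n_iter=n_iter,
    )


def estimate_liver_range(
    model: GaussianMixtureModel, seed_mask_mean: float, k: float = 2.5
) -> IntensityRange:
    """Turn the fitted mixture into an HU interval for the liver.

    The liver component is the one whose mean is nearest ``seed_mask_mean``
    (ties resolve to index 0 with a warning); the interval is
    ``mu_L ± k * sigma_L``.
    """
    if not k > 0:
        raise ContractError("k must be > 0")
    d = np.abs(model.means - seed_mask_mean)
    if d[0] == d[1]:
        warnings.warn("seed mean equidistant from both components; choosing index 0", stacklevel=2)
        idx = 0
    else:
        idx = int(np.argmin(d))
    mu = float(model.means[idx])
    sigma = float(np.sqrt(model.variances[idx]))
    return IntensityRange(lo=mu - k * sigma, hi=mu + k * sigma, liver_component_index=idx)


_BALL_CACHE: dict[int, np.ndarray] = {}


def _ball(radius: int) -> np.ndarray:
    # radius 1 uses the Chebyshev unit ball (full 3x3x3 box): the Euclidean
    # digital ball of radius 1 is a 7-voxel cross whose opening erodes the
    # corners of rectangular solids; larger radii use the Euclidean ball
    if radius not in _BALL_CACHE:
        r = int(radius)
        if r == 1:
            _BALL_CACHE[radius] = np.ones((3, 3, 3), dtype=bool)
        else:
            zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
            _BALL_CACHE[radius] = (zz**2 + yy**2 + xx**2) <= r**2
    return _BALL_CACHE[radius]


def closing_ball(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a ball, padded so the result ⊇ the input.

    Unpadded closing can erode foreground touching the array border (the
    dilation is clipped before the erosion); padding by the radius restores
    the extensivity guarantee of closing on the infinite lattice.
    """
    if radius <= 0:
        return mask.copy()
    r = int(radius)
    padded = np.pad(mask, r, mode="constant")
    closed = ndimage.binary_closing(padded, structure=_ball(r))
    out = closed[r:-r, r:-r, r:-r]
    return out | mask


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component (6, 18 or 26-connectivity)."""
    structure = _connectivity_structure(connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ContractError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def segment_liver(
    volume: CTVolume,
    seed_slice_index: int,
    seed_mask_2d: np.ndarray,
    k: float = 2.5,
    closing_radius_vox: int = 2,
    fill_holes: bool = True,
    return_details: bool = False,
):
    """Segment the liver from a seeded axial slice.

    Parameters
    ----------
    volume : CTVolume
        Portal-phase CT in HU.
    seed_slice_index : int
        Index of the manually annotated axial slice (a large mid-liver slice).
    seed_mask_2d : 2-D bool array
        Manual liver mask on that slice; only its mean HU is used, to decide
        which mixture component is liver.
    k : float
        Half-width of the liver HU interval in liver-component standard
        deviations.
    closing_radius_vox : int
        Ball radius for the hole-closing step; 0 disables it.
    fill_holes : bool
        Also fill fully enclosed interior cavities.  Hypodense lesions fall
        outside the parenchyma HU range but are still liver tissue; filling
        them keeps the liver region usable as the tumor-classification ROI.
    return_details : bool
        Also return the fitted model and intensity range.

    Raises
    ------
    EmptySegmentationError
        If thresholding to the estimated range selects no voxel.
    """
    nz = volume.shape[0]
    if not 0 <= seed_slice_index < nz:
        raise ContractError(f"seed slice {seed_slice_index} outside [0, {nz})")
    seed_mask_2d = np.asarray(seed_mask_2d, dtype=bool)
    if seed_mask_2d.shape != volume.shape[1:]:
        raise ContractError(
            f"seed mask shape {seed_mask_2d.shape} != slice shape {volume.shape[1:]}"
        )
    if not seed_mask_2d.any():
        raise ContractError("seed mask is empty")

    slice_hu = volume.data[seed_slice_index]
    model = fit_gmm_em(slice_hu.ravel())
    rng = estimate_liver_range(model, float(slice_hu[seed_mask_2d].mean()), k=k)

    thresholded = (volume.data >= rng.lo) & (volume.data <= rng.hi)
    if not thresholded.any():
        raise EmptySegmentationError(
            f"threshold range [{rng.lo:.1f}, {rng.hi:.1f}] HU selected no voxels"
        )
    component = largest_component(thresholded, connectivity=26)
    closed = closing_ball(component, closing_radius_vox)
    if fill_holes:
        closed = ndimage.binary_fill_holes(closed)
    mask = BinaryMask(closed, volume.spacing)
    if return_details:
        return mask, model, rng
    return mask
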