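"""Whole-islet quantification: alignment, illumination correction, Otsu
islet detection, background subtraction, per-islet measurement and
co-localisation.

The detection route is: sum the endocrine marker planes, threshold at the
Otsu level, morphologically close and fill holes, then drop connected
components below a minimum area (ten cells' worth by default, mirroring
the >= 10 cells/cluster inclusion rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .image import MultiChannelImage

__all__ = [
    "DegenerateHistogramError",
    "IsletObject",
    "otsu_threshold",
    "align_channels",
    "correct_illumination",
    "detect_islets",
    "subtract_background",
    "measure_islet",
    "manders_coefficients",
    "measure_image_islets",
]

# per-cell footprint on the *detected* mask scale: cytoplasm + nucleus of a
# typical islet cell (~117 um^2) plus the smoothing/closing halo
DEFAULT_MEDIAN_CELL_AREA_UM2 = 130.0


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested on a (near-)constant signal."""


@dataclass
class IsletObject:
    """One connected islet region and its per-channel measurements."""

    islet_id: int
    mask: np.ndarray
    area_um2: float
    occupied_area_fraction: dict[str, float] = field(default_factory=dict)
    mean_intensity: dict[str, float] = field(default_factory=dict)
    median_intensity: dict[str, float] = field(default_factory=dict)
    manders: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# thresholding


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximising threshold on a 256-bin histogram
    of the observed intensity range.

    Returns the centre of the highest bin assigned to the lower class;
    classify as positive with ``value > threshold``.  When several cut
    points tie (the variance is flat across an empty gap between modes),
    the middle of the tied run is taken, so the threshold sits mid-gap.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DegenerateHistogramError("no finite values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise DegenerateHistogramError("constant signal: threshold undefined")
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist.astype(np.float64) / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b2 = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b2[~np.isfinite(sigma_b2)] = -np.inf
    # a valid cut leaves mass on both sides
    sigma_b2[-1] = -np.inf
    best = sigma_b2.max()
    ties = np.flatnonzero(sigma_b2 >= best - 1e-12 * abs(best))
    k = int(ties[(ties.size - 1) // 2])
    return float(centers[k])


# ---------------------------------------------------------------------------
# preprocessing


def align_channels(
    image: MultiChannelImage,
    reference_channel: str,
    max_shift_px: int = 10,
) -> tuple[MultiChannelImage, dict[str, tuple[int, int]]]:
    """Integer-translation registration of every plane to a reference.

    Each non-reference plane is shifted by the integer translation that
    maximises its cross-correlation with the reference.  A shift whose
    magnitude exceeds ``max_shift_px`` is treated as spurious: a warning
    is emitted and the plane is left untouched.
    """
    ref = image.plane(reference_channel)
    planes = image.planes.copy()
    shifts: dict[str, tuple[int, int]] = {}
    for i, name in enumerate(image.channel_names):
        if name == reference_channel:
            shifts[name] = (0, 0)
            continue
        shift, _, _ = phase_cross_correlation(ref, planes[i], upsample_factor=1)
        sy, sx = int(round(shift[0])), int(round(shift[1]))
        if max(abs(sy), abs(sx)) > max_shift_px:
            warnings.warn(
                f"channel {name!r}: estimated shift ({sy}, {sx}) exceeds "
                f"bound {max_shift_px}; leaving unaligned",
                stacklevel=2,
            )
            shifts[name] = (0, 0)
            continue
        planes[i] = np.roll(planes[i], (sy, sx), axis=(0, 1))
        shifts[name] = (sy, sx)
    return image.with_planes(planes), shifts


def correct_illumination(
    plane: np.ndarray,
    smoothing_scale_um: float,
    pixel_size_um: float,
    robust: bool = True,
) -> np.ndarray:
    """Flat-field correction by division with a heavily smoothed copy.

    The output is rescaled to preserve the global mean (within 0.1%).
    ``smoothing_scale_um`` should be well above one cell diameter so that
    individual cells do not imprint on the estimated field.  With
    ``robust`` (default) the field is a low-order surface fitted to the
    background pixels, so bright objects (islets) cannot bleed into the
    estimate; otherwise a plain Gaussian blur of the plane is used.
    """
    plane = np.asarray(plane, dtype=np.float64)
    sigma_px = smoothing_scale_um / pixel_size_um
    if robust:
        field = _background_surface(plane)
    else:
        field = ndi.gaussian_filter(plane, sigma=sigma_px, mode="reflect")
    eps = 1e-6 * max(field.max(), 1.0)
    if (field <= 0).any():
        warnings.warn("smoothed field contains zeros; flooring at epsilon", stacklevel=2)
        field = np.maximum(field, eps)
    corrected = plane / field
    mean_in = plane.mean()
    mean_out = corrected.mean()
    if mean_out > 0:
        corrected *= mean_in / mean_out
    return corrected


def _background_surface(plane: np.ndarray) -> np.ndarray:
    """Quadratic illumination surface fitted to background pixels.

    Foreground (above the Otsu cut) is excluded from the fit, so the
    estimate interpolates smoothly through bright objects.  The surface
    is normalised to mean 1 before use as a divisor.
    """
    h, w = plane.shape
    try:
        t = otsu_threshold(plane)
        mask = plane <= t
    except DegenerateHistogramError:
        mask = np.ones_like(plane, dtype=bool)
    if mask.sum() < 64:
        mask = np.ones_like(plane, dtype=bool)
    ys, xs = np.mgrid[0:h, 0:w]
    yn = ys / max(h - 1, 1) * 2.0 - 1.0
    xn = xs / max(w - 1, 1) * 2.0 - 1.0
    basis = np.stack(
        [np.ones_like(yn), yn, xn, yn * yn, xn * xn, yn * xn], axis=-1
    )
    sel_idx = np.flatnonzero(mask.ravel())
    if sel_idx.size > 20000:
        sel_idx = sel_idx[:: sel_idx.size // 20000 + 1]
    a = basis.reshape(-1, 6)[sel_idx]
    b = plane.ravel()[sel_idx]
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    field = basis.reshape(-1, 6) @ coef
    field = field.reshape(h, w)
    m = field.mean()
    if m != 0:
        field = field / m
    else:
        field = np.ones_like(field)
    # a physical illumination field stays within a modest range of 1;
    # clamping keeps corner extrapolation from exploding the division
    return np.clip(field, 0.25, 4.0)


# ---------------------------------------------------------------------------
# islet detection and measurement


def detect_islets(
    image: MultiChannelImage,
    marker_channels: list[str],
    min_cells: int = 10,
    min_area_um2: float | None = None,
    median_cell_area_um2: float = DEFAULT_MEDIAN_CELL_AREA_UM2,
    closing_radius_um: float = 6.0,
    smoothing_um: float = 3.0,
) -> list[IsletObject]:
    """Detect islets on the summed endocrine marker planes.

    The summed plane is smoothed at roughly the cell scale before the
    Otsu cut, so sub-cellular texture does not fragment the tissue-level
    bimodality; closing with a one-cell-radius disk plus hole filling
    then bridges marker-dim cells inside the islet.  Components smaller
    than ``min_area_um2`` (default: ``min_cells`` times a median cell
    area) are discarded.  Returns disjoint masks; an image with no
    surviving component yields an empty list.
    """
    total = np.zeros(image.shape, dtype=np.float64)
    for ch in marker_channels:
        total += image.plane(ch)
    if smoothing_um > 0:
        total = ndi.gaussian_filter(total, sigma=smoothing_um / image.pixel_size_um)
    try:
        t = otsu_threshold(total)
    except DegenerateHistogramError:
        return []
    fg = total > t
    if not fg.any():
        return []
    radius_px = max(1, int(round(closing_radius_um / image.pixel_size_um)))
    fg = ndi.binary_closing(fg, structure=disk(radius_px))
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    if min_area_um2 is None:
        min_area_um2 = min_cells * median_cell_area_um2
    px_area = image.pixel_area_um2()
    islets: list[IsletObject] = []
    counts = np.bincount(labels.ravel())
    next_id = 0
    for lab in range(1, n + 1):
        area = counts[lab] * px_area
        if area < min_area_um2:
            continue
        islets.append(
            IsletObject(islet_id=next_id, mask=labels == lab, area_um2=float(area))
        )
        next_id += 1
    return islets


def subtract_background(
    image: MultiChannelImage, islet_masks: list[IsletObject] | list[np.ndarray]
) -> MultiChannelImage:
    """Subtract, per channel, the median intensity outside all islet masks;
    negative results are clipped to zero."""
    union = np.zeros(image.shape, dtype=bool)
    for m in islet_masks:
        union |= m.mask if isinstance(m, IsletObject) else m
    outside = ~union
    if not outside.any():
        raise ValueError("islet masks cover the entire image; background undefined")
    planes = image.planes.copy()
    for i in range(planes.shape[0]):
        bg = float(np.median(planes[i][outside]))
        planes[i] = np.clip(planes[i] - bg, 0.0, None)
    return image.with_planes(planes)


def manders_coefficients(
    intensities_a: np.ndarray,
    intensities_b: np.ndarray,
    threshold_a: float,
    threshold_b: float,
    region: np.ndarray | None = None,
) -> tuple[float, float]:
    """Thresholded Manders coefficients over a region of interest.

    ``M1`` is the fraction of channel-A intensity (summed over A-positive
    pixels) that falls on B-positive pixels; ``M2`` is symmetric.  A
    channel with no positive pixels yields ``nan`` for its coefficient,
    with a warning.
    """
    a = np.asarray(intensities_a, dtype=np.float64)
    b = np.asarray(intensities_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("intensity arrays must have the same shape")
    if region is not None:
        a = a[region]
        b = b[region]
    pos_a = a >= threshold_a
    pos_b = b >= threshold_b
    denom_a = a[pos_a].sum()
    denom_b = b[pos_b].sum()
    if denom_a > 0:
        m1 = float(a[pos_b].sum() / denom_a)
    else:
        warnings.warn("no A-positive pixels; M1 undefined", stacklevel=2)
        m1 = float("nan")
    if denom_b > 0:
        m2 = float(b[pos_a].sum() / denom_b)
    else:
        warnings.warn("no B-positive pixels; M2 undefined", stacklevel=2)
        m2 = float("nan")
    return m1, m2


def measure_islet(
    islet: IsletObject,
    image: MultiChannelImage,
    positivity_thresholds: dict[str, float],
    manders_pairs: list[tuple[str, str]] | None = None,
) -> IsletObject:
    """Fill an islet's per-channel area fractions, intensities and
    (optionally) per-pair Manders coefficients.  Expects a
    background-subtracted image."""
    mask = islet.mask
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty islet mask")
    for ch in image.channel_names:
        vals = image.plane(ch)[mask]
        thr = positivity_thresholds.get(ch)
        if thr is not None:
            islet.occupied_area_fraction[ch] = float((vals >= thr).sum() / n_mask)
        islet.mean_intensity[ch] = float(vals.mean())
        islet.median_intensity[ch] = float(np.median(vals))
    for a, b in manders_pairs or []:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            islet.manders[(a, b)] = manders_coefficients(
                image.plane(a),
                image.plane(b),
                positivity_thresholds[a],
                positivity_thresholds[b],
                region=mask,
            )
    return islet


def within_islet_thresholds(
    image: MultiChannelImage,
    islets: list[IsletObject],
    channels: list[str],
    overrides: dict[str, float] | None = None,
) -> dict[str, float]:
    """Default per-channel positivity thresholds: Otsu over within-islet
    pixels, with manual overrides taking precedence."""
    union = np.zeros(image.shape, dtype=bool)
    for isl in islets:
        union |= isl.mask
    thresholds: dict[str, float] = {}
    for ch in channels:
        if overrides and ch in overrides:
            thresholds[ch] = float(overrides[ch])
            continue
        vals = image.plane(ch)[union]
        try:
            thresholds[ch] = otsu_threshold(vals)
        except DegenerateHistogramError:
            thresholds[ch] = float("inf")
    return thresholds


def measure_image_islets(
    image: MultiChannelImage,
    marker_channels: list[str],
    min_cells: int = 10,
    threshold_overrides: dict[str, float] | None = None,
    manders_pairs: list[tuple[str, str]] | None = None,
    median_cell_area_um2: float = DEFAULT_MEDIAN_CELL_AREA_UM2,
) -> tuple[pd.DataFrame, list[IsletObject], MultiChannelImage, dict[str, float]]:
    """Convenience whole-islet pipeline for one image.

    Detect islets, subtract background, derive positivity thresholds and
    measure every islet.  Returns the tidy measurement table plus the
    intermediate objects for further analysis.
    """
    islets = detect_islets(
        image, marker_channels, min_cells=min_cells,
        median_cell_area_um2=median_cell_area_um2,
    )
    if not islets:
        empty = pd.DataFrame()
        return empty, [], image, {}
    corrected = subtract_background(image, islets)
    thresholds = within_islet_thresholds(
        corrected, islets, marker_channels, overrides=threshold_overrides
    )
    rows = []
    for isl in islets:
        measure_islet(isl, corrected, thresholds, manders_pairs=manders_pairs)
        row: dict = {"islet_id": isl.islet_id, "area_um2": isl.area_um2}
        for ch in marker_channels:
            row[f"area_fraction_{ch}"] = isl.occupied_area_fraction[ch]
            row[f"mean_intensity_{ch}"] = isl.mean_intensity[ch]
            row[f"median_intensity_{ch}"] = isl.median_intensity[ch]
        for (a, b), (m1, m2) in isl.manders.items():
            row[f"manders_m1_{a}_{b}"] = m1
            row[f"manders_m2_{a}_{b}"] = m2
        rows.append(row)
    return pd.DataFrame(rows), islets, corrected, thresholds
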