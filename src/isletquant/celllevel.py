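"""Single-cell quantification: nucleus detection, cytoplasm expansion,
per-cell measurement, threshold classification, combinatorial phenotyping
and per-cell co-localisation.

Nucleus detection is a classical stand-in for a learned detector: the
nuclear plane is smoothed, thresholded (Otsu) and each connected component
is seeded with the local maxima of a Laplacian-of-Gaussian response at the
expected nucleus scale; components carrying more than one seed are split
by watershed.  Cells are grown from nuclei by a distance-bounded Voronoi
expansion, clipped to the islet mask for islet cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import expand_labels, watershed

from .image import MultiChannelImage
from .isletlevel import (
    DegenerateHistogramError,
    IsletObject,
    manders_coefficients,
    otsu_threshold,
)

__all__ = [
    "detect_nuclei",
    "expand_cells",
    "measure_cells",
    "determine_cell_thresholds",
    "classify_cells",
    "cell_manders",
    "proinsulin_insulin_ratio",
    "peri_islet_exocrine_cells",
    "phenotype_class",
]

DEFAULT_EXPANSION_UM = 5.0
DEFAULT_PERI_ISLET_UM = 20.0


def _islet_union(islet_masks) -> np.ndarray | None:
    if islet_masks is None:
        return None
    masks = [m.mask if isinstance(m, IsletObject) else m for m in islet_masks]
    if not masks:
        return None
    union = np.zeros_like(masks[0], dtype=bool)
    for m in masks:
        union |= m
    return union


def _islet_label_image(islet_masks) -> np.ndarray | None:
    if islet_masks is None:
        return None
    masks = [m.mask if isinstance(m, IsletObject) else m for m in islet_masks]
    if not masks:
        return None
    lab = np.full(masks[0].shape, -1, dtype=np.int32)
    for i, m in enumerate(masks):
        ident = islet_masks[i].islet_id if isinstance(islet_masks[i], IsletObject) else i
        lab[m] = ident
    return lab


# ---------------------------------------------------------------------------
# segmentation


def detect_nuclei(
    nuclear_plane: np.ndarray,
    pixel_size_um: float,
    expected_diameter_um: float = 6.0,
    islet_masks=None,
    membership_tolerance_um: float = 2.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect and label nuclei on the nuclear counterstain plane.

    Returns ``(labels, table)`` where ``labels`` is an int32 label image
    (0 = background) and ``table`` has one row per nucleus: centroid,
    area, and an ``endocrine_candidate`` flag (nucleus overlaps an islet
    mask).  A blank plane yields an empty labelling with a warning.
    """
    if expected_diameter_um <= 0:
        raise ValueError("expected_diameter_um must be > 0")
    plane = np.asarray(nuclear_plane, dtype=np.float64)
    d_px = expected_diameter_um / pixel_size_um
    smooth = ndi.gaussian_filter(plane, sigma=max(1.0, 0.15 * d_px))
    # threshold the raw plane: a smoothed mask is biased outward by about
    # a pixel ring, which inflates every downstream area
    try:
        t = otsu_threshold(plane)
    except DegenerateHistogramError:
        warnings.warn("blank nuclear plane: no nuclei detected", stacklevel=2)
        return np.zeros(plane.shape, dtype=np.int32), _empty_nucleus_table()
    mask = plane > t
    min_px = max(4, int(0.15 * np.pi * (d_px / 2) ** 2))
    lab0, n0 = ndi.label(mask)
    sizes = np.bincount(lab0.ravel())
    mask &= sizes[lab0] >= min_px
    if not mask.any():
        warnings.warn("no nuclei above threshold", stacklevel=2)
        return np.zeros(plane.shape, dtype=np.int32), _empty_nucleus_table()
    # LoG blob response at the expected nucleus scale
    log_resp = -ndi.gaussian_laplace(smooth, sigma=d_px / (2.0 * np.sqrt(2.0)))
    comp, n_comp = ndi.label(mask)
    min_dist = max(2, int(round(0.55 * d_px)))
    peaks = peak_local_max(
        log_resp, min_distance=min_dist, labels=comp, exclude_border=False
    )
    markers = np.zeros(plane.shape, dtype=np.int32)
    seeded = np.zeros(n_comp + 1, dtype=bool)
    next_marker = 1
    for py, px_ in peaks:
        markers[py, px_] = next_marker
        seeded[comp[py, px_]] = True
        next_marker += 1
    # guarantee one seed per component (tiny/flat nuclei may carry no peak)
    for lab in range(1, n_comp + 1):
        if not seeded[lab]:
            m = comp == lab
            flat = np.argmax(np.where(m, log_resp, -np.inf))
            py, px_ = np.unravel_index(flat, plane.shape)
            markers[py, px_] = next_marker
            next_marker += 1
    labels = watershed(-log_resp, markers=markers, mask=mask).astype(np.int32)
    core_union = _islet_union(islet_masks)
    union = core_union
    if union is not None and membership_tolerance_um > 0:
        # marker-dim cells on the islet rim still belong to the islet
        r = max(1, int(round(membership_tolerance_um / pixel_size_um)))
        union = ndi.binary_dilation(union, iterations=r)
    rows = []
    px_area = pixel_size_um**2
    for lab in range(1, next_marker):
        m = labels == lab
        n = int(m.sum())
        if n == 0:
            continue
        ys, xs = np.nonzero(m)
        endocrine = bool(union[ys, xs].any()) if union is not None else False
        # strict membership (majority of the nucleus inside the raw mask):
        # used to build clean per-batch intensity distributions
        core = (
            bool(core_union[ys, xs].mean() >= 0.5)
            if core_union is not None
            else False
        )
        rows.append(
            {
                "nucleus_id": lab,
                "centroid_row": float(ys.mean()),
                "centroid_col": float(xs.mean()),
                "nucleus_area_um2": n * px_area,
                "endocrine_candidate": endocrine,
                "core_islet": core,
            }
        )
    return labels, pd.DataFrame(rows) if rows else _empty_nucleus_table()


def _empty_nucleus_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "nucleus_id",
            "centroid_row",
            "centroid_col",
            "nucleus_area_um2",
            "endocrine_candidate",
            "core_islet",
        ]
    )


def expand_cells(
    nucleus_labels: np.ndarray,
    nucleus_table: pd.DataFrame,
    islet_masks,
    pixel_size_um: float,
    max_expansion_um: float = DEFAULT_EXPANSION_UM,
    membership_tolerance_um: float = 0.0,
) -> np.ndarray:
    """Grow cell masks from nuclei by bounded nearest-nucleus expansion.

    Contested pixels go to the nearest nucleus (Voronoi rule).  Cells
    whose nucleus overlaps an islet are clipped to the islet union
    (optionally dilated by a tolerance); other cells are clipped to the
    non-islet field.  Every cell mask contains its nucleus; masks are
    pairwise disjoint.
    """
    if nucleus_labels.max() == 0:
        return np.zeros_like(nucleus_labels)
    dist_px = max_expansion_um / pixel_size_um
    expanded = expand_labels(nucleus_labels, distance=dist_px)
    union = _islet_union(islet_masks)
    if union is None:
        return expanded.astype(np.int32)
    if membership_tolerance_um > 0:
        r = max(1, int(round(membership_tolerance_um / pixel_size_um)))
        union = ndi.binary_dilation(union, iterations=r)
    endo = np.zeros(int(nucleus_labels.max()) + 1, dtype=bool)
    if len(nucleus_table):
        endo[nucleus_table["nucleus_id"].to_numpy()] = nucleus_table[
            "endocrine_candidate"
        ].to_numpy()
    is_endo_px = endo[expanded]
    allowed = np.where(is_endo_px, union, ~union)
    cells = np.where(allowed | (nucleus_labels > 0), expanded, 0)
    return cells.astype(np.int32)


# ---------------------------------------------------------------------------
# measurement


def measure_cells(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    nucleus_table: pd.DataFrame,
    image: MultiChannelImage,
    islet_masks=None,
    membership_tolerance_um: float = 2.0,
) -> pd.DataFrame:
    """Per-cell areas, N/C ratio and per-channel mean intensities.

    Cytoplasm is the cell mask minus the nucleus mask; the N/C ratio is
    nucleus area over cytoplasm area.  Expects an aligned,
    background-subtracted image.
    """
    ids = nucleus_table["nucleus_id"].to_numpy() if len(nucleus_table) else np.array([], int)
    if ids.size == 0:
        return pd.DataFrame()
    max_lab = int(max(cell_labels.max(), nucleus_labels.max()))
    index = np.arange(1, max_lab + 1)
    cell_px = np.bincount(cell_labels.ravel(), minlength=max_lab + 1)[1:]
    nuc_px = np.bincount(nucleus_labels.ravel(), minlength=max_lab + 1)[1:]
    if (cell_px[ids - 1] == 0).any():
        raise ValueError("cell mask with zero pixels")
    px_area = image.pixel_area_um2()
    islet_lab = _islet_label_image(islet_masks)
    if islet_lab is not None and membership_tolerance_um > 0:
        r = membership_tolerance_um / image.pixel_size_um
        islet_lab = expand_labels((islet_lab + 1).astype(np.int32), distance=r) - 1
    df = pd.DataFrame({"cell_id": index})
    df["cell_area_um2"] = cell_px * px_area
    df["nucleus_area_um2"] = nuc_px * px_area
    df["cytoplasm_area_um2"] = (cell_px - nuc_px) * px_area
    with np.errstate(divide="ignore", invalid="ignore"):
        df["nc_ratio"] = np.where(
            df["cytoplasm_area_um2"] > 0,
            df["nucleus_area_um2"] / df["cytoplasm_area_um2"],
            np.nan,
        )
    for ch in image.channel_names:
        means = ndi.mean(image.plane(ch), labels=cell_labels, index=index)
        df[f"mean_{ch}"] = means
    nt = nucleus_table.set_index("nucleus_id")
    df = df[df["cell_id"].isin(ids)].reset_index(drop=True)
    df["centroid_row"] = nt.loc[df["cell_id"], "centroid_row"].to_numpy()
    df["centroid_col"] = nt.loc[df["cell_id"], "centroid_col"].to_numpy()
    df["endocrine_candidate"] = nt.loc[df["cell_id"], "endocrine_candidate"].to_numpy()
    if "core_islet" in nt.columns:
        df["core_islet"] = nt.loc[df["cell_id"], "core_islet"].to_numpy()
    if islet_lab is not None:
        cy = df["centroid_row"].round().astype(int).clip(0, islet_lab.shape[0] - 1)
        cx = df["centroid_col"].round().astype(int).clip(0, islet_lab.shape[1] - 1)
        df["islet_id"] = islet_lab[cy, cx]
        # an endocrine candidate whose centroid falls just outside keeps the
        # islet of its nucleus overlap
        df.loc[df["endocrine_candidate"] & (df["islet_id"] < 0), "islet_id"] = -1
    else:
        df["islet_id"] = -1
    return df


class NoPositivePopulation(ValueError):
    """The cell-mean distribution shows no separable positive mode."""


def _fit_log_gmm2(x: np.ndarray, n_iter: int = 100):
    """Deterministic 1D two-component EM on log intensities.

    Initialised from the Otsu split; returns (weights, means, variances,
    log-likelihood).
    """
    try:
        t = otsu_threshold(x)
    except DegenerateHistogramError:
        t = float(np.median(x))
    lo, hi = x[x < t], x[x >= t]
    if not lo.size or not hi.size:
        t = float(np.median(x))
        lo, hi = x[x < t], x[x >= t]
    if not lo.size or not hi.size:
        return None
    w = np.array([lo.size, hi.size], float) / x.size
    mu = np.array([lo.mean(), hi.mean()])
    var = np.array([lo.var() + 1e-6, hi.var() + 1e-6])
    ll = -np.inf
    for _ in range(n_iter):
        log_p = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi * var)[:, None]
            - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
        )
        m = log_p.max(axis=0)
        lse = m + np.log(np.exp(log_p - m).sum(axis=0))
        new_ll = lse.sum()
        resp = np.exp(log_p - lse)
        nk = resp.sum(axis=1) + 1e-12
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2 + 1e-6
        if abs(new_ll - ll) < 1e-9:
            ll = new_ll
            break
        ll = new_ll
    return w, mu, var, ll


def has_positive_population(
    values: np.ndarray, min_component_ratio: float = 2.5
) -> bool:
    """Decide whether a cell-mean distribution carries a positive mode.

    A two-component Gaussian mixture on log intensities must beat the
    single Gaussian on BIC, and the bright component's mean must exceed
    the dim component's by at least ``min_component_ratio`` (multiplicative).
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 10:
        return False
    x = np.log(v)
    n = x.size
    var1 = x.var() + 1e-12
    ll1 = -0.5 * n * (np.log(2 * np.pi * var1) + 1.0)
    bic1 = 2 * np.log(n) - 2 * ll1
    fit = _fit_log_gmm2(x)
    if fit is None:
        return False
    w, mu, var, ll2 = fit
    bic2 = 5 * np.log(n) - 2 * ll2
    if bic2 >= bic1:
        return False
    separation = float(np.exp(abs(mu[1] - mu[0])))
    return separation >= min_component_ratio


def _gmm_boundary(values: np.ndarray) -> float | None:
    """Equal-posterior decision boundary of the two-component log-GMM.

    More stable than Otsu under heavy class imbalance (a 90/10 split
    drags the between-class-variance optimum into the dominant mode).
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 10:
        return None
    fit = _fit_log_gmm2(np.log(v))
    if fit is None:
        return None
    w, mu, var, _ = fit
    order = np.argsort(mu)
    w, mu, var = w[order], mu[order], var[order]
    # solve equal-posterior quadratic a x^2 + b x + c = 0 on the log scale
    a = 0.5 / var[0] - 0.5 / var[1]
    b = mu[1] / var[1] - mu[0] / var[0]
    c = (
        0.5 * mu[0] ** 2 / var[0]
        - 0.5 * mu[1] ** 2 / var[1]
        + np.log(w[0] / np.sqrt(var[0]))
        - np.log(w[1] / np.sqrt(var[1]))
    )
    roots: list[float] = []
    if abs(a) < 1e-12:
        if abs(b) > 1e-12:
            roots = [-c / b]
    else:
        disc = b**2 - 4 * a * c
        if disc >= 0:
            roots = [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
    between = [r for r in roots if mu[0] < r < mu[1]]
    if not between:
        return float(np.exp(0.5 * (mu[0] + mu[1])))
    return float(np.exp(between[0]))


def determine_cell_thresholds(
    cells: pd.DataFrame,
    channel: str,
    method: str = "otsu",
    manual_value: float | None = None,
    min_cells: int = 20,
    require_bimodal: bool = True,
) -> float:
    """Positivity threshold on the distribution of cell mean intensities.

    Default: Otsu over the per-cell means for the channel (one threshold
    per staining batch).  ``method='manual'`` uses ``manual_value``.  With
    ``require_bimodal`` (default), a batch whose distribution shows no
    separable bright mode (:func:`has_positive_population`) raises
    :class:`NoPositivePopulation` so every cell is treated as negative.
    """
    col = f"mean_{channel}"
    if col not in cells.columns:
        raise KeyError(f"no measured means for channel {channel!r}")
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual method requires manual_value")
        return float(manual_value)
    if method not in ("otsu", "gmm", "hybrid"):
        raise ValueError(f"unknown method {method!r}")
    vals = cells[col].to_numpy(dtype=float)
    if vals.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells to derive a threshold")
    if np.std(vals) < 1e-12 * max(1.0, abs(np.mean(vals))):
        raise DegenerateHistogramError(
            f"cell-mean distribution for {channel!r} is degenerate; "
            "supply a manual threshold"
        )
    if require_bimodal and not has_positive_population(vals):
        raise NoPositivePopulation(
            f"channel {channel!r}: cell-mean distribution shows no "
            "separable positive mode; treating batch as negative"
        )
    t_otsu = otsu_threshold(vals)
    if method == "otsu":
        return t_otsu
    t_gmm = _gmm_boundary(vals)
    if t_gmm is None:
        return t_otsu
    if method == "gmm":
        return t_gmm
    # hybrid: both estimators fail towards the positive mode when they
    # fail at all, so the lower candidate is the safer cut
    return float(min(t_otsu, t_gmm))


def phenotype_class(flags: dict[str, bool], order: list[str]) -> str:
    """Canonical class label from ordered marker flags, e.g.
    ``ins+proins-pc13+``; all-negative cells are ``triple-negative``."""
    if not any(flags[ch] for ch in order):
        return "triple-negative"
    return "".join(f"{ch}{'+' if flags[ch] else '-'}" for ch in order)


def classify_cells(
    cells: pd.DataFrame, thresholds: dict[str, float], marker_channels: list[str]
) -> pd.DataFrame:
    """Flag each cell per marker (mean >= threshold counts as positive;
    ties are positive by convention) and derive the combinatorial class."""
    for ch in marker_channels:
        if ch not in thresholds:
            raise KeyError(f"missing threshold for channel {ch!r}")
    out = cells.copy()
    for ch in marker_channels:
        out[f"flag_{ch}"] = out[f"mean_{ch}"].to_numpy(dtype=float) >= thresholds[ch]
    out["phenotype"] = [
        phenotype_class({ch: row[f"flag_{ch}"] for ch in marker_channels}, marker_channels)
        for _, row in out.iterrows()
    ]
    return out


def phenotype_counts(cells: pd.DataFrame, marker_channels: list[str]) -> pd.DataFrame:
    """Counts per phenotype class over the 2^k flag combinations."""
    combos = []
    k = len(marker_channels)
    for bits in range(2**k):
        flags = {ch: bool(bits >> i & 1) for i, ch in enumerate(marker_channels)}
        combos.append(phenotype_class(flags, marker_channels))
    counts = cells["phenotype"].value_counts()
    rows = [{"phenotype": c, "n_cells": int(counts.get(c, 0))} for c in dict.fromkeys(combos)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived per-cell read-outs


def cell_manders(
    cell_mask: np.ndarray,
    image: MultiChannelImage,
    channel_a: str,
    channel_b: str,
    thresholds: dict[str, float],
) -> tuple[float, float]:
    """Manders coefficients restricted to one cell mask."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return manders_coefficients(
            image.plane(channel_a),
            image.plane(channel_b),
            thresholds[channel_a],
            thresholds[channel_b],
            region=cell_mask,
        )


def cells_manders(
    cells: pd.DataFrame,
    cell_labels: np.ndarray,
    image: MultiChannelImage,
    channel_a: str,
    channel_b: str,
    thresholds: dict[str, float],
    only_positive: bool = True,
) -> pd.DataFrame:
    """Per-cell Manders for one channel pair, appended as columns.

    By default only cells flagged positive for both channels get a value
    (others are NaN); the donor-level summary is then the mean over
    positive cells.
    """
    out = cells.copy()
    m1 = np.full(len(out), np.nan)
    m2 = np.full(len(out), np.nan)
    slices = ndi.find_objects(cell_labels)
    plane_a = image.plane(channel_a)
    plane_b = image.plane(channel_b)
    ta, tb = thresholds[channel_a], thresholds[channel_b]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (_, row) in enumerate(out.iterrows()):
            if only_positive and not (
                row.get(f"flag_{channel_a}", True)
                and row.get(f"flag_{channel_b}", True)
            ):
                continue
            lab = int(row["cell_id"])
            if lab - 1 >= len(slices) or slices[lab - 1] is None:
                continue
            sl = slices[lab - 1]
            mask = cell_labels[sl] == lab
            m1[i], m2[i] = manders_coefficients(
                plane_a[sl], plane_b[sl], ta, tb, region=mask
            )
    out[f"manders_m1_{channel_a}_{channel_b}"] = m1
    out[f"manders_m2_{channel_a}_{channel_b}"] = m2
    return out


def proinsulin_insulin_ratio(
    cells: pd.DataFrame,
    proins_channel: str = "proins",
    ins_channel: str = "ins",
) -> pd.Series:
    """Per-cell proinsulin/insulin mean-intensity ratio.

    Only insulin-positive cells qualify; cells with zero insulin mean are
    excluded (NaN) and counted via the returned series' NaNs.
    """
    flag_col = f"flag_{ins_channel}"
    ins = cells[f"mean_{ins_channel}"].to_numpy(dtype=float)
    pro = cells[f"mean_{proins_channel}"].to_numpy(dtype=float)
    qualify = (cells[flag_col].to_numpy() if flag_col in cells else ins > 0) & (ins > 0)
    ratio = np.where(qualify, pro / np.where(ins > 0, ins, np.nan), np.nan)
    return pd.Series(ratio, index=cells.index, name="proins_ins_ratio")


def peri_islet_exocrine_cells(
    cells: pd.DataFrame,
    islet_masks,
    pixel_size_um: float,
    max_distance_um: float = DEFAULT_PERI_ISLET_UM,
) -> pd.DataFrame:
    """Exocrine cells whose centroid lies within ``max_distance_um`` of an
    islet boundary."""
    union = _islet_union(islet_masks)
    exo = cells[~cells["endocrine_candidate"]].copy()
    if union is None or not len(exo):
        return exo.iloc[0:0]
    dist_px = ndi.distance_transform_edt(~union)
    cy = exo["centroid_row"].round().astype(int).clip(0, union.shape[0] - 1)
    cx = exo["centroid_col"].round().astype(int).clip(0, union.shape[1] - 1)
    d_um = dist_px[cy, cx] * pixel_size_um
    return exo[d_um <= max_distance_um]
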