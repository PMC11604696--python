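"""Rendering of synthetic multiplex-IF islet images with per-cell truth.

Geometry
--------
Each islet is a radially perturbed disc sized to the summed target cell
areas.  Cell positions and relative sizes come from an iteratively
reweighted (capacity-adjusted) power diagram of the disc; each cell's
nucleus is an ellipse at its region centroid, and the cell boundary is
then defined by bounded nearest-nucleus expansion (the same convention a
nucleus-seeded segmenter uses — membranes are not imaged, so cell extent
is a convention, and sharing it keeps per-cell recovery well-posed).
Delta cells get elongated nuclei/regions, emulating the profiles that
defeat 2D single-cell segmentation.  The surrounding field is tiled with
exocrine cells the same way at a density set by the exocrine target
area.  Ground truth is always measured from the rendered masks.

Intensity
---------
Marker signal lives in sub-cellular "granule" pixels: a positive cell gets
granules at intensity ``I`` (lognormal draw) over a dim cytoplasmic
baseline ``b*I``; a negative cell gets a dim uniform level.  For a
configured channel pair, positive-positive cells share a fraction ``c`` of
their granule pixels, which makes the thresholded Manders coefficient
analytically ``c + b*(1-c)``.  Illumination gradient, uniform background,
integer channel shifts and additive Gaussian noise are applied last;
exceeding the declared dynamic range is an error, never a silent clip.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.segmentation import expand_labels

from ..image import MultiChannelImage
from .config import CELL_TYPES, GeneratorConfig
from .presets import group_metadata

__all__ = ["GeneratorError", "render_islet_image", "render_cohort"]

_EXO_NUCLEUS_UM2 = 30.0
_POS_TRUNC = 0.60   # truncation of the positive lognormal tail (rel. units)
_NUC_TRUNC = 0.80


class GeneratorError(RuntimeError):
    """Raised when an image cannot be rendered under the configuration."""


# ---------------------------------------------------------------------------
# geometry helpers


def _boundary_profile(rng: np.random.Generator, roughness: float):
    """Smooth random radial perturbation f(theta) with max |f| <= 1."""
    harmonics = np.arange(2, 7)
    amps = rng.uniform(0.3, 1.0, size=harmonics.size)
    phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
    norm = amps.sum() or 1.0

    def f(theta: np.ndarray) -> np.ndarray:
        out = np.zeros_like(theta, dtype=float)
        for a, k, p in zip(amps, harmonics, phases):
            out += a * np.cos(k * theta + p)
        return roughness * out / norm

    return f


def _partition_islet(rng, specs, radius_px, roughness):
    """Partition a perturbed disc into len(specs) cells.

    Returns (islet_mask, labels, half) on a local square grid of side
    2*half+1 centred on the islet centre; labels are 0..n-1 inside the
    islet and -1 outside.
    """
    n = len(specs)
    targets = np.array([s["area_px"] for s in specs], dtype=float)
    profile = _boundary_profile(rng, roughness)
    half = int(math.ceil(radius_px * (1 + roughness))) + 2
    ys, xs = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    theta = np.arctan2(ys, xs)
    rr = np.hypot(ys, xs)
    islet_mask = rr <= radius_px * (1.0 + profile(theta))
    iy, ix = np.nonzero(islet_mask)
    if iy.size < n:
        raise GeneratorError("islet too small for requested cell count")

    # dart-throwing initial seeds, biggest cells first
    order = np.argsort(-targets)
    radii = np.sqrt(targets / np.pi)
    seeds = np.full((n, 2), np.nan)
    inner = rr <= max(1.0, radius_px * (1 - roughness) - 1.0)
    cy, cx = np.nonzero(inner & islet_mask)
    for i in order:
        placed = False
        for _ in range(200):
            j = rng.integers(cy.size)
            p = np.array([ys[cy[j], cx[j]], xs[cy[j], cx[j]]])
            ok = True
            for k in range(n):
                if not np.isnan(seeds[k, 0]):
                    if np.hypot(*(p - seeds[k])) < 0.75 * (radii[i] + radii[k]):
                        ok = False
                        break
            if ok:
                seeds[i] = p
                placed = True
                break
        if not placed:
            j = rng.integers(iy.size)
            seeds[i] = (ys[iy[j], ix[j]], xs[iy[j], ix[j]])

    aspects = np.array([s["aspect"] for s in specs])
    angles = np.array(
        [s.get("angle", rng.uniform(0, np.pi)) for s in specs]
    )
    weights = targets.copy()
    labels = np.full(islet_mask.shape, -1, dtype=np.int32)
    for _ in range(5):
        d2 = np.empty((n,) + islet_mask.shape)
        for i in range(n):
            dy = ys - seeds[i, 0]
            dx = xs - seeds[i, 1]
            ca, sa = math.cos(angles[i]), math.sin(angles[i])
            du = dy * ca + dx * sa
            dv = -dy * sa + dx * ca
            s = math.sqrt(aspects[i])
            d2[i] = ((du / s) ** 2 + (dv * s) ** 2) / weights[i]
        labels.fill(-1)
        labels[islet_mask] = np.argmin(d2[:, islet_mask], axis=0)
        areas = np.bincount(labels[islet_mask], minlength=n).astype(float)
        # reseed any starved cell at a random islet pixel
        for i in np.nonzero(areas == 0)[0]:
            j = rng.integers(iy.size)
            seeds[i] = (ys[iy[j], ix[j]], xs[iy[j], ix[j]])
            areas[i] = 1.0
        weights *= np.clip(targets / areas, 0.5, 2.0)
        for i in range(n):
            m = labels == i
            if m.any():
                seeds[i] = (ys[m].mean(), xs[m].mean())
    return islet_mask, labels, half


def _ellipse_mask(shape, center, area_px, aspect, angle):
    rn = math.sqrt(max(area_px, 1.0) / np.pi)
    s = math.sqrt(aspect)
    a1, a2 = rn * s, rn / s
    half = int(math.ceil(max(a1, a2))) + 1
    cy, cx = center
    y0, y1 = int(cy) - half, int(cy) + half + 1
    x0, x1 = int(cx) - half, int(cx) + half + 1
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
    ys, xs = np.mgrid[y0c:y1c, x0c:x1c].astype(float)
    dy, dx = ys - cy, xs - cx
    ca, sa = math.cos(angle), math.sin(angle)
    du = dy * ca + dx * sa
    dv = -dy * sa + dx * ca
    inside = (du / a1) ** 2 + (dv / a2) ** 2 <= 1.0
    return (slice(y0c, y1c), slice(x0c, x1c)), inside


# ---------------------------------------------------------------------------
# intensity helpers


def _lognormal(rng, mu, sigma, trunc):
    return float(min(trunc, math.exp(rng.normal(mu, sigma))))


def _draw_flags(rng, config: GeneratorConfig, cell_type: str) -> dict[str, bool]:
    probs = {
        ch: config.marker_model(cell_type, ch).p_positive
        for ch in config.marker_channels
    }
    if config.positivity_coupling == "comonotone":
        u = rng.uniform()
        return {ch: bool(u < p) for ch, p in probs.items()}
    return {ch: bool(rng.uniform() < p) for ch, p in probs.items()}


# ---------------------------------------------------------------------------
# main renderer


def render_islet_image(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render one field of view; returns the image and its truth table.

    Deterministic for a fixed (config, seed).  The truth table holds one
    row per cell with its type, islet membership, rendered areas, marker
    positivity flags and expected cytoplasmic mean intensity (relative
    units).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    H, W = config.image_shape_px
    px_area = config.pixel_size_um**2
    channels = config.channel_names
    markers = config.marker_channels

    cell_label = np.zeros((H, W), dtype=np.int32)
    nucleus_label = np.zeros((H, W), dtype=np.int32)
    rows: list[dict] = []
    cell_pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    next_id = 1

    # endocrine fractions renormalised over islet cells
    fr = {ct: config.cell_type_fractions.get(ct, 0.0) for ct in CELL_TYPES}
    tot = sum(fr.values())
    if tot <= 0:
        raise GeneratorError("no endocrine cell types configured")
    type_p = np.array([fr[ct] / tot for ct in CELL_TYPES])

    # ---- sample and place islets -------------------------------------
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    for islet_id in range(config.n_islets):
        n_cells = int(
            max(
                config.min_cells_per_islet,
                round(rng.normal(config.cells_per_islet_mean, config.cells_per_islet_dispersion)),
            )
        )
        types = [CELL_TYPES[i] for i in rng.choice(3, size=n_cells, p=type_p)]
        specs = []
        for ct in types:
            morph = config.morphology[ct]
            factor = math.exp(rng.normal(0.0, morph.area_dispersion))
            cyto = morph.cytoplasm_area_um2 * factor
            nuc = morph.nucleus_area_um2 * factor
            specs.append(
                {
                    "type": ct,
                    "area_px": (cyto + nuc) / px_area,
                    "nucleus_px": nuc / px_area,
                    "aspect": morph.aspect_ratio,
                }
            )
        radius_px = math.sqrt(sum(s["area_px"] for s in specs) / np.pi)
        bound = radius_px * (1 + config.star_roughness) + 3
        margin = bound + 2
        if 2 * margin >= min(H, W):
            raise GeneratorError(
                f"islet of {n_cells} cells does not fit the image; "
                f"maximum feasible n_islets at this size: {islet_id}"
            )
        ok = False
        for _ in range(500):
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            if all(
                np.hypot(cy - py, cx - px_) > bound + pb + 4 for py, px_, pb in placed
            ):
                ok = True
                break
        if not ok:
            raise GeneratorError(
                f"could not place islet {islet_id + 1} without overlap; "
                f"maximum feasible n_islets: {islet_id}"
            )
        placed.append((cy, cx, bound))

        islet_mask, labels, half = _partition_islet(
            rng, specs, radius_px, config.star_roughness
        )
        oy, ox = int(round(cy)) - half, int(round(cx)) - half
        # nuclei at region centroids, clipped to their power-diagram region
        local_nuc = np.zeros(labels.shape, dtype=np.int32)
        centroids = {}
        for i, spec in enumerate(specs):
            m = labels == i
            if not m.any():
                continue
            ly, lx = np.nonzero(m)
            ctr = (ly.mean(), lx.mean())
            centroids[i] = ctr
            nuc_aspect = 2.0 if spec["type"] == "delta" else 1.2
            sl, ell = _ellipse_mask(
                labels.shape, ctr, spec["nucleus_px"], nuc_aspect,
                rng.uniform(0, np.pi),
            )
            nuc_sel = ell & (labels[sl] == i)
            local_nuc[sl][nuc_sel] = i + 1
            if not nuc_sel.any():
                j = np.argmin((ly - ctr[0]) ** 2 + (lx - ctr[1]) ** 2)
                local_nuc[ly[j], lx[j]] = i + 1
        # cell boundary convention: bounded nearest-nucleus expansion
        exp_px = config.cell_boundary_expansion_um / config.pixel_size_um
        local_cells = expand_labels(local_nuc, distance=exp_px)
        local_cells[~islet_mask] = 0
        for i, spec in enumerate(specs):
            if i not in centroids:
                continue
            cid = next_id
            next_id += 1
            ly, lx = np.nonzero(local_cells == i + 1)
            gy, gx = ly + oy, lx + ox
            sub_sel = cell_label[gy, gx] == 0
            gy, gx = gy[sub_sel], gx[sub_sel]
            if gy.size == 0:
                next_id -= 1
                continue
            cell_label[gy, gx] = cid
            ny, nx = np.nonzero(local_nuc == i + 1)
            nucleus_label[ny + oy, nx + ox] = cid
            n_nuc = ny.size
            ctr = (gy.mean(), gx.mean())
            cell_pixels[cid] = (gy, gx)
            rows.append(
                {
                    "cell_id": cid,
                    "islet_id": islet_id,
                    "cell_type": spec["type"],
                    "centroid_row": ctr[0],
                    "centroid_col": ctr[1],
                    "cytoplasm_area_um2": (gy.size - n_nuc) * px_area,
                    "nucleus_area_um2": n_nuc * px_area,
                }
            )

    # ---- exocrine tissue tiling --------------------------------------
    if config.include_exocrine:
        islet_union = cell_label > 0
        area_px_target = config.exocrine_cell_area_um2 / px_area
        spacing = math.sqrt(2.0 * area_px_target / math.sqrt(3.0))
        pts = []
        yy = spacing / 2
        row_i = 0
        while yy < H:
            xx = spacing / 2 + (spacing / 2 if row_i % 2 else 0)
            while xx < W:
                jy = yy + rng.uniform(-0.25, 0.25) * spacing
                jx = xx + rng.uniform(-0.25, 0.25) * spacing
                iy, ix = int(jy), int(jx)
                if 0 <= iy < H and 0 <= ix < W and not islet_union[iy, ix]:
                    pts.append((iy, ix))
                xx += spacing
            yy += spacing * math.sqrt(3.0) / 2
            row_i += 1
        seed_img = np.zeros((H, W), dtype=np.int32)
        exo_ids = []
        for iy, ix in pts:
            cid = next_id
            next_id += 1
            sl, ell = _ellipse_mask(
                (H, W), (iy, ix), _EXO_NUCLEUS_UM2 / px_area, 1.2,
                rng.uniform(0, np.pi),
            )
            place = ell & (seed_img[sl] == 0) & ~islet_union[sl]
            if not place.any():
                next_id -= 1
                continue
            seed_img[sl][place] = cid
            exo_ids.append(cid)
        exp_px = config.cell_boundary_expansion_um / config.pixel_size_um
        tiled = expand_labels(seed_img, distance=exp_px)
        tiled[islet_union] = 0
        for cid in exo_ids:
            m = tiled == cid
            gy, gx = np.nonzero(m)
            if gy.size < 4:
                continue
            cell_label[gy, gx] = cid
            nuc = seed_img[gy, gx] == cid
            nucleus_label[gy[nuc], gx[nuc]] = cid
            n_nuc = int(nuc.sum())
            ctr = (gy.mean(), gx.mean())
            cell_pixels[cid] = (gy, gx)
            rows.append(
                {
                    "cell_id": cid,
                    "islet_id": -1,
                    "cell_type": "exocrine",
                    "centroid_row": ctr[0],
                    "centroid_col": ctr[1],
                    "cytoplasm_area_um2": (gy.size - n_nuc) * px_area,
                    "nucleus_area_um2": n_nuc * px_area,
                }
            )

    # ---- intensities (relative units) --------------------------------
    planes = np.zeros((len(channels), H, W), dtype=np.float64)
    dapi = planes[0]
    marker_idx = {ch: channels.index(ch) for ch in markers}
    b = config.baseline_fraction
    g = config.granule_density

    for row in rows:
        cid = row["cell_id"]
        gy, gx = cell_pixels[cid]
        nuc = nucleus_label[gy, gx] == cid
        dapi[gy[nuc], gx[nuc]] = _lognormal(
            rng, config.nuclear_mu, config.nuclear_sigma, _NUC_TRUNC
        )
        if row["cell_type"] == "exocrine":
            for ch in markers:
                row[f"pos_{ch}"] = False
                row[f"intensity_{ch}"] = 0.0
            continue
        ct = row["cell_type"]
        flags = _draw_flags(rng, config, ct)
        cy_idx = np.nonzero(~nuc)[0]  # cytoplasm pixels (indices into gy/gx)
        n_pix = cy_idx.size
        # intensity draws per channel (scale_of ties ratios between markers)
        draws: dict[str, float] = {}
        for ch in markers:
            model = config.marker_model(ct, ch)
            if model.scale_of is None:
                draws[ch] = _lognormal(rng, model.mu_pos, model.sigma_pos, _POS_TRUNC)
        for ch in markers:
            model = config.marker_model(ct, ch)
            if model.scale_of is not None:
                draws[ch] = min(_POS_TRUNC, draws[model.scale_of] * model.scale_factor)
        if n_pix > 0:
            n_g = max(1, int(round(g * n_pix)))
            perm = rng.permutation(n_pix)
            granules: dict[str, np.ndarray] = {}
            for key, c in config.coloc_fraction.items():
                a, bch = key.split("+")
                if a in granules or bch in granules:
                    continue
                if flags.get(a) and flags.get(bch):
                    n_sh = int(round(c * n_g))
                    granules[a] = perm[:n_g]
                    granules[bch] = np.concatenate(
                        [perm[:n_sh], perm[n_g : 2 * n_g - n_sh]]
                    )
            for ch in markers:
                if flags[ch] and ch not in granules:
                    model = config.marker_model(ct, ch)
                    if model.scale_of is not None and model.scale_of in granules:
                        granules[ch] = granules[model.scale_of]
                    else:
                        granules[ch] = perm[:n_g]
            for ch in markers:
                plane = planes[marker_idx[ch]]
                model = config.marker_model(ct, ch)
                if flags[ch]:
                    intensity = draws[ch]
                    sel = cy_idx
                    plane[gy[sel], gx[sel]] = b * intensity
                    gr = cy_idx[granules[ch]]
                    plane[gy[gr], gx[gr]] = intensity
                    row[f"intensity_{ch}"] = intensity * (
                        g + b * (1 - g)
                    )
                else:
                    neg = _lognormal(rng, model.mu_neg, model.sigma_neg, _POS_TRUNC)
                    plane[gy[cy_idx], gx[cy_idx]] = neg
                    row[f"intensity_{ch}"] = neg
                row[f"pos_{ch}"] = bool(flags[ch])
        else:
            for ch in markers:
                row[f"pos_{ch}"] = bool(flags[ch])
                row[f"intensity_{ch}"] = 0.0

    # ---- field effects ------------------------------------------------
    planes += config.background_level
    if config.illumination_gradient_amplitude > 0:
        angle = rng.uniform(0, 2 * np.pi)
        ys, xs = np.mgrid[0:H, 0:W].astype(float)
        proj = (ys / max(H - 1, 1) - 0.5) * math.cos(angle) + (
            xs / max(W - 1, 1) - 0.5
        ) * math.sin(angle)
        field = 1.0 + config.illumination_gradient_amplitude * 2.0 * proj
        planes *= field[None]
    for ch, (sy, sx) in config.channel_shift_px.items():
        i = channels.index(ch)
        planes[i] = np.roll(planes[i], (int(sy), int(sx)), axis=(0, 1))
    if config.noise_sd > 0:
        planes += rng.normal(0.0, config.noise_sd, size=planes.shape)
    np.clip(planes, 0.0, None, out=planes)
    if planes.max() > 1.0:
        raise GeneratorError(
            "rendered intensity exceeds the declared dynamic range; "
            "reduce intensity/illumination parameters"
        )

    full_scale = 2**config.bit_depth - 1
    image = MultiChannelImage(
        planes=np.round(planes * full_scale),
        channel_names=list(channels),
        pixel_size_um=config.pixel_size_um,
        bit_depth=config.bit_depth,
    )
    truth = pd.DataFrame(rows)
    # column order: identity, geometry, then per-marker flags/intensities
    cols = [
        "cell_id",
        "islet_id",
        "cell_type",
        "centroid_row",
        "centroid_col",
        "cytoplasm_area_um2",
        "nucleus_area_um2",
    ]
    cols += [f"pos_{ch}" for ch in markers] + [f"intensity_{ch}" for ch in markers]
    truth = truth[cols]
    return image, truth


# ---------------------------------------------------------------------------
# cohort rendering


def _sanitize(label: str) -> str:
    return label.replace("+", "pos").replace("/", "_")


def render_cohort(
    config_per_group: dict[str, GeneratorConfig],
    n_donors_per_group: int,
    islets_per_donor: int,
    seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Render a donor cohort to disk: one folder per donor, one TIFF per
    islet, a per-donor truth CSV and a cohort metadata table.

    Per-donor and per-image seeds are derived deterministically from the
    master seed, so a re-run reproduces the dataset exactly.
    """
    if n_donors_per_group < 1:
        raise ValueError("n_donors_per_group must be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise GeneratorError(f"cannot create output directory {out}: {exc}") from exc
    meta_rows = []
    for gi, (group, config) in enumerate(sorted(config_per_group.items())):
        meta = group_metadata(group) if _has_group_meta(group) else {"age": 40.0, "duration": 0.0}
        for di in range(n_donors_per_group):
            donor_id = f"{_sanitize(group)}_{di:02d}"
            donor_dir = out / donor_id
            donor_dir.mkdir(exist_ok=True)
            jitter_rng = np.random.default_rng(
                np.random.SeedSequence((seed, gi, di, 982451653))
            )
            age = round(meta["age"] + jitter_rng.normal(0, 3.0), 1)
            duration = round(max(0.0, meta["duration"] + jitter_rng.normal(0, 1.0) * (meta["duration"] > 0)), 1)
            truths = []
            for k in range(islets_per_donor):
                img_seed = int(
                    np.random.SeedSequence((seed, gi, di, k)).generate_state(1)[0]
                )
                image, truth = render_islet_image(config, seed=img_seed)
                img_path = donor_dir / f"islet_{k:03d}.tiff"
                try:
                    image.save(img_path)
                except OSError as exc:
                    raise GeneratorError(f"write failed: {img_path}: {exc}") from exc
                truth.insert(0, "image_id", f"islet_{k:03d}")
                truths.append(truth)
            pd.concat(truths, ignore_index=True).to_csv(
                donor_dir / "truth.csv", index=False
            )
            config.save(donor_dir / "config.yaml")
            meta_rows.append(
                {
                    "donor_id": donor_id,
                    "group": group,
                    "age": age,
                    "diabetes_duration": duration,
                    "panel": config.panel,
                    "pixel_size_um": config.pixel_size_um,
                    "n_images": islets_per_donor,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    metadata.to_csv(out / "metadata.csv", index=False)
    return metadata


def _has_group_meta(group: str) -> bool:
    try:
        group_metadata(group)
        return True
    except Exception:
        return False
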