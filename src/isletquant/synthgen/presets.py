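"""Donor-group presets for the synthetic generator.

Each preset pins the generative parameters to published group-level
read-outs where a value is printed (individual-cell areas, positive-cell
percentages, co-localisation coefficients, intensity ratios) and to
documented defaults everywhere else.  Presets differ between groups only
in the parameters reported to differ.

Group labels: ``ND`` (non-diabetic), ``AAb+`` (autoantibody-positive,
non-diabetic), ``T1D_recent`` (type 1 diabetes, duration < 5 y),
``T1D_long`` (duration > 15 y), ``T2D`` (type 2 diabetes).
"""

from __future__ import annotations

from .config import CellMorphology, ConfigError, GeneratorConfig, MarkerModel

__all__ = ["GROUPS", "make_group_preset", "coloc_fraction_for_manders", "group_metadata"]

GROUPS = ("ND", "AAb+", "T1D_recent", "T1D_long", "T2D")

# shared-granule fraction c maps to a thresholded Manders coefficient
# M = c + b*(1-c) where b is the sub-threshold cytoplasmic baseline as a
# fraction of the granule intensity (see synthgen.render).
_BASELINE = 0.15


def coloc_fraction_for_manders(m_target: float, baseline: float = _BASELINE) -> float:
    """Invert the granule-sharing model: choose c so the expected Manders
    coefficient equals ``m_target``."""
    c = (m_target - baseline) / (1.0 - baseline)
    return float(min(1.0, max(0.0, c)))


# ---------------------------------------------------------------------------
# per-group morphometry (um^2).  Reported group means/medians where printed;
# unreported entries inherit the non-diabetic value.
_BETA_CYTO = {"ND": 86.83, "AAb+": 86.83, "T1D_recent": 73.52, "T1D_long": 49.75, "T2D": 86.83}
_BETA_NUC = {"ND": 30.69, "AAb+": 30.69, "T1D_recent": 29.48, "T1D_long": 25.40, "T2D": 30.69}
_ALPHA_CYTO = {"ND": 96.07, "AAb+": 96.07, "T1D_recent": 75.15, "T1D_long": 76.37, "T2D": 96.07}
_ALPHA_NUC = {"ND": 34.97, "AAb+": 34.97, "T1D_recent": 31.79, "T1D_long": 31.77, "T2D": 34.97}
_EXO_AREA = {"ND": 95.76, "AAb+": 95.76, "T1D_recent": 86.42, "T1D_long": 95.76, "T2D": 95.76}

# reported single-cell positive fractions (fraction of islet cells)
_PC13_CELL_FRAC = {"ND": 0.8375, "AAb+": 0.8375, "T1D_recent": 0.4201, "T1D_long": 0.4764, "T2D": 0.80}
_INS_CELL_FRAC = {"ND": 0.8534, "AAb+": 0.8534, "T1D_recent": 0.4155, "T1D_long": 0.0041, "T2D": 0.80}
_GCG_PC13_FRAC = {"ND": 0.3430, "AAb+": 0.3430, "T1D_recent": 0.6253, "T1D_long": 0.5824, "T2D": 0.5454}

# per-cell proinsulin/insulin intensity ratio (panel A)
_PROINS_RATIO = {"ND": 1.009, "AAb+": 1.009, "T1D_recent": 0.823, "T1D_long": 0.171, "T2D": 1.009}

# co-localisation (Manders) targets
_M_PC13_INS = {"ND": 0.845, "AAb+": 0.845, "T1D_recent": 0.60, "T1D_long": 0.347, "T2D": 0.845}
_M_PC13_GCG = {"ND": 0.624, "AAb+": 0.624, "T1D_recent": 0.817, "T1D_long": 0.730, "T2D": 0.624}

# islet composition per panel (endocrine fractions; tuned so that overall
# marker-positive cell fractions land near the printed medians)
_FRACTIONS_A = {
    "ND": {"beta": 0.88, "alpha": 0.07, "delta": 0.05},
    "AAb+": {"beta": 0.88, "alpha": 0.07, "delta": 0.05},
    "T1D_recent": {"beta": 0.52, "alpha": 0.34, "delta": 0.14},
    "T1D_long": {"beta": 0.30, "alpha": 0.50, "delta": 0.20},
    "T2D": {"beta": 0.75, "alpha": 0.17, "delta": 0.08},
}
_FRACTIONS_B = {
    "ND": {"beta": 0.59, "alpha": 0.36, "delta": 0.05},
    "AAb+": {"beta": 0.59, "alpha": 0.36, "delta": 0.05},
    "T1D_recent": {"beta": 0.12, "alpha": 0.76, "delta": 0.12},
    "T1D_long": {"beta": 0.15, "alpha": 0.70, "delta": 0.15},
    "T2D": {"beta": 0.35, "alpha": 0.575, "delta": 0.075},
}

# beta-cell marker positivity (panel A)
_BETA_PROBS_A = {
    "ND": {"ins": 0.97, "proins": 0.97, "pc13": 0.86},
    "AAb+": {"ins": 0.97, "proins": 0.97, "pc13": 0.86},
    "T1D_recent": {"ins": 0.80, "proins": 0.74, "pc13": 0.45},
    "T1D_long": {"ins": 0.014, "proins": 0.007, "pc13": 0.40},
    "T2D": {"ins": 0.95, "proins": 0.95, "pc13": 0.85},
}
_ALPHA_PC13_A = {"ND": 0.45, "AAb+": 0.45, "T1D_recent": 0.35, "T1D_long": 0.50, "T2D": 0.60}
_DELTA_PC13_A = {"ND": 0.90, "AAb+": 0.90, "T1D_recent": 0.50, "T1D_long": 0.55, "T2D": 0.90}

# panel B: probability that an alpha cell is PC1/3-positive, chosen so the
# glucagon+/PC1/3+ islet-cell fraction matches the printed value
_ALPHA_PC13_B = {
    g: min(1.0, _GCG_PC13_FRAC[g] / (_FRACTIONS_B[g]["alpha"] * 0.99)) for g in GROUPS
}

# donor metadata defaults (cohort table means)
_GROUP_META = {
    "ND": {"age": 31.6, "duration": 0.0},
    "AAb+": {"age": 20.8, "duration": 0.0},
    "T1D_recent": {"age": 20.3, "duration": 3.2},
    "T1D_long": {"age": 41.8, "duration": 24.3},
    "T2D": {"age": 42.6, "duration": 30.6},
}


def group_metadata(group: str) -> dict[str, float]:
    _check(group)
    return dict(_GROUP_META[group])


def _check(group: str) -> None:
    if group not in GROUPS:
        raise ConfigError(
            f"unknown group {group!r}; valid groups are {list(GROUPS)}"
        )


def _morphology(group: str) -> dict[str, CellMorphology]:
    return {
        "beta": CellMorphology(_BETA_CYTO[group], _BETA_NUC[group]),
        "alpha": CellMorphology(_ALPHA_CYTO[group], _ALPHA_NUC[group]),
        "delta": CellMorphology(70.0, 28.0, aspect_ratio=3.2),
    }


def _marker_models_a(group: str) -> dict[str, dict[str, MarkerModel]]:
    bp = _BETA_PROBS_A[group]
    ratio = _PROINS_RATIO[group]
    return {
        "beta": {
            "ins": MarkerModel(p_positive=bp["ins"]),
            "proins": MarkerModel(
                p_positive=bp["proins"], scale_of="ins", scale_factor=ratio
            ),
            "pc13": MarkerModel(p_positive=bp["pc13"]),
        },
        "alpha": {
            "ins": MarkerModel(p_positive=0.02),
            "proins": MarkerModel(p_positive=0.02),
            "pc13": MarkerModel(p_positive=_ALPHA_PC13_A[group]),
        },
        "delta": {
            "ins": MarkerModel(p_positive=0.02),
            "proins": MarkerModel(p_positive=0.02),
            "pc13": MarkerModel(p_positive=_DELTA_PC13_A[group]),
        },
    }


def _marker_models_b(group: str) -> dict[str, dict[str, MarkerModel]]:
    return {
        "beta": {
            "gcg": MarkerModel(p_positive=0.02),
            "sst": MarkerModel(p_positive=0.02),
            "pc13": MarkerModel(p_positive=0.85 if group in ("ND", "AAb+", "T2D") else 0.45),
        },
        "alpha": {
            "gcg": MarkerModel(p_positive=0.99),
            "sst": MarkerModel(p_positive=0.02),
            "pc13": MarkerModel(p_positive=_ALPHA_PC13_B[group]),
        },
        "delta": {
            "gcg": MarkerModel(p_positive=0.02),
            "sst": MarkerModel(p_positive=0.95),
            "pc13": MarkerModel(p_positive=0.90),
        },
    }


def make_group_preset(group: str, panel: str = "A", **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` for one donor group and panel.

    Parameters printed for the group are used as generative targets;
    everything else comes from documented defaults.  Keyword overrides are
    applied last (e.g. ``image_shape_px=(256, 256)``).
    """
    _check(group)
    if panel == "A":
        marker_models = _marker_models_a(group)
        fractions = _FRACTIONS_A[group]
        coloc = {
            "pc13+ins": coloc_fraction_for_manders(_M_PC13_INS[group]),
        }
        targets = {
            "beta_cytoplasm_area_um2": _BETA_CYTO[group],
            "beta_nucleus_area_um2": _BETA_NUC[group],
            "pc13_cell_fraction": _PC13_CELL_FRAC[group],
            "ins_cell_fraction": _INS_CELL_FRAC[group],
            "proins_ins_ratio": _PROINS_RATIO[group],
            "manders_pc13_ins": _M_PC13_INS[group],
            "exocrine_cell_area_um2": _EXO_AREA[group],
        }
    elif panel == "B":
        marker_models = _marker_models_b(group)
        fractions = _FRACTIONS_B[group]
        coloc = {
            "pc13+gcg": coloc_fraction_for_manders(_M_PC13_GCG[group]),
            "pc13+sst": coloc_fraction_for_manders(0.50),
        }
        targets = {
            "alpha_cytoplasm_area_um2": _ALPHA_CYTO[group],
            "alpha_nucleus_area_um2": _ALPHA_NUC[group],
            "gcg_pc13_cell_fraction": _GCG_PC13_FRAC[group],
            "manders_pc13_gcg": _M_PC13_GCG[group],
            "exocrine_cell_area_um2": _EXO_AREA[group],
        }
    else:
        raise ConfigError("panel must be 'A' or 'B'")

    cfg = GeneratorConfig(
        panel=panel,
        cell_type_fractions=dict(fractions),
        marker_models=marker_models,
        morphology=_morphology(group),
        coloc_fraction=coloc,
        baseline_fraction=_BASELINE,
        exocrine_cell_area_um2=_EXO_AREA[group],
        targets=targets,
    )
    if overrides:
        cfg = cfg.evolve(**overrides)
    cfg.validate()
    return cfg
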