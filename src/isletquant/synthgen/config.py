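"""Configuration schema for the synthetic multiplex-IF islet generator.

Intensities are expressed in *relative units* (fraction of the detector
full scale); rendered images are quantised to the configured bit depth.
Lognormal intensity models are parameterised by the log-median ``mu`` and
log-sd ``sigma`` of the relative intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "MarkerModel",
    "CellMorphology",
    "GeneratorConfig",
    "ConfigError",
]

NUCLEAR_CHANNEL = "dapi"
PANEL_CHANNELS = {
    "A": ["ins", "proins", "pc13"],
    "B": ["gcg", "sst", "pc13"],
}
CELL_TYPES = ("beta", "alpha", "delta")


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class MarkerModel:
    """Per cell-type, per-channel staining model.

    ``p_positive`` is the probability a cell of this type expresses the
    marker; positive cells draw a granule intensity from
    ``lognormal(mu_pos, sigma_pos)``, negative cells a dim uniform
    cytoplasmic level from ``lognormal(mu_neg, sigma_neg)``.  If
    ``scale_of`` names another channel, the positive intensity is that
    channel's draw times ``scale_factor`` instead (used to pin intensity
    ratios between co-expressed markers).
    """

    p_positive: float
    mu_pos: float = -1.4   # median ~0.25 of full scale
    sigma_pos: float = 0.15
    mu_neg: float = -3.5   # median ~0.03 of full scale
    sigma_neg: float = 0.20
    scale_of: Optional[str] = None
    scale_factor: float = 1.0

    def validate(self, label: str) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ConfigError(f"{label}: p_positive must be in [0, 1]")
        for name in ("sigma_pos", "sigma_neg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{label}: {name} must be >= 0")


@dataclass
class CellMorphology:
    """Cell-type shape model (areas in um^2)."""

    cytoplasm_area_um2: float
    nucleus_area_um2: float
    area_dispersion: float = 0.12   # lognormal sd of the shared size factor
    aspect_ratio: float = 1.0       # >= 3 emulates elongated delta profiles

    def validate(self, label: str) -> None:
        if not self.cytoplasm_area_um2 > 0:
            raise ConfigError(f"{label}: cytoplasm_area_um2 must be > 0")
        if not self.nucleus_area_um2 > 0:
            raise ConfigError(f"{label}: nucleus_area_um2 must be > 0")
        if self.aspect_ratio < 1.0:
            raise ConfigError(f"{label}: aspect_ratio must be >= 1")


@dataclass
class GeneratorConfig:
    """Full parameterisation of one synthetic image / donor panel."""

    image_shape_px: tuple[int, int] = (384, 384)
    pixel_size_um: float = 0.5
    bit_depth: int = 16
    panel: str = "A"
    n_islets: int = 1
    cells_per_islet_mean: float = 25.0
    cells_per_islet_dispersion: float = 4.0
    min_cells_per_islet: int = 10
    # endocrine fractions within islets; exocrine tissue fills the rest of
    # the field when include_exocrine is set
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: {"beta": 0.75, "alpha": 0.17, "delta": 0.08}
    )
    marker_models: dict[str, dict[str, MarkerModel]] = field(default_factory=dict)
    morphology: dict[str, CellMorphology] = field(default_factory=dict)
    star_roughness: float = 0.12
    # co-localisation: fraction of granule pixels shared between the two
    # channels of a pair, keyed "chA+chB"
    coloc_fraction: dict[str, float] = field(default_factory=dict)
    granule_density: float = 0.45
    baseline_fraction: float = 0.15
    # cell-boundary convention: nuclei expanded by this bound (matches the
    # analysis arm's expansion default; membranes are not imaged)
    cell_boundary_expansion_um: float = 5.0
    positivity_coupling: str = "comonotone"   # or "independent"
    nuclear_mu: float = -0.7    # median ~0.5 of full scale
    nuclear_sigma: float = 0.08
    background_level: float = 0.01
    noise_sd: float = 0.004
    illumination_gradient_amplitude: float = 0.0
    channel_shift_px: dict[str, tuple[int, int]] = field(default_factory=dict)
    include_exocrine: bool = True
    exocrine_cell_area_um2: float = 95.76
    seed: int = 0
    # documented paper-derived targets carried alongside the generative
    # parameters (used by presets and reporting, not by the renderer)
    targets: dict[str, float] = field(default_factory=dict)

    # ------------------------------------------------------------------

    @property
    def channel_names(self) -> list[str]:
        return [NUCLEAR_CHANNEL] + PANEL_CHANNELS[self.panel]

    @property
    def marker_channels(self) -> list[str]:
        return PANEL_CHANNELS[self.panel]

    def marker_model(self, cell_type: str, channel: str) -> MarkerModel:
        return self.marker_models[cell_type][channel]

    def pair_key(self, a: str, b: str) -> str:
        return f"{a}+{b}"

    def validate(self) -> None:
        h, w = self.image_shape_px
        if h < 32 or w < 32:
            raise ConfigError("image_shape_px must be at least 32x32")
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.panel not in PANEL_CHANNELS:
            raise ConfigError(f"panel must be one of {sorted(PANEL_CHANNELS)}")
        if self.n_islets < 1:
            raise ConfigError("n_islets must be >= 1")
        if self.min_cells_per_islet < 1:
            raise ConfigError("min_cells_per_islet must be >= 1")
        fr = self.cell_type_fractions
        if any(not 0.0 <= v <= 1.0 for v in fr.values()):
            raise ConfigError("cell_type_fractions must be in [0, 1]")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ConfigError("cell_type_fractions must sum to <= 1")
        for v in self.coloc_fraction.values():
            if not 0.0 <= v <= 1.0:
                raise ConfigError("coloc_fraction values must be in [0, 1]")
        if not 0.0 <= self.illumination_gradient_amplitude <= 0.5:
            raise ConfigError("illumination_gradient_amplitude must be in [0, 0.5]")
        if not 0.0 <= self.star_roughness <= 1.0:
            raise ConfigError("star_roughness must be in [0, 1]")
        if not 0.0 < self.granule_density <= 0.5:
            raise ConfigError("granule_density must be in (0, 0.5]")
        if self.positivity_coupling not in ("comonotone", "independent"):
            raise ConfigError("positivity_coupling must be comonotone|independent")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ConfigError("background_level and noise_sd must be >= 0")
        for ch, shift in self.channel_shift_px.items():
            if ch not in self.channel_names:
                raise ConfigError(f"channel_shift_px: unknown channel {ch!r}")
            if any(int(s) != s for s in shift):
                raise ConfigError("channel_shift_px entries must be integers")
        for ct in CELL_TYPES:
            if self.cell_type_fractions.get(ct, 0) > 0:
                if ct not in self.morphology:
                    raise ConfigError(f"morphology missing for cell type {ct!r}")
                self.morphology[ct].validate(f"morphology[{ct}]")
                for ch in self.marker_channels:
                    if ct not in self.marker_models or ch not in self.marker_models[ct]:
                        raise ConfigError(f"marker model missing for ({ct}, {ch})")
                    self.marker_model(ct, ch).validate(f"marker_models[{ct}][{ch}]")

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape_px"] = list(self.image_shape_px)
        d["channel_shift_px"] = {k: list(v) for k, v in self.channel_shift_px.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "image_shape_px" in d:
            d["image_shape_px"] = tuple(d["image_shape_px"])
        if "marker_models" in d:
            d["marker_models"] = {
                ct: {
                    ch: mm if isinstance(mm, MarkerModel) else MarkerModel(**mm)
                    for ch, mm in chans.items()
                }
                for ct, chans in d["marker_models"].items()
            }
        if "morphology" in d:
            d["morphology"] = {
                ct: m if isinstance(m, CellMorphology) else CellMorphology(**m)
                for ct, m in d["morphology"].items()
            }
        if "channel_shift_px" in d:
            d["channel_shift_px"] = {
                k: tuple(int(s) for s in v) for k, v in d["channel_shift_px"].items()
            }
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def evolve(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)
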