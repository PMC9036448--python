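"""Trait arithmetic from field sampling to canopy level.

Aboveground dry biomass per unit ground area is computed from a fresh-weight
harvest and an oven-dried subsample:

    biomass = TotalFW * (SubsampleDW / SubsampleFW) / HarvestedArea   [g m-2]

Leaf area index is green lamina area per stem times stem density; specific
leaf area and leaf mass per area are the area/mass ratio and its reciprocal.

Leaf-level light-saturated assimilation is upscaled to the canopy by
weighting each layer's rate with that layer's LAI and summing over the flag,
second and third leaf layers:

    A_canopy = sum_layers ( A_sat^layer * LAI^layer )    [umol m-2 ground s-1]

Stomatal conductance is pooled as the unweighted mean of the three layers
(an LAI-weighted variant is available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectra_io import LAYERS

__all__ = [
    "BiomassSample", "LayerProfile", "CanopyEstimate",
    "aboveground_biomass", "lai", "sla", "lma",
    "canopy_photosynthesis", "pooled_gs",
]


@dataclass(frozen=True)
class BiomassSample:
    """One destructive biomass harvest (fresh weights in g, area in m²)."""

    total_fw: float
    subsample_fw: float
    subsample_dw: float
    harvested_area: float

    def __post_init__(self):
        for name in ("total_fw", "subsample_fw", "subsample_dw", "harvested_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.subsample_dw > self.subsample_fw:
            raise ValueError("subsample dry weight exceeds its fresh weight")


@dataclass(frozen=True)
class LayerProfile:
    """Per-layer A_sat (umol m-2 s-1), g_s (mol m-2 s-1) and LAI (m2 m-2).

    Keys of the three dicts must be exactly the canopy layers
    ``top`` (flag leaf), ``middle`` (second leaf), ``bottom`` (third leaf).
    """

    asat: dict
    gs: dict
    lai: dict

    def __post_init__(self):
        for name, d in (("asat", self.asat), ("gs", self.gs), ("lai", self.lai)):
            missing = set(LAYERS) - set(d)
            if missing:
                raise ValueError(
                    f"{name} missing layers {sorted(missing)}; all three canopy "
                    "layers are required (no two-layer fallback)"
                )
        if any(v < 0 for v in self.lai.values()):
            raise ValueError("LAI must be non-negative")


@dataclass(frozen=True)
class CanopyEstimate:
    """Canopy photosynthesis and pooled conductance for one plot/stage."""

    canopy_asat: float
    pooled_gs: float

    @classmethod
    def from_profile(cls, profile: LayerProfile) -> "CanopyEstimate":
        return cls(canopy_photosynthesis(profile), pooled_gs(profile))


def aboveground_biomass(sample: BiomassSample) -> float:
    """Dry aboveground biomass in g m-2: fresh weight scaled by the
    subsample dry-matter fraction, per harvested area."""
    dry_fraction = sample.subsample_dw / sample.subsample_fw
    return sample.total_fw * dry_fraction / sample.harvested_area


def lai(green_area_per_stem: float, stems_per_m2: float) -> float:
    """Leaf area index: green lamina area per stem × stems per m² (unitless)."""
    if green_area_per_stem < 0 or stems_per_m2 < 0:
        raise ValueError("LAI inputs must be non-negative")
    return green_area_per_stem * stems_per_m2


def sla(green_area: float, dry_mass: float) -> float:
    """Specific leaf area, m² kg⁻¹."""
    if dry_mass <= 0:
        raise ValueError("dry mass must be positive")
    return green_area / dry_mass


def lma(dry_mass: float, green_area: float) -> float:
    """Leaf mass per area, kg m⁻² (reciprocal of SLA)."""
    if green_area <= 0:
        raise ValueError("green area must be positive")
    return dry_mass / green_area


def canopy_photosynthesis(profile: LayerProfile) -> float:
    """LAI-weighted sum of layer A_sat over the three canopy layers."""
    return float(sum(profile.asat[l] * profile.lai[l] for l in LAYERS))


def pooled_gs(profile: LayerProfile, lai_weighted: bool = False) -> float:
    """Canopy-pooled stomatal conductance.

    Default is the unweighted arithmetic mean of the three layers;
    ``lai_weighted=True`` weights each layer by its LAI instead.
    """
    if lai_weighted:
        total = sum(profile.lai[l] for l in LAYERS)
        if total <= 0:
            raise ValueError("LAI-weighted pooling needs positive total LAI")
        return float(sum(profile.gs[l] * profile.lai[l] for l in LAYERS) / total)
    return float(sum(profile.gs[l] for l in LAYERS) / len(LAYERS))
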