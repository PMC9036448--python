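"""In-silico spring-wheat field trials for end-to-end pipeline testing.

The generator emulates a three-year, replicated trial of 11 spring wheat
genotypes in which leaf reflectance (350–2500 nm), ten physiological traits,
leaf area index, daily irradiance and staged biomass are observed for the
top (flag), middle (second) and bottom (third) leaf layers at two growth
stages: initiation of booting (InB) and 7 days after anthesis (A7).

Structure of the generative model:

* Per-sample latent leaf state (chlorophyll, nitrogen, water, dry matter)
  drawn around layer × stage targets, with additive genotype and year
  effects.  Trait targets default to field means ± SDs typical of irrigated
  spring wheat canopies.
* Reflectance is a smooth continuum minus Gaussian absorption features
  scaled by the latents — chlorophyll features in the visible (430/460/
  670 nm) with a red-edge shoulder at 700–750 nm, water features at
  1450/1940 nm, nitrogen/dry-matter features at 2050–2200 nm — a minimal
  Beer–Lambert-flavored construction, not a radiative-transfer model.
* Traits are deterministic functions of the latents plus additive genotype,
  year and residual noise, so spectra are genuinely predictive of the
  traits (chlorophyll-linked traits most strongly).
* Biomass accumulates linearly with intercepted PAR at a per-genotype true
  RUE, with multiplicative lognormal noise; genotype RUE is optionally
  correlated with the genotype's photosynthesis effect so that trait
  predictions carry information about RUE.

Everything is driven by one integer seed: identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rue_blues import PAR_FRACTION, WeatherSeries
from .spectra_io import LAYERS, STAGES, TRAIT_NAMES, TRAIT_UNITS, SpectraSet, TraitTable

__all__ = [
    "DEFAULT_TRAIT_MEANS", "DEFAULT_TRAIT_SDS", "STAGE_DAYS",
    "TrialConfig", "LatentLeafState",
    "spectral_forward_model", "trait_from_latents", "generate_field_trial",
    "default_wavelengths",
]

# Layer x stage trait targets (mean, sd): irrigated spring wheat canopies,
# flag/second/third leaves at initiation of booting and 7 d after anthesis.
_TARGETS = {
    "Asat":    {"InB": {"top": (25.5, 3.07), "middle": (26.9, 4.70), "bottom": (15.9, 4.12)},
                "A7":  {"top": (22.0, 3.96), "middle": (16.7, 3.98), "bottom": (10.1, 3.70)}},
    "gs":      {"InB": {"top": (0.39, 0.12), "middle": (0.46, 0.15), "bottom": (0.34, 0.14)},
                "A7":  {"top": (0.32, 0.09), "middle": (0.25, 0.09), "bottom": (0.15, 0.06)}},
    "FvpFmp":  {"InB": {"top": (0.47, 0.03), "middle": (0.52, 0.03), "bottom": (0.50, 0.027)},
                "A7":  {"top": (0.52, 0.03), "middle": (0.54, 0.03), "bottom": (0.51, 0.03)}},
    "PhiPSII": {"InB": {"top": (0.31, 0.02), "middle": (0.31, 0.037), "bottom": (0.26, 0.04)},
                "A7":  {"top": (0.25, 0.029), "middle": (0.22, 0.029), "bottom": (0.17, 0.03)}},
    "LAI":     {"InB": {"top": (1.53, 0.33), "middle": (1.73, 0.33), "bottom": (1.75, 0.34)},
                "A7":  {"top": (1.43, 0.30), "middle": (2.31, 0.62), "bottom": (2.14, 0.54)}},
    "C":       {"InB": {"top": (44.5, 1.49), "middle": (44.2, 1.61), "bottom": (42.6, 1.64)},
                "A7":  {"top": (40.4, 2.15), "middle": (41.1, 4.16), "bottom": (43.4, 5.55)}},
    "N":       {"InB": {"top": (4.4, 0.34), "middle": (4.6, 0.40), "bottom": (4.2, 0.47)},
                "A7":  {"top": (4.0, 0.48), "middle": (3.7, 0.64), "bottom": (3.6, 0.80)}},
    "SLA":     {"InB": {"top": (19.8, 3.00), "middle": (20.4, 2.15), "bottom": (24.2, 1.92)},
                "A7":  {"top": (17.6, 2.27), "middle": (37.4, 5.04), "bottom": (31.9, 3.83)}},
    "LMA":     {"InB": {"top": (0.05, 0.010), "middle": (0.05, 0.005), "bottom": (0.04, 0.004)},
                "A7":  {"top": (0.06, 0.010), "middle": (0.04, 0.004), "bottom": (0.04, 0.005)}},
    "SPAD":    {"InB": {"top": (45.8, 2.16), "middle": (48.1, 1.71), "bottom": (45.3, 2.34)},
                "A7":  {"top": (50.6, 1.93), "middle": (49.3, 2.18), "bottom": (44.4, 2.78)}},
}

DEFAULT_TRAIT_MEANS = {
    t: {(l, s): _TARGETS[t][s][l][0] for s in STAGES for l in LAYERS}
    for t in _TARGETS
}
DEFAULT_TRAIT_SDS = {
    t: {(l, s): _TARGETS[t][s][l][1] for s in STAGES for l in LAYERS}
    for t in _TARGETS
}

#: loading of each trait on the standardized chlorophyll latent deviation
_CHL_LOADING = {
    "Asat": 0.55, "gs": 0.45, "FvpFmp": 0.35, "PhiPSII": 0.50,
}
#: traits that are deterministic transforms of a latent (no extra effects)
_LATENT_TRAITS = ("SPAD", "N", "LMA")
_NITROGEN_LOADING = {"C": 0.35}
_DRYMATTER_LOADING = {"SLA": -0.60}

#: days after emergence at which biomass is sampled
STAGE_DAYS = {"E40": 40, "InB": 75, "A7": 110, "PM": 140}

_EMERGENCE = {"Y1": "2017-12-12", "Y2": "2018-12-12", "Y3": "2019-12-26"}
_SEASON_DAYS = 150
_SPAD_PER_CHL = 50.0          # SPAD units per unit chlorophyll latent
_LMA_PER_DRYMATTER = 0.05     # kg m-2 of LMA per unit dry-matter latent
_WATER_BASE = {"InB": 1.0, "A7": 0.85}


@dataclass
class TrialConfig:
    """Design and noise structure of a synthetic field trial.

    Trait targets are (layer, stage)-keyed mean/SD matrices.  Genotype and
    year effects, the residual and the measurement error are expressed as
    fractions of each trait's cell SD so that one setting applies across
    traits spanning four orders of magnitude; their squares sum to at most 1
    so the realized cell SDs track the configured ones.
    """

    n_genotypes: int = 11
    n_reps: int = 3
    years: tuple = ("Y1", "Y2", "Y3")
    layers: tuple = LAYERS
    stages: tuple = STAGES
    trait_means: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_TRAIT_MEANS.items()})
    trait_sds: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_TRAIT_SDS.items()})
    spectral_noise_sd: float = 0.002      # reflectance units per band
    trait_noise_frac: float = 0.2         # measurement error, fraction of cell SD
    genotype_effect_frac: float = 0.4     # genotype intercept, fraction of cell SD
    year_effect_frac: float = 0.3         # year intercept, fraction of cell SD
    genotype_trait_corr: float = 0.7      # loading of physiological genotype
                                          # effects on a shared vigor factor
    rue_true: float = 3.0                 # g MJ-1 intercepted PAR
    rue_genotype_sd: float = 0.3          # g MJ-1 spread across genotypes
    rue_trait_linkage: float = 0.8        # corr(genotype RUE, genotype Asat effect)
    biomass_cv: float = 0.05              # lognormal CV of biomass observations
    seed: int = 1

    def __post_init__(self):
        if self.n_genotypes < 1 or self.n_reps < 1:
            raise ValueError("n_genotypes and n_reps must be positive")
        if tuple(self.layers) != LAYERS:
            raise ValueError(f"layers must be exactly {LAYERS} in order")
        unknown = set(self.trait_means) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(f"unknown trait names in mean matrix: {sorted(unknown)}")
        for t, cells in self.trait_sds.items():
            for key, sd in cells.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {t} at {key}")
        for frac in (self.trait_noise_frac, self.genotype_effect_frac,
                     self.year_effect_frac):
            if frac < 0:
                raise ValueError("effect fractions must be non-negative")
        if self.spectral_noise_sd < 0 or self.biomass_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if not -1 <= self.rue_trait_linkage <= 1:
            raise ValueError("rue_trait_linkage is a correlation in [-1, 1]")
        if not -1 <= self.genotype_trait_corr <= 1:
            raise ValueError("genotype_trait_corr is a correlation in [-1, 1]")

    @property
    def genotype_names(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]

    def cell(self, trait: str, layer: str, stage: str) -> tuple[float, float]:
        return (self.trait_means[trait][(layer, stage)],
                self.trait_sds[trait][(layer, stage)])

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        for key in ("trait_means", "trait_sds"):
            doc[key] = {t: {f"{l}:{s}": float(v) for (l, s), v in cells.items()}
                        for t, cells in doc[key].items()}
        doc["years"] = list(doc["years"])
        doc["layers"] = list(doc["layers"])
        doc["stages"] = list(doc["stages"])
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "TrialConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        for key in ("trait_means", "trait_sds"):
            if key in doc:
                doc[key] = {t: {tuple(k.split(":")): float(v)
                                for k, v in cells.items()}
                            for t, cells in doc[key].items()}
        for key in ("years", "layers", "stages"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass(frozen=True)
class LatentLeafState:
    """Latent drivers linking leaf composition to the reflectance spectrum."""

    chlorophyll: float   # arbitrary concentration units, ~1 for a healthy leaf
    nitrogen: float      # % dry mass
    water: float         # thickness-equivalent units, ~1
    dry_matter: float    # mass-per-area units, ~1

    def __post_init__(self):
        for name in ("chlorophyll", "nitrogen", "water", "dry_matter"):
            if getattr(self, name) < 0:
                raise ValueError(f"latent {name} must be non-negative")


def default_wavelengths() -> np.ndarray:
    """The 350–2500 nm, 1 nm field-spectroradiometer grid (2151 bands)."""
    return np.arange(350, 2501)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


_SHAPE_CACHE: dict[bytes, dict[str, np.ndarray]] = {}


def _feature_shapes(wl: np.ndarray) -> dict[str, np.ndarray]:
    key = wl.tobytes()
    if key not in _SHAPE_CACHE:
        wl = wl.astype(float)
        _SHAPE_CACHE[key] = {
            "baseline": 0.50 - 0.10 * (wl - 350.0) / 2150.0,
            # pigment absorption: blue/red features plus a red-edge shoulder
            "chl": (0.18 * _gauss(wl, 430, 22)
                    + 0.15 * _gauss(wl, 460, 20)
                    + 0.22 * _gauss(wl, 670, 38)
                    + 0.10 / (1.0 + np.exp((wl - 710.0) / 12.0))),
            "water": 0.18 * _gauss(wl, 1450, 55) + 0.25 * _gauss(wl, 1940, 85),
            "nitrogen": 0.012 * _gauss(wl, 2100, 45),
            "dry_matter": 0.05 * _gauss(wl, 2200, 60) + 0.04 * _gauss(wl, 2060, 45),
        }
    return _SHAPE_CACHE[key]


def spectral_forward_model(
    state: LatentLeafState, noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Reflectance on the 350–2500 nm grid for one latent leaf state.

    A smooth continuum minus latent-scaled Gaussian absorption features;
    with all latents zero and no noise the continuum is returned exactly.
    Output is clipped to [0, 1].
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    shapes = _feature_shapes(wl)
    refl = (shapes["baseline"]
            - state.chlorophyll * shapes["chl"]
            - state.water * shapes["water"]
            - state.nitrogen * shapes["nitrogen"]
            - state.dry_matter * shapes["dry_matter"])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        refl = refl + rng.normal(0.0, noise_sd, size=wl.size)
    return np.clip(refl, 0.0, 1.0)


def trait_from_latents(state: LatentLeafState, layer: str, stage: str,
                       config: TrialConfig) -> dict[str, float]:
    """Deterministic map from a latent leaf state to the ten traits.

    SPAD, N and LMA are direct transforms of their latents; the remaining
    traits sit at their layer × stage target shifted by loadings on the
    standardized latent deviations.  LAI is returned at its cell target
    (it is a canopy property, generated independently of leaf latents).
    """
    if layer not in config.layers or stage not in config.stages:
        raise ValueError(f"unknown layer/stage ({layer!r}, {stage!r})")

    out: dict[str, float] = {}
    out["SPAD"] = _SPAD_PER_CHL * state.chlorophyll
    out["N"] = state.nitrogen
    out["LMA"] = _LMA_PER_DRYMATTER * state.dry_matter

    def z(trait: str, value: float) -> float:
        mean, sd = config.cell(trait, layer, stage)
        return (value - mean) / sd if sd > 0 else 0.0

    z_chl = z("SPAD", out["SPAD"])
    z_n = z("N", out["N"])
    z_dm = z("LMA", out["LMA"])

    for trait, loading in _CHL_LOADING.items():
        mean, sd = config.cell(trait, layer, stage)
        out[trait] = mean + loading * z_chl * sd
    for trait, loading in _NITROGEN_LOADING.items():
        mean, sd = config.cell(trait, layer, stage)
        out[trait] = mean + loading * z_n * sd
    for trait, loading in _DRYMATTER_LOADING.items():
        mean, sd = config.cell(trait, layer, stage)
        out[trait] = mean + loading * z_dm * sd
    out["LAI"] = config.cell("LAI", layer, stage)[0]
    return out


def _fapar(day: np.ndarray | float) -> np.ndarray | float:
    """Seasonal fAPAR: logistic canopy closure reaching ~0.95."""
    return 0.95 / (1.0 + np.exp(-(np.asarray(day, dtype=float) - 30.0) / 7.0))


def _residual_frac(config: TrialConfig, extra_load: float = 0.0) -> float:
    used = (config.genotype_effect_frac ** 2 + config.year_effect_frac ** 2
            + config.trait_noise_frac ** 2 + extra_load ** 2)
    return float(np.sqrt(max(0.0, 1.0 - used)))


def generate_field_trial(
    config: TrialConfig | None = None,
) -> tuple[SpectraSet, TraitTable, WeatherSeries, pd.DataFrame]:
    """Generate one complete trial: spectra, traits, weather and biomass.

    Returns one spectrum and one full trait record per
    (genotype, rep, year, stage, layer) combination, a daily weather series
    covering all years, and a staged biomass table with the accumulated
    intercepted PAR each biomass observation corresponds to (plus the
    per-genotype true RUE, for recovery checks).
    """
    config = config or TrialConfig()
    rng = np.random.default_rng(config.seed)

    genotypes = config.genotype_names
    traits_all = list(_TARGETS)

    # additive effects in cell-SD units, consistent across cells; genotype
    # effects on physiological traits share a common "vigor" factor so a
    # genotype with more chlorophyll/N also photosynthesizes more — without
    # this, spectral predictions could never rank genotypes for RUE
    vigor = rng.standard_normal(config.n_genotypes)
    rho = {t: (config.genotype_trait_corr if t in
               ("Asat", "gs", "SPAD", "PhiPSII", "FvpFmp", "N", "LAI") else 0.0)
           for t in traits_all}
    z_geno = {
        t: config.genotype_effect_frac
           * (rho[t] * vigor + np.sqrt(1.0 - rho[t] ** 2)
              * rng.standard_normal(config.n_genotypes))
        for t in traits_all
    }
    z_year = {t: rng.normal(0.0, config.year_effect_frac, len(config.years))
              for t in traits_all}

    frac_e_latent = _residual_frac(config)          # SPAD / N / LMA structural part
    wl = default_wavelengths()

    meta_rows, trait_rows, spectra_rows = [], [], []
    for yi, year in enumerate(config.years):
        for gi, geno in enumerate(genotypes):
            for rep in range(1, config.n_reps + 1):
                plot = f"{year}-{geno}-R{rep}"
                for stage in config.stages:
                    for layer in config.layers:
                        sid = f"{plot}-{stage}-{layer}"

                        def core(trait: str) -> float:
                            mean, sd = config.cell(trait, layer, stage)
                            zz = (z_geno[trait][gi] + z_year[trait][yi]
                                  + frac_e_latent * rng.standard_normal())
                            return mean + zz * sd

                        state = LatentLeafState(
                            chlorophyll=max(core("SPAD"), 1.0) / _SPAD_PER_CHL,
                            nitrogen=max(core("N"), 0.05),
                            water=max(_WATER_BASE[stage]
                                      * (1.0 + 0.08 * rng.standard_normal()), 0.0),
                            dry_matter=max(core("LMA"), 1e-4) / _LMA_PER_DRYMATTER,
                        )
                        base = trait_from_latents(state, layer, stage, config)

                        values: dict[str, float] = {}
                        for t in traits_all:
                            mean, sd = config.cell(t, layer, stage)
                            if t in _LATENT_TRAITS:
                                values[t] = base[t] + \
                                    config.trait_noise_frac * sd * rng.standard_normal()
                            else:
                                load = (_CHL_LOADING.get(t)
                                        or _NITROGEN_LOADING.get(t)
                                        or _DRYMATTER_LOADING.get(t) or 0.0)
                                frac_res = _residual_frac(config, load)
                                noise = np.sqrt(frac_res ** 2
                                                + config.trait_noise_frac ** 2)
                                values[t] = base[t] + sd * (
                                    z_geno[t][gi] + z_year[t][yi]
                                    + noise * rng.standard_normal())

                        spectra_rows.append(spectral_forward_model(
                            state, config.spectral_noise_sd, rng, wl))
                        meta_rows.append({
                            "sample_id": sid, "genotype": geno, "plot": plot,
                            "replicate": rep, "year": year, "stage": stage,
                            "layer": layer,
                            "chlorophyll": state.chlorophyll,
                            "nitrogen": state.nitrogen,
                            "water": state.water,
                            "dry_matter": state.dry_matter,
                        })
                        for t in traits_all:
                            trait_rows.append({
                                "sample_id": sid, "trait": t,
                                "value": values[t], "units": TRAIT_UNITS[t],
                            })

    spectra = SpectraSet(wl, np.vstack(spectra_rows), pd.DataFrame(meta_rows))
    traits = TraitTable(pd.DataFrame(trait_rows))

    # --- weather: one daily series per year, concatenated chronologically
    weather_frames = []
    cum_ipar_by_year: dict[str, np.ndarray] = {}
    for yi, year in enumerate(config.years):
        t0 = pd.Timestamp(_EMERGENCE[year]) if year in _EMERGENCE else \
            pd.Timestamp("2017-12-15") + pd.DateOffset(years=yi)
        days = np.arange(_SEASON_DAYS + 1)
        irr = np.clip(14.0 + 10.0 * days / _SEASON_DAYS
                      + rng.normal(0.0, 1.5, days.size), 3.0, None)
        weather_frames.append(pd.DataFrame({
            "year": year,
            "date": t0 + pd.to_timedelta(days, unit="D"),
            "irradiance": irr,
        }))
        cum_ipar_by_year[year] = np.cumsum(irr * PAR_FRACTION * _fapar(days))
    weather = WeatherSeries(pd.concat(weather_frames, ignore_index=True))

    # --- per-genotype true RUE, optionally linked to the genotype's canopy
    # photosynthesis effect (direct Asat effect + chlorophyll-mediated part
    # + LAI effect), the quantity canopy upscaling actually estimates
    link = config.rue_trait_linkage
    dc = np.zeros(config.n_genotypes)
    for stage in config.stages:
        for layer in config.layers:
            a_mean, a_sd = config.cell("Asat", layer, stage)
            l_mean, l_sd = config.cell("LAI", layer, stage)
            dc += (a_sd * (z_geno["Asat"] + _CHL_LOADING["Asat"] * z_geno["SPAD"])
                   * l_mean + a_mean * l_sd * z_geno["LAI"]) / len(config.stages)
    g_std = dc / dc.std(ddof=0) if dc.std(ddof=0) > 0 else dc
    rue_g = (config.rue_true + config.rue_genotype_sd
             * (link * g_std
                + np.sqrt(max(0.0, 1.0 - link ** 2))
                * rng.standard_normal(config.n_genotypes)))

    sigma = float(np.sqrt(np.log1p(config.biomass_cv ** 2)))
    biomass_rows = []
    for yi, year in enumerate(config.years):
        cum = cum_ipar_by_year[year]
        for gi, geno in enumerate(genotypes):
            for rep in range(1, config.n_reps + 1):
                for stage, day in STAGE_DAYS.items():
                    noise = (np.exp(rng.normal(-sigma ** 2 / 2.0, sigma))
                             if sigma > 0 else 1.0)
                    biomass_rows.append({
                        "genotype": geno, "rep": rep, "year": year,
                        "stage": stage, "days_after_emergence": day,
                        "cum_ipar": float(cum[day]),
                        "biomass": float(rue_g[gi] * cum[day] * noise),
                        "rue_true": float(rue_g[gi]),
                    })
    biomass = pd.DataFrame(biomass_rows)

    return spectra, traits, weather, biomass
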