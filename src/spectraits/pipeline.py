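"""End-to-end experiment orchestration.

``run_experiment`` executes the whole analysis: load or simulate a trial,
filter trait outliers (±3 sd within layer × stage strata), split 70/30 into
training and validation, fit PLS1 models per canopy layer and/or with all
layers combined, choose the component count at the cross-validated RMSEP
minimum, evaluate on the held-out split, extract VIP band importance,
upscale leaf predictions to canopy photosynthesis and pooled conductance,
compute genotype BLUEs of predicted and observed canopy values, estimate
per-genotype RUE from staged biomass, and correlate trait predictions with
RUE.  Every random draw is traced to seeds carried in the configuration, so
a rerun with the same config is byte-identical.

The combined strategy pools all layers into one design of spectra only — no
layer indicator column — so the model must explain layer differences from
reflectance alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import canopy_traits, model_eval, plsr_core, preprocess, rue_blues, spectra_io
from .spectra_io import LAYERS, SpectraSet, TraitTable
from .synthetic_data import TrialConfig, generate_field_trial

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "compare_layer_strategies"]

log = logging.getLogger("spectraits.pipeline")

_LAYER_LABEL = {"top": "Top", "middle": "Middle", "bottom": "Bottom"}

#: growth intervals over which RUE slopes are fit (stage subsets of the
#: biomass series)
RUE_INTERVALS = {
    "E40-InB": ("E40", "InB"),
    "InB-A7": ("InB", "A7"),
    "GrainFill": ("A7", "PM"),
    "Total": ("E40", "InB", "A7", "PM"),
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    trial: TrialConfig | None = field(default_factory=TrialConfig)
    spectra_path: str | None = None       # file-driven mode (wide dialect)
    traits_path: str | None = None
    meta_path: str | None = None
    biomass_path: str | None = None

    traits: tuple = ("Asat", "gs", "SPAD")
    strategy: str = "both"                # per_layer | combined | both
    split_fraction: float = 0.7
    split_seed: int = 7
    outlier_k: float = 3.0
    outlier_stratified: bool = True
    stratify_split_by_layer: bool = False
    a_max: int = 15
    cv_scheme: str = "kfold"              # loo | kfold
    cv_k: int = 10
    vip_threshold: float = 1.0
    lai_source: str = "measured"          # measured | predicted
    out_dir: str | None = None

    def __post_init__(self):
        if not self.traits:
            raise ValueError("at least one trait must be modelled")
        if self.strategy not in ("per_layer", "combined", "both"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.lai_source not in ("measured", "predicted"):
            raise ValueError(f"unknown lai_source {self.lai_source!r}")
        if self.trial is None and (self.spectra_path is None
                                   or self.traits_path is None):
            raise ValueError("either a synthetic trial or data paths required")


@dataclass
class ExperimentReport:
    """All tables produced by one experiment run."""

    summary: pd.DataFrame
    vip_profiles: pd.DataFrame
    vip_regions: dict
    canopy: pd.DataFrame | None
    canopy_blues: pd.DataFrame | None
    canopy_eval: pd.DataFrame | None
    rue: pd.DataFrame | None
    rue_correlations: pd.DataFrame | None
    models: dict
    splits: dict


def _load(config: ExperimentConfig):
    if config.trial is not None:
        log.info("simulating synthetic trial (seed=%d)", config.trial.seed)
        return generate_field_trial(config.trial)
    meta = (spectra_io.read_sample_meta(config.meta_path)
            if config.meta_path else None)
    spectra = spectra_io.read_spectra(config.spectra_path, "wide", meta=meta)
    traits = spectra_io.read_traits(config.traits_path)
    biomass = (pd.read_csv(config.biomass_path)
               if config.biomass_path else None)
    return spectra, traits, None, biomass


def _strategies(config: ExperimentConfig) -> list[str]:
    per_layer = [_LAYER_LABEL[l] for l in LAYERS]
    if config.strategy == "per_layer":
        return per_layer
    if config.strategy == "combined":
        return ["Combined"]
    return per_layer + ["Combined"]


def _fit_one(spectra: SpectraSet, traits: TraitTable, trait: str,
             strategy: str, config: ExperimentConfig, seed: int):
    """Filter, split, fit, select components and evaluate one model."""
    if strategy == "Combined":
        subset = spectra
    else:
        layer = {v: k for k, v in _LAYER_LABEL.items()}[strategy]
        subset = spectra.select((spectra.meta["layer"] == layer).to_numpy())

    X_all, y_all, meta = spectra_io.join_spectra_traits(subset, traits, trait)
    y_series = pd.Series(y_all, index=meta["sample_id"])
    strata = (meta.set_index("sample_id")[["layer", "stage"]]
              if config.outlier_stratified
              and {"layer", "stage"} <= set(meta.columns) else None)
    y_kept, removed = preprocess.remove_outliers_stratified(
        y_series, strata, config.outlier_k)
    if removed:
        log.info("%s/%s: removed %d trait outliers", trait, strategy,
                 len(removed))

    ids = list(y_kept.index)
    split_strata = None
    if config.stratify_split_by_layer and strategy == "Combined":
        split_strata = meta.set_index("sample_id")["layer"]
    split = preprocess.split_train_validation(
        ids, config.split_fraction, seed, strata=split_strata)

    pos = pd.Series(np.arange(len(meta)), index=meta["sample_id"])
    tr = pos.loc[list(split.train_ids)].to_numpy()
    va = pos.loc[list(split.validation_ids)].to_numpy()
    X_tr, y_tr = X_all[tr], y_all[tr]
    X_va, y_va = X_all[va], y_all[va]

    model = plsr_core.fit_pls1(
        X_tr, y_tr, config.a_max, wavelengths=subset.wavelengths,
        provenance={"trait": trait, "strategy": strategy, "split_seed": seed})
    cv = model_eval.cross_validate(
        X_tr, y_tr, min(config.a_max, model.a_max),
        scheme=config.cv_scheme, k=config.cv_k, seed=seed + 1)
    model.selected_a = cv.selected_a

    rep_tr = model_eval.evaluate(y_tr, plsr_core.predict(model, X_tr))
    rep_va = model_eval.evaluate(y_va, plsr_core.predict(model, X_va))
    row = {
        "trait": trait, "layer": strategy,
        "n_train": split.n_train, "n_validation": split.n_validation,
        "rmsep_cv": cv.rmsep_by_a[cv.selected_a - 1],
        "n_comp": cv.selected_a,
        "r2_train": rep_tr.r2, "r2_validation": rep_va.r2,
        "rmse_v": rep_va.rmse, "bias_v": rep_va.bias,
        "bias_v_pct": rep_va.bias_pct,
    }
    return row, model, split


def _canopy_tables(spectra, traits, models, config):
    """Per-plot canopy photosynthesis / pooled gs, predicted and observed."""
    need = {"Asat", "gs"}
    if not need <= set(models):
        log.info("canopy upscaling skipped (needs combined Asat and gs models)")
        return None
    meta = spectra.meta
    if not {"genotype", "year", "replicate", "stage", "layer"} <= set(meta.columns):
        return None

    pred = {t: plsr_core.predict(models[t], spectra.reflectance)
            for t in ("Asat", "gs")}
    if config.lai_source == "predicted" and "LAI" in models:
        lai_pred = plsr_core.predict(models["LAI"], spectra.reflectance)
        lai_by_sample = pd.Series(lai_pred, index=meta["sample_id"])
    else:
        lai_by_sample = traits.trait("LAI")

    obs = {t: traits.trait(t) for t in ("Asat", "gs")}
    frame = meta[["sample_id", "genotype", "year", "replicate", "stage",
                  "layer"]].copy()
    frame["asat_pred"] = pred["Asat"]
    frame["gs_pred"] = pred["gs"]
    frame["asat_obs"] = frame["sample_id"].map(obs["Asat"]).to_numpy()
    frame["gs_obs"] = frame["sample_id"].map(obs["gs"]).to_numpy()
    frame["lai"] = frame["sample_id"].map(lai_by_sample).to_numpy()

    rows = []
    for (geno, year, rep, stage), grp in frame.groupby(
            ["genotype", "year", "replicate", "stage"], sort=True):
        if set(grp["layer"]) != set(LAYERS) or grp["lai"].isna().any():
            continue
        by_layer = grp.set_index("layer")
        lai = by_layer["lai"].to_dict()
        prof_pred = canopy_traits.LayerProfile(
            by_layer["asat_pred"].to_dict(), by_layer["gs_pred"].to_dict(), lai)
        prof_obs = canopy_traits.LayerProfile(
            by_layer["asat_obs"].to_dict(), by_layer["gs_obs"].to_dict(), lai)
        rows.append({
            "genotype": geno, "year": year, "rep": rep, "stage": stage,
            "canopy_asat_pred": canopy_traits.canopy_photosynthesis(prof_pred),
            "canopy_asat_obs": canopy_traits.canopy_photosynthesis(prof_obs),
            "pooled_gs_pred": canopy_traits.pooled_gs(prof_pred),
            "pooled_gs_obs": canopy_traits.pooled_gs(prof_obs),
        })
    return pd.DataFrame(rows) if rows else None


def _canopy_blues(canopy: pd.DataFrame):
    """Genotype BLUEs of canopy values per stage, plus pred-vs-obs metrics."""
    value_cols = ["canopy_asat_pred", "canopy_asat_obs",
                  "pooled_gs_pred", "pooled_gs_obs"]
    blues_rows, eval_rows = [], []
    for stage, grp in canopy.groupby("stage", sort=True):
        per_stage = {}
        for col in value_cols:
            spec = rue_blues.BLUEModelSpec(response=col, env="year", rep="rep")
            table = rue_blues.fit_blues(grp, spec)
            per_stage[col] = table.set_index("genotype")["blue"]
            for _, r in table.iterrows():
                blues_rows.append({"stage": stage, "quantity": col,
                                   "genotype": r["genotype"],
                                   "blue": r["blue"], "se": r["se"]})
        for name in ("canopy_asat", "pooled_gs"):
            rep = model_eval.evaluate(per_stage[f"{name}_obs"].to_numpy(),
                                      per_stage[f"{name}_pred"].to_numpy())
            from scipy import stats
            lr = stats.linregress(per_stage[f"{name}_pred"],
                                  per_stage[f"{name}_obs"])
            eval_rows.append({"stage": stage, "quantity": name,
                              "r2": rep.r2, "p": float(lr.pvalue),
                              "rmse": rep.rmse, "n": rep.n})
    return pd.DataFrame(blues_rows), pd.DataFrame(eval_rows)


def _rue_table(biomass: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for interval, stages in RUE_INTERVALS.items():
        sub = biomass[biomass["stage"].isin(stages)]
        for geno, grp in sub.groupby("genotype", sort=True):
            pts = grp[["cum_ipar", "biomass"]].to_numpy()
            if pts.shape[0] < 2 or np.ptp(pts[:, 0]) == 0:
                continue
            est = rue_blues.rue_slope(pts, interval)
            rows.append({"genotype": geno, "interval": interval,
                         "slope": est.slope, "intercept": est.intercept,
                         "r2": est.r2, "n": est.n})
    return pd.DataFrame(rows)


def _rue_correlations(canopy_blues: pd.DataFrame, rue: pd.DataFrame):
    rows = []
    for quantity, label in (("canopy_asat_pred", "canopy_asat"),
                            ("pooled_gs_pred", "pooled_gs")):
        for stage in sorted(canopy_blues["stage"].unique()):
            pred = canopy_blues[(canopy_blues["stage"] == stage)
                                & (canopy_blues["quantity"] == quantity)]
            pred = pred[["genotype", "blue"]]
            for interval in RUE_INTERVALS:
                slopes = rue[rue["interval"] == interval][["genotype", "slope"]]
                if len(pred) < 3 or len(slopes) < 3:
                    continue
                rep = rue_blues.correlate_predictions_with_rue(pred, slopes)
                rows.append({"prediction": label, "stage": stage,
                             "interval": interval, **rep})
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full experiment described by ``config``.

    Any stage failure raises with the stage name; on success all result
    tables are returned (and written as CSV when ``out_dir`` is set).
    """
    stage = "load"
    try:
        spectra, traits, weather, biomass = _load(config)
        log.info("loaded %d spectra, %d trait records", spectra.n_samples,
                 len(traits.data))

        stage = "fit"
        rows, models, splits = [], {}, {}
        for ti, trait in enumerate(config.traits):
            for si, strat in enumerate(_strategies(config)):
                seed = config.split_seed + 131 * ti + 17 * si
                row, model, split = _fit_one(
                    spectra, traits, trait, strat, config, seed)
                rows.append(row)
                models[(trait, strat)] = model
                splits[(trait, strat)] = split
                log.info("fit %s/%s: A=%d R2v=%.3f", trait, strat,
                         row["n_comp"], row["r2_validation"])
        summary = pd.DataFrame(rows)

        stage = "vip"
        combined = {t: m for (t, s), m in models.items() if s == "Combined"}
        vip_frames = {}
        vip_regions = {}
        for trait, model in combined.items():
            profile = model_eval.vip_scores(model)
            vip_frames[trait] = profile.vip
            vip_regions[trait] = model_eval.important_regions(
                profile, config.vip_threshold)
        if vip_frames:
            any_model = next(iter(combined.values()))
            vip_profiles = pd.DataFrame(
                {"wavelength": np.asarray(any_model.wavelengths), **vip_frames})
        else:
            vip_profiles = pd.DataFrame()

        stage = "canopy"
        canopy = _canopy_tables(spectra, traits, combined, config)
        canopy_blues = canopy_eval = None
        if canopy is not None and len(canopy):
            canopy_blues, canopy_eval = _canopy_blues(canopy)

        stage = "rue"
        rue = corr = None
        if biomass is not None and len(biomass):
            rue = _rue_table(biomass)
            if canopy_blues is not None and len(rue):
                corr = _rue_correlations(canopy_blues, rue)

        stage = "write"
        report = ExperimentReport(
            summary=summary, vip_profiles=vip_profiles,
            vip_regions=vip_regions, canopy=canopy,
            canopy_blues=canopy_blues, canopy_eval=canopy_eval,
            rue=rue, rue_correlations=corr, models=models, splits=splits)
        if config.out_dir:
            _write_report(report, Path(config.out_dir))
        return report
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc


def _write_report(report: ExperimentReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.summary.to_csv(out / "summary.csv", index=False, float_format=fmt)
    report.vip_profiles.to_csv(out / "vip_profiles.csv", index=False,
                               float_format=fmt)
    for name, table in (("canopy_predictions", report.canopy),
                        ("canopy_blues", report.canopy_blues),
                        ("canopy_eval", report.canopy_eval),
                        ("rue", report.rue),
                        ("rue_correlations", report.rue_correlations)):
        if table is not None:
            table.to_csv(out / f"{name}.csv", index=False, float_format=fmt)
    splits_dir = out / "splits"
    splits_dir.mkdir(exist_ok=True)
    for (trait, strat), split in report.splits.items():
        split.to_csv(splits_dir / f"{trait}_{strat}.csv")
    try:
        comparison = compare_layer_strategies(report)
        comparison.to_csv(out / "strategy_comparison.csv", index=False,
                          float_format=fmt)
    except ValueError:
        pass


def compare_layer_strategies(report: ExperimentReport | pd.DataFrame
                             ) -> pd.DataFrame:
    """Side-by-side combined vs best single-layer validation metrics.

    The winner per trait is the strategy with the higher validation R²;
    exact ties are reported as ``tie``.
    """
    summary = report.summary if isinstance(report, ExperimentReport) else report
    has_combined = (summary["layer"] == "Combined").any()
    has_layers = summary["layer"].isin(list(_LAYER_LABEL.values())).any()
    if not (has_combined and has_layers):
        raise ValueError("comparison needs both per-layer and combined rows")

    rows = []
    for trait, grp in summary.groupby("trait", sort=False):
        comb = grp[grp["layer"] == "Combined"]
        layers = grp[grp["layer"] != "Combined"]
        if comb.empty or layers.empty:
            raise ValueError(f"trait {trait!r} missing a strategy")
        comb = comb.iloc[0]
        best = layers.loc[layers["r2_validation"].idxmax()]
        if comb["r2_validation"] > best["r2_validation"]:
            winner = "Combined"
        elif comb["r2_validation"] < best["r2_validation"]:
            winner = str(best["layer"])
        else:
            winner = "tie"
        rows.append({
            "trait": trait,
            "combined_r2_v": comb["r2_validation"],
            "combined_rmse_v": comb["rmse_v"],
            "combined_bias_v": comb["bias_v"],
            "best_layer": best["layer"],
            "best_layer_r2_v": best["r2_validation"],
            "best_layer_rmse_v": best["rmse_v"],
            "best_layer_bias_v": best["bias_v"],
            "winner": winner,
        })
    return pd.DataFrame(rows)
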