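"""Radiation use efficiency and genotype adjusted means (BLUEs).

RUE is the slope of the ordinary least-squares regression of accumulated
aboveground dry biomass (g m-2) on accumulated intercepted PAR (MJ m-2)
over a growth interval.  Intercepted PAR is built from daily total
irradiance scaled by 0.45 (the PAR fraction of global radiation) and by the
fraction of absorbed PAR, linearly interpolated in time between ceptometer
readings and held constant beyond the last reading.

Genotype BLUEs come from a linear mixed model with genotype and an optional
phenology covariate (days to the measurement stage) fixed, and environment
(= trial year), replicate nested in environment, and environment × genotype
random, fit by REML.  Adjusted means are reported at the covariate mean.
Single-environment data degrades to fixed genotype + covariate with
replicate random.  Model fitting delegates to statsmodels' mixed-model
machinery; this module owns the model specification, the BLUE extraction
and the degenerate-case behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAR_FRACTION", "WeatherSeries", "RUEEstimate", "BLUEModelSpec",
    "accumulate_ipar", "rue_slope", "fit_blues",
    "correlate_predictions_with_rue",
]

#: fraction of daily global irradiance that is photosynthetically active
PAR_FRACTION = 0.45


@dataclass
class WeatherSeries:
    """Daily total irradiance (MJ m-2 d-1) on strictly increasing dates."""

    data: pd.DataFrame  # columns: date, irradiance

    def __post_init__(self):
        needed = {"date", "irradiance"}
        if not needed.issubset(self.data.columns):
            raise ValueError(f"weather needs columns {sorted(needed)}")
        self.data = self.data.assign(date=pd.to_datetime(self.data["date"]))
        if not self.data["date"].is_monotonic_increasing or \
                self.data["date"].duplicated().any():
            raise ValueError("weather dates must be strictly increasing")
        if (self.data["irradiance"] < 0).any():
            raise ValueError("irradiance must be non-negative")


@dataclass(frozen=True)
class RUEEstimate:
    """Slope-based RUE for one growth interval."""

    slope: float          # g MJ-1
    intercept: float      # g m-2
    r2: float
    interval: str
    n: int


@dataclass
class BLUEModelSpec:
    """Specification of the multi-environment adjusted-means model."""

    response: str
    genotype: str = "genotype"
    env: str = "env"
    rep: str = "rep"
    covariate: str | None = None
    include_covariate: bool = True


def accumulate_ipar(weather: WeatherSeries, fapar_readings, window) -> float:
    """Accumulated intercepted PAR (MJ m-2) over ``window``.

    ``fapar_readings`` is a sequence of ``(date, fraction)`` pairs (or a
    DataFrame with ``date`` and ``fapar`` columns); fractions are linearly
    interpolated between readings and held constant beyond the last one.
    ``window`` is an inclusive (start, end) date pair within the weather
    record.
    """
    if isinstance(fapar_readings, pd.DataFrame):
        readings = list(zip(pd.to_datetime(fapar_readings["date"]),
                            fapar_readings["fapar"]))
    else:
        readings = [(pd.Timestamp(d), float(f)) for d, f in fapar_readings]
    if not readings:
        raise ValueError("no fAPAR readings supplied")
    readings.sort(key=lambda r: r[0])
    fr = np.array([f for _, f in readings], dtype=float)
    if fr.min() < 0 or fr.max() > 1:
        raise ValueError("fAPAR fractions must lie in [0, 1]")

    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if start > end:
        raise ValueError("window start after end")
    w = weather.data
    if start < w["date"].iloc[0] or end > w["date"].iloc[-1]:
        raise ValueError("window outside the weather record")
    if readings[0][0] > end:
        raise ValueError("no fAPAR reading before or within the window")

    days = w[(w["date"] >= start) & (w["date"] <= end)]
    t0 = readings[0][0]
    rt = np.array([(d - t0).days for d, _ in readings], dtype=float)
    td = np.array([(d - t0).days for d in days["date"]], dtype=float)
    fapar = np.interp(td, rt, fr)
    return float(np.sum(days["irradiance"].to_numpy() * PAR_FRACTION * fapar))


def rue_slope(points, interval: str = "Total") -> RUEEstimate:
    """OLS slope of biomass (g m-2) on accumulated intercepted PAR (MJ m-2)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (cum_ipar, biomass) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all cum_ipar values equal")
    if pts.shape[0] == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return RUEEstimate(float(slope), float(y[0] - slope * x[0]),
                           1.0, interval, 2)
    res = stats.linregress(x, y)
    return RUEEstimate(float(res.slope), float(res.intercept),
                       float(res.rvalue ** 2), interval, pts.shape[0])


def _ols_blues(data: pd.DataFrame, spec: BLUEModelSpec,
               formula_rhs: str) -> pd.DataFrame:
    import statsmodels.formula.api as smf

    fit = smf.ols(f"_y ~ {formula_rhs}", data=data).fit()
    return _extract_genotype_params(fit.params, fit.bse, spec, data)


def _extract_genotype_params(params, bse, spec, data) -> pd.DataFrame:
    rows = []
    for g in sorted(data[spec.genotype].unique()):
        key = f"C({spec.genotype})[{g}]"
        if key not in params.index:
            key = f"C({spec.genotype})[T.{g}]"
        rows.append({"genotype": g, "blue": float(params[key]),
                     "se": float(bse[key])})
    return pd.DataFrame(rows)


def fit_blues(data: pd.DataFrame, spec: BLUEModelSpec) -> pd.DataFrame:
    """Per-genotype adjusted means (BLUEs) under the multi-environment model.

    Returns a DataFrame with columns ``genotype``, ``blue``, ``se``.  The
    fixed part is parameterized without an intercept (one coefficient per
    genotype) with the covariate centered, so each genotype coefficient *is*
    its adjusted mean at the covariate mean.  Falls back to ordinary least
    squares if the REML fit fails to converge.
    """
    import statsmodels.formula.api as smf

    for col in (spec.response, spec.genotype, spec.env, spec.rep):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if data[spec.genotype].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    df = data.copy()
    df["_y"] = df[spec.response].astype(float)
    df = df.dropna(subset=["_y"])

    lost = set(data[spec.genotype].unique()) - set(df[spec.genotype].unique())
    if lost:
        raise ValueError(
            f"genotypes with no usable observations in any environment: "
            f"{sorted(map(str, lost))}"
        )

    rhs = f"0 + C({spec.genotype})"
    use_cov = (spec.include_covariate and spec.covariate is not None
               and spec.covariate in df.columns
               and df[spec.covariate].nunique() > 1)
    if use_cov:
        df["_cov"] = df[spec.covariate] - df[spec.covariate].mean()
        rhs += " + _cov"

    n_env = df[spec.env].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if n_env >= 2:
                model = smf.mixedlm(
                    f"_y ~ {rhs}", df, groups=df[spec.env].astype(str),
                    re_formula="1",
                    vc_formula={
                        "rep": f"0 + C({spec.rep})",
                        "gxe": f"0 + C({spec.genotype})",
                    },
                )
            else:
                model = smf.mixedlm(
                    f"_y ~ {rhs}", df, groups=df[spec.rep].astype(str),
                    re_formula="1",
                )
            fit = model.fit(reml=True)
            if not np.all(np.isfinite(fit.params)) or not fit.converged:
                raise np.linalg.LinAlgError("degenerate mixed-model fit")
            # a vanishing residual variance means the REML surface is flat
            # and the fixed effects can absorb an arbitrary shift; the OLS
            # projection is then the defensible answer
            if fit.scale <= 1e-10 * max(float(df["_y"].var()), 1.0):
                raise np.linalg.LinAlgError("zero residual variance")
            return _extract_genotype_params(fit.fe_params, fit.bse_fe, spec, df)
        except (np.linalg.LinAlgError, ValueError):
            return _ols_blues(df, spec, rhs)


def correlate_predictions_with_rue(
    blue_pred: pd.DataFrame, blue_rue: pd.DataFrame,
    value_pred: str = "blue", value_rue: str = "slope",
) -> dict:
    """Squared Pearson correlation between predicted-trait BLUEs and RUE.

    Both inputs are genotype-keyed tables; the report carries R², the
    two-sided p-value (t-distribution on n−2 df), the regression slope of
    RUE on the prediction, and n.
    """
    merged = blue_pred.merge(blue_rue, on="genotype",
                             suffixes=("_pred", "_rue"))
    cols = {c for c in merged.columns}
    xcol = value_pred if value_pred in cols else f"{value_pred}_pred"
    ycol = value_rue if value_rue in cols else f"{value_rue}_rue"
    x = merged[xcol].to_numpy(dtype=float)
    y = merged[ycol].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 overlapping genotypes")
    res = stats.linregress(x, y)
    return {
        "r2": float(res.rvalue ** 2),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "n": int(x.size),
    }
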