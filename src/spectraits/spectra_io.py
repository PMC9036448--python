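"""Reading, writing, validation and resampling of leaf spectra and trait tables.

The native on-disk format is delimited text (CSV).  Spectra are accepted in
two dialects:

``wide``
    first column ``wavelength`` (nm), one additional column per sample.
``long``
    one row per observation with columns ``sample_id, wavelength, reflectance``.

Trait observations travel as a long CSV with columns
``sample_id, trait, value, units``; sample metadata as a CSV keyed by
``sample_id``.

Reflectance slightly above 1 occurs in field data from calibration drift, so
values in (1, 1.2] are accepted with a warning; anything above 1.2 or below 0
is rejected.  No detector-splice ("jump") correction is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LAYERS",
    "STAGES",
    "TRAIT_NAMES",
    "TRAIT_UNITS",
    "SpectraSet",
    "TraitTable",
    "read_spectra",
    "write_spectra",
    "read_traits",
    "write_traits",
    "read_sample_meta",
    "write_sample_meta",
    "resample_to_grid",
    "join_spectra_traits",
]

#: Canopy layers, ordered top of the canopy (flag leaf) downwards.
LAYERS = ("top", "middle", "bottom")

#: Growth stages: initiation of booting and 7 days after anthesis.
STAGES = ("InB", "A7")

#: Closed vocabulary of trait names used throughout the pipeline.
TRAIT_NAMES = (
    "Asat", "gs", "FvpFmp", "PhiPSII", "SPAD", "C", "N", "SLA", "LMA", "LAI",
)

TRAIT_UNITS = {
    "Asat": "umol m-2 s-1",
    "gs": "mol m-2 s-1",
    "FvpFmp": "dimensionless",
    "PhiPSII": "dimensionless",
    "SPAD": "SPAD units",
    "C": "% dry mass",
    "N": "% dry mass",
    "SLA": "m2 kg-1",
    "LMA": "kg m-2",
    "LAI": "m2 m-2",
}

_META_COLUMNS = ("sample_id", "genotype", "plot", "replicate", "year", "stage", "layer")

_REFLECTANCE_HARD_MAX = 1.2


@dataclass
class SpectraSet:
    """A wavelength grid plus aligned per-sample reflectance vectors.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, shape ``(p,)``.
    reflectance
        Array of shape ``(n_samples, p)``; finite, within ``[0, 1.2]``.
    meta
        Per-sample metadata indexed like ``reflectance`` rows; must contain a
        ``sample_id`` column with unique values.  ``stage`` and ``layer``
        columns, when present, are validated against the closed vocabularies.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelength grid must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.reflectance.ndim != 2 or self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"grid length {self.wavelengths.size}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.reflectance.size:
            lo, hi = self.reflectance.min(), self.reflectance.max()
            if lo < 0 or hi > _REFLECTANCE_HARD_MAX:
                raise ValueError(
                    f"reflectance outside [0, {_REFLECTANCE_HARD_MAX}] "
                    f"(range {lo:.4g}..{hi:.4g})"
                )
            if hi > 1.0:
                warnings.warn(
                    f"reflectance above 1 (max {hi:.4g}); accepted but suspicious",
                    stacklevel=2,
                )
        if "sample_id" not in self.meta.columns:
            raise ValueError("meta must contain a sample_id column")
        if len(self.meta) != self.reflectance.shape[0]:
            raise ValueError("meta row count does not match reflectance rows")
        ids = self.meta["sample_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id values: {dups}")
        for col, vocab in (("stage", STAGES), ("layer", LAYERS)):
            if col in self.meta.columns:
                bad = set(self.meta[col].dropna()) - set(vocab)
                if bad:
                    raise ValueError(f"unknown {col} labels: {sorted(bad)}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def sample_ids(self) -> pd.Series:
        return self.meta["sample_id"]

    def select(self, mask: np.ndarray) -> "SpectraSet":
        """Return the subset of samples where ``mask`` is true."""
        mask = np.asarray(mask)
        return SpectraSet(
            self.wavelengths.copy(),
            self.reflectance[mask],
            self.meta.loc[mask].reset_index(drop=True),
        )


@dataclass
class TraitTable:
    """Long-format trait observations: one record per (sample_id, trait)."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "trait", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        self.data = self.data.assign(sample_id=self.data["sample_id"].astype(str))
        if "units" not in self.data.columns:
            self.data = self.data.assign(
                units=self.data["trait"].map(TRAIT_UNITS).fillna("")
            )
        bad = set(self.data["trait"]) - set(TRAIT_NAMES)
        if bad:
            raise ValueError(f"unknown trait names: {sorted(bad)}")
        dup = self.data.duplicated(subset=["sample_id", "trait"])
        if dup.any():
            pairs = self.data.loc[dup, ["sample_id", "trait"]].values.tolist()
            raise ValueError(f"duplicate (sample_id, trait) records: {pairs[:5]}")
        frac = self.data.loc[self.data["trait"].isin(["FvpFmp", "PhiPSII"]), "value"]
        if len(frac) and ((frac < 0) | (frac > 1)).any():
            raise ValueError("FvpFmp / PhiPSII values must lie in [0, 1]")
        self.data = self.data.reset_index(drop=True)

    def trait(self, name: str) -> pd.Series:
        """Values of one trait as a Series indexed by sample_id."""
        sub = self.data[self.data["trait"] == name]
        if sub.empty:
            raise KeyError(f"trait {name!r} not present")
        return sub.set_index("sample_id")["value"]

    @property
    def trait_names(self) -> list[str]:
        return sorted(self.data["trait"].unique())


def _to_numeric(series: pd.Series, what: str) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric {what} at data row {row + 1}: {series.iloc[row]!r}"
        )
    if converted.isna().any():
        row = int(np.flatnonzero(converted.isna().to_numpy())[0])
        raise ValueError(f"missing {what} at data row {row + 1}")
    return converted


def read_spectra(path: str | Path, dialect: str = "wide",
                 meta: pd.DataFrame | None = None) -> SpectraSet:
    """Read a spectra CSV in the ``wide`` or ``long`` dialect.

    Every sample must cover the full wavelength grid; duplicate
    (sample, wavelength) entries are rejected.  If ``meta`` is not given a
    minimal metadata frame holding only ``sample_id`` is attached.
    """
    path = Path(path)
    if dialect == "wide":
        raw = pd.read_csv(path, float_precision="round_trip")
        if raw.shape[1] < 2:
            raise ValueError("wide spectra file needs a wavelength column plus samples")
        wl = _to_numeric(raw.iloc[:, 0], "wavelength").to_numpy()
        order = np.argsort(wl)
        wl = wl[order]
        if np.any(np.diff(wl) == 0):
            raise ValueError("duplicate wavelengths in wide spectra file")
        sample_ids = [str(c) for c in raw.columns[1:]]
        refl = np.empty((len(sample_ids), wl.size))
        for j, col in enumerate(raw.columns[1:]):
            vals = _to_numeric(raw[col], f"reflectance for sample {col!r}")
            refl[j] = vals.to_numpy()[order]
    elif dialect == "long":
        raw = pd.read_csv(path, float_precision="round_trip")
        needed = {"sample_id", "wavelength", "reflectance"}
        if not needed.issubset(raw.columns):
            raise ValueError(f"long spectra file must have columns {sorted(needed)}")
        raw["wavelength"] = _to_numeric(raw["wavelength"], "wavelength")
        raw["reflectance"] = _to_numeric(raw["reflectance"], "reflectance")
        if raw.duplicated(subset=["sample_id", "wavelength"]).any():
            raise ValueError("duplicate (sample_id, wavelength) rows")
        wl = np.sort(raw["wavelength"].unique())
        sample_ids = sorted(raw["sample_id"].astype(str).unique())
        wide = raw.pivot(index="sample_id", columns="wavelength", values="reflectance")
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        if incomplete:
            raise ValueError(
                f"samples missing wavelengths: {incomplete} "
                f"(each sample must cover the full grid)"
            )
        wide.index = wide.index.astype(str)
        wide = wide.loc[sample_ids, wl]
        refl = wide.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if meta is None:
        meta = pd.DataFrame({"sample_id": sample_ids})
    else:
        meta = meta.set_index("sample_id").loc[sample_ids].reset_index()
    return SpectraSet(wl.astype(int) if np.allclose(wl, np.round(wl)) else wl,
                      refl, meta)


def write_spectra(spectra: SpectraSet, path: str | Path, dialect: str = "wide") -> None:
    """Write spectra to CSV at full float precision (round-trip exact)."""
    path = Path(path)
    ids = spectra.sample_ids.astype(str).tolist()
    if dialect == "wide":
        frame = pd.DataFrame(spectra.reflectance.T, columns=ids)
        frame.insert(0, "wavelength", spectra.wavelengths)
        frame.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "long":
        n, p = spectra.reflectance.shape
        frame = pd.DataFrame({
            "sample_id": np.repeat(ids, p),
            "wavelength": np.tile(spectra.wavelengths, n),
            "reflectance": spectra.reflectance.ravel(),
        })
        frame.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_traits(path: str | Path) -> TraitTable:
    raw = pd.read_csv(path, float_precision="round_trip")
    if "value" in raw.columns:
        raw["value"] = _to_numeric(raw["value"], "trait value")
    if "sample_id" in raw.columns:
        raw["sample_id"] = raw["sample_id"].astype(str)
    return TraitTable(raw)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, index=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata file must contain a sample_id column")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def resample_to_grid(spectra: SpectraSet, grid: Sequence[float]) -> SpectraSet:
    """Linear interpolation of every spectrum onto ``grid``.

    The target grid must lie within the source range; no extrapolation is
    performed.
    """
    grid = np.asarray(grid)
    src = np.asarray(spectra.wavelengths, dtype=float)
    if grid.min() < src.min() or grid.max() > src.max():
        raise ValueError(
            f"target grid {grid.min()}..{grid.max()} outside source range "
            f"{src.min():g}..{src.max():g}; extrapolation is not supported"
        )
    out = np.vstack([np.interp(grid, src, row) for row in spectra.reflectance])
    return SpectraSet(grid, out, spectra.meta.copy())


def join_spectra_traits(
    spectra: SpectraSet, traits: TraitTable, trait_name: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Align spectra with one trait into an (X, y, meta) design.

    Rows are the intersection of sample ids holding both a spectrum and a
    value for ``trait_name``, in stable (sorted) sample_id order — so the
    result does not depend on input file row order.
    """
    y_all = traits.trait(trait_name)
    spec_ids = spectra.sample_ids.astype(str)
    common = sorted(set(spec_ids) & set(map(str, y_all.index)))
    if not common:
        raise ValueError(
            f"no samples have both a spectrum and a {trait_name!r} value"
        )
    pos = pd.Series(np.arange(len(spec_ids)), index=spec_ids)
    rows = pos.loc[common].to_numpy()
    X = spectra.reflectance[rows]
    y = y_all.loc[common].to_numpy(dtype=float)
    meta = spectra.meta.iloc[rows].reset_index(drop=True)
    return X, y, meta
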