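"""Data conditioning before model fitting.

Two steps are applied before any PLSR model is built: trait outliers beyond
±k standard deviations of the trait mean are removed (k = 3 by default,
computed once on the full input, not iteratively), and the remaining samples
are split at random into training (70%) and validation (30%) subsets with
equal inclusion probability.

Outlier filtering is applied per trait *within each (layer, stage) stratum*
by default: layer and stage means differ strongly, so a global filter would
preferentially delete bottom-layer observations.  A global variant is
available through ``stratify=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SplitResult", "remove_outliers", "remove_outliers_stratified",
           "split_train_validation"]


@dataclass(frozen=True)
class SplitResult:
    """A disjoint, exhaustive train/validation partition of sample ids."""

    train_ids: tuple
    validation_ids: tuple
    fraction: float
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation sets overlap")

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_validation(self) -> int:
        return len(self.validation_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": list(self.train_ids) + list(self.validation_ids),
            "partition": ["train"] * self.n_train
                         + ["validation"] * self.n_validation,
        })

    def to_csv(self, path: str | Path) -> None:
        """Persist the partition so a fitted model's split is auditable."""
        self.to_frame().to_csv(path, index=False)


def remove_outliers(y: pd.Series, k: float = 3.0) -> tuple[pd.Series, list]:
    """Drop values farther than ``k`` sample standard deviations from the mean.

    The mean and sd (ddof=1) are computed once on the full input; the filter
    is a single pass, never re-applied to its own output.  Returns the kept
    values and the list of removed ids.
    """
    y = pd.Series(y, dtype=float)
    if len(y) < 2:
        raise ValueError("outlier filter needs at least 2 values")
    mean = y.mean()
    sd = y.std(ddof=1)
    if k == 0 and sd == 0:
        raise ValueError("k=0 with zero variance removes nothing meaningfully")
    keep = (y - mean).abs() <= k * sd
    removed = y.index[~keep].tolist()
    return y[keep], removed


def remove_outliers_stratified(
    y: pd.Series, strata: pd.DataFrame | None, k: float = 3.0,
) -> tuple[pd.Series, list]:
    """Outlier filter applied independently within each stratum.

    ``strata`` is a frame aligned with ``y`` (same index) whose columns
    define the grouping, typically layer and stage.  With ``strata=None``
    this is the global single-pass filter.
    """
    if strata is None:
        return remove_outliers(y, k)
    strata = strata.loc[y.index]
    kept_parts: list[pd.Series] = []
    removed: list = []
    for _, idx in y.groupby([strata[c] for c in strata.columns]).groups.items():
        part = y.loc[idx]
        if len(part) < 2:
            kept_parts.append(part)
            continue
        kept, rem = remove_outliers(part, k)
        kept_parts.append(kept)
        removed.extend(rem)
    out = pd.concat(kept_parts)
    return out.loc[[i for i in y.index if i in out.index]], removed


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_train_validation(
    ids, fraction: float = 0.7, seed: int = 0,
    strata: pd.Series | None = None,
) -> SplitResult:
    """Simple random split of ``ids`` into train/validation.

    Sampling is without replacement with equal inclusion probability; the
    train size is ``round(fraction * n)`` (half away from zero).  With
    ``strata`` given (a Series aligned with ids, e.g. canopy layer), the
    split is performed within each stratum and the parts concatenated.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")

    if strata is not None:
        strata = pd.Series(strata)
        train: list = []
        val: list = []
        for g, (_, members) in enumerate(
            pd.Series(ids).groupby(strata.loc[ids].to_numpy()).groups.items()
        ):
            sub = [ids[i] for i in members]
            part = split_train_validation(sub, fraction, seed + 1009 * (g + 1))
            train.extend(part.train_ids)
            val.extend(part.validation_ids)
        if not train or not val:
            raise ValueError("fraction yields an empty partition")
        return SplitResult(tuple(train), tuple(val), fraction, seed)

    n_train = _round_half_away(fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"fraction {fraction} yields an empty partition for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_ids = tuple(ids[i] for i in sorted(perm[:n_train]))
    val_ids = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SplitResult(train_ids, val_ids, fraction, seed)
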