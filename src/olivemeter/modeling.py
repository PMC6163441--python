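"""Linear calibration of physical fruit features from image measurements.

A calibration maps one image-derived feature to one physical magnitude by
ordinary least squares: axis length in pixels -> axis length in mm, or
projected area in pixels -> mass in g (every foreground pixel contributes
equally to mass, a deliberate linearization of the 3-D problem).  Models
are tagged by variety; a "variety-independent" model is simply one fitted
on the concatenated training sets.

Validation quality is summarized by three error measures over the n
validation fruits with predictions yhat_i and references y_i:

* ``rmse``     = sqrt(mean((yhat - y)^2)), in physical units;
* ``se_pct``   = 100 * rmse / mean(y)  (relative RMSE, %);
* ``abs_e_pct``= 100 * |sum(yhat - y)| / sum(y)  (relative mean error, %).

Note that ``abs_e_pct`` takes the absolute value AFTER summing the signed
errors, so over- and under-estimation cancel; it measures aggregate bias,
not average accuracy.  The per-fruit relative errors e_i = yhat_i / y_i
are returned alongside for downstream population comparisons.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationModel",
    "ModelMetrics",
    "fit_linear",
    "predict",
    "compute_metrics",
    "train_eval_split",
]


@dataclass(frozen=True)
class CalibrationModel:
    """An affine map from an image measurement to a physical magnitude."""

    feature: str  # e.g. "major_axis", "minor_axis", "mass"
    slope: float
    intercept: float
    r_squared: float
    n_train: int
    variety_tag: str = "variety-independent"
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")
    through_origin: bool = False

    def __post_init__(self) -> None:
        if self.n_train < 3:
            raise ValueError(f"n_train must be >= 3, got {self.n_train}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def predict(self, x) -> np.ndarray:
        return predict(self, x)

    def slope_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1 - alpha) confidence interval for the slope."""
        from scipy import stats

        dof = self.n_train - (1 if self.through_origin else 2)
        half = stats.t.ppf(1.0 - alpha / 2.0, dof) * self.slope_stderr
        return self.slope - half, self.slope + half

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "feature": self.feature,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_train": self.n_train,
            "variety_tag": self.variety_tag,
            "slope_stderr": self.slope_stderr,
            "intercept_stderr": self.intercept_stderr,
            "through_origin": self.through_origin,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class ModelMetrics:
    """Validation errors of a calibration model (see module docstring)."""

    rmse: float
    se_pct: float
    abs_e_pct: float
    n: int
    relative_errors: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "se_pct": self.se_pct,
            "abs_e_pct": self.abs_e_pct,
            "n": self.n,
        }


def fit_linear(
    x,
    y,
    feature: str = "feature",
    variety_tag: str = "variety-independent",
    through_origin: bool = False,
) -> CalibrationModel:
    """Ordinary-least-squares calibration of physical y against image x."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"x and y differ in length: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 training fruits, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all image measurements are equal")
    design = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    if through_origin:
        slope, intercept = float(res.params[0]), 0.0
        slope_se, intercept_se = float(res.bse[0]), 0.0
    else:
        intercept, slope = float(res.params[0]), float(res.params[1])
        intercept_se, slope_se = float(res.bse[0]), float(res.bse[1])
    return CalibrationModel(
        feature=feature,
        slope=slope,
        intercept=intercept,
        r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
        n_train=int(x.size),
        variety_tag=variety_tag,
        slope_stderr=slope_se,
        intercept_stderr=intercept_se,
        through_origin=through_origin,
    )


def predict(model: CalibrationModel, x) -> np.ndarray:
    """Apply the calibration: yhat = slope * x + intercept, elementwise."""
    return model.slope * np.asarray(x, dtype=float) + model.intercept


def compute_metrics(y_hat, y) -> ModelMetrics:
    """RMSE, relative RMSE (%), relative mean error (%) and e_i = yhat/y."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.size} vs {y.size}")
    if y.size == 0:
        raise ValueError("need at least one observation")
    if np.any(y <= 0):
        raise ValueError("all reference values must be strictly positive")
    err = y_hat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    se_pct = float(rmse / np.mean(y) * 100.0)
    abs_e_pct = float(abs(err.sum()) / y.sum() * 100.0)
    return ModelMetrics(
        rmse=rmse,
        se_pct=se_pct,
        abs_e_pct=abs_e_pct,
        n=int(y.size),
        relative_errors=y_hat / y,
    )


def train_eval_split(
    table: pd.DataFrame,
    train_n: int,
    seed: int,
    stratify_by: str | None = None,
    n_strata: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded split into a training set of ``train_n`` fruits and a validation set.

    With ``stratify_by`` set to a column name, training fruits are drawn
    per quantile bin of that column (largest-remainder allocation), so the
    training set is representative of the feature's variability; bin
    training counts differ by at most 1 when bins are equally filled.
    """
    total = len(table)
    if not 0 < train_n < total:
        raise ValueError(f"train_n must be in (0, {total}), got {train_n}")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(total)
        idx_train = np.sort(perm[:train_n])
    else:
        values = table[stratify_by].to_numpy(float)
        ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable")
        bins = (ranks * n_strata) // total  # equal-frequency quantile bins
        sizes = np.bincount(bins, minlength=n_strata)
        quota = train_n * sizes / total
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        for b in np.argsort(-remainder, kind="stable")[: train_n - counts.sum()]:
            counts[b] += 1
        picks = []
        for b in range(n_strata):
            members = np.flatnonzero(bins == b)
            picks.append(rng.choice(members, size=min(counts[b], members.size), replace=False))
        idx_train = np.sort(np.concatenate(picks))
    mask = np.zeros(total, dtype=bool)
    mask[idx_train] = True
    return (
        table.iloc[np.flatnonzero(mask)].reset_index(drop=True),
        table.iloc[np.flatnonzero(~mask)].reset_index(drop=True),
    )
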