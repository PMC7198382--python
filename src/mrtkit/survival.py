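"""Clonogenic survival: surviving fractions, linear-quadratic fits, D90,
and dose-response comparison between irradiation modalities.

The LQ model is SF = exp(-alpha*D - beta*D^2); D90 is the dose at which
survival has dropped 10-fold, i.e. the positive root of
alpha*D + beta*D^2 = ln 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SurvivalDataset",
    "LQFit",
    "surviving_fraction",
    "fit_lq",
    "d90_from_lq",
    "compare_modalities",
]

LN10 = np.log(10.0)


@dataclass
class SurvivalDataset:
    """Colony counts per (dose, replicate) for one condition.

    ``data`` columns: dose_Gy, replicate, colonies, plated.  Plating
    efficiency is estimated from the 0-dose wells.
    """

    data: pd.DataFrame
    modality: str = "EBRT"  # EBRT | MRT
    condition: str = ""

    def __post_init__(self) -> None:
        req = {"dose_Gy", "colonies", "plated"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"data must have columns {sorted(req)}")
        if (self.data["colonies"] > self.data["plated"]).any():
            raise ValueError("colonies cannot exceed cells plated")
        if (self.data[["colonies", "plated", "dose_Gy"]] < 0).any().any():
            raise ValueError("negative counts or doses")

    @classmethod
    def from_csv(cls, path, **kw) -> "SurvivalDataset":
        return cls(pd.read_csv(path, comment="#"), **kw)

    @property
    def plating_efficiency(self) -> float:
        zero = self.data[self.data["dose_Gy"] == 0]
        if zero.empty:
            raise ValueError("no 0-dose wells: plating efficiency undefined")
        pe = zero["colonies"].sum() / zero["plated"].sum()
        if pe <= 0:
            raise ValueError("zero plating efficiency")
        return float(pe)


def surviving_fraction(ds: SurvivalDataset) -> pd.DataFrame:
    """Per-dose surviving fraction with a binomial standard error.

    SF = (colonies/plated) / PE, pooling replicates at each dose.
    """
    pe = ds.plating_efficiency
    rows = []
    for dose, grp in ds.data.groupby("dose_Gy"):
        n = int(grp["plated"].sum())
        k = int(grp["colonies"].sum())
        p = k / n
        se_p = np.sqrt(p * (1 - p) / n)
        rows.append({"dose_Gy": float(dose), "sf": p / pe, "se": se_p / pe,
                     "colonies": k, "plated": n})
    return pd.DataFrame(rows).sort_values("dose_Gy", ignore_index=True)


def d90_from_lq(alpha: float, beta: float) -> float:
    """Positive root of alpha*D + beta*D^2 = ln 10."""
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
    # quadratic root degrades numerically once beta*ln10 << alpha^2
    if beta == 0 or 4 * beta * LN10 < 1e-9 * alpha ** 2:
        return LN10 / alpha
    return (-alpha + np.sqrt(alpha ** 2 + 4 * beta * LN10)) / (2 * beta)


@dataclass
class LQFit:
    """Constrained weighted least-squares LQ fit on ln SF."""

    alpha: float
    beta: float
    covariance: np.ndarray
    d90: float
    n_points: int
    dof: int
    rss: float  # weighted residual sum of squares
    doses: np.ndarray = field(repr=False, default=None)

    def predict_sf(self, dose) -> np.ndarray:
        d = np.asarray(dose, float)
        return np.exp(-self.alpha * d - self.beta * d * d)

    def predict_log_sf_se(self, dose) -> np.ndarray:
        """SE of the predicted ln SF by linear error propagation."""
        d = np.asarray(dose, float)
        X = np.stack([d, d * d], axis=-1)
        var = np.einsum("...i,ij,...j->...", X, self.covariance, X)
        return np.sqrt(np.maximum(var, 0.0))


def fit_lq(sf_table: pd.DataFrame) -> LQFit:
    """Fit ln SF = -alpha*D - beta*D^2 by weighted least squares with
    alpha, beta >= 0.

    Weights are inverse variances of ln SF (var = (se/sf)^2, unit weight when
    no ``se`` column is given).  Non-positive SF rows are excluded with a
    warning.
    """
    df = sf_table.copy()
    bad = df["sf"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive SF entries")
        df = df[~bad]
    doses = df["dose_Gy"].to_numpy(float)
    if len(np.unique(doses)) < 3:
        raise ValueError("need >= 3 distinct doses to fit the LQ model")

    y = np.log(df["sf"].to_numpy(float))
    if "se" in df.columns and np.all(df["se"] > 0):
        w = (df["sf"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
    else:
        w = np.ones_like(y)
    X = np.column_stack([doses, doses ** 2])
    sw = np.sqrt(w)
    res = optimize.lsq_linear(-X * sw[:, None], y * sw, bounds=(0, np.inf),
                              tol=1e-14)
    alpha, beta = res.x
    resid = (y - (-X @ res.x)) * sw
    rss = float(resid @ resid)
    dof = max(len(y) - 2, 1)
    s2 = rss / dof
    xtx = (X * w[:, None]).T @ X
    try:
        cov = s2 * np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return LQFit(float(alpha), float(beta), cov, d90_from_lq(alpha, beta),
                 len(y), dof, rss, doses=doses)


def compare_modalities(fit_a: LQFit, fit_b: LQFit, dose_grid) -> dict:
    """Compare two fitted dose-response curves.

    Returns predicted SF differences with propagated 95% CIs across the grid
    and a curve-coincidence test: Wald chi-square on the parameter difference
    plus the equivalent F statistic on the stored degrees of freedom.
    """
    grid = np.asarray(dose_grid, float)
    if (fit_a.doses is not None and fit_b.doses is not None
            and (grid.max() > min(fit_a.doses.max(), fit_b.doses.max()))):
        warnings.warn("dose grid extends beyond the fitted dose ranges")

    diff_log = ((-fit_a.alpha * grid - fit_a.beta * grid ** 2)
                - (-fit_b.alpha * grid - fit_b.beta * grid ** 2))
    se = np.sqrt(fit_a.predict_log_sf_se(grid) ** 2
                 + fit_b.predict_log_sf_se(grid) ** 2)
    z = stats.norm.ppf(0.975)

    theta = np.array([fit_a.alpha - fit_b.alpha, fit_a.beta - fit_b.beta])
    cov = fit_a.covariance + fit_b.covariance
    try:
        chi2 = float(theta @ np.linalg.solve(cov, theta))
    except np.linalg.LinAlgError:
        chi2 = np.nan
    dof = fit_a.dof + fit_b.dof
    f_stat = chi2 / 2
    p = float(stats.f.sf(f_stat, 2, dof)) if np.isfinite(f_stat) else np.nan

    return {
        "dose_grid": grid,
        "log_sf_difference": diff_log,
        "ci_low": diff_log - z * se,
        "ci_high": diff_log + z * se,
        "chi2": chi2,
        "f_statistic": f_stat,
        "df": (2, dof),
        "p_value": p,
        "significant": bool(p < 0.05) if np.isfinite(p) else False,
    }
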