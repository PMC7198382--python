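"""Spatial dose-damage correlation on co-registered map pairs.

Covers integer-pixel translation registration, pixel-by-pixel density
scatter with OLS regression plus a Wald-Wolfowitz runs test for
non-linearity, and voxel-binned analysis with detection of the largest lower
activity sub-range over which the damage link stays linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import special, stats

__all__ = [
    "RegisteredMapPair",
    "DensityScatter",
    "coregister",
    "runs_test",
    "density_scatter",
    "voxel_bin_analysis",
]


@dataclass
class RegisteredMapPair:
    """Two co-registered maps (2-D or 3-D) with a shared region-of-interest mask."""

    map_a: np.ndarray
    map_b: np.ndarray
    mask: np.ndarray = None
    shift: tuple = (0, 0)
    attained_correlation: float = np.nan

    def __post_init__(self) -> None:
        self.map_a = np.asarray(self.map_a, float)
        self.map_b = np.asarray(self.map_b, float)
        if self.map_a.shape != self.map_b.shape:
            raise ValueError("maps must have identical shape after registration")
        if self.mask is None:
            self.mask = np.ones(self.map_a.shape, bool)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.map_a.shape:
            raise ValueError("mask must match map shape")


def coregister(map_a: np.ndarray, map_b: np.ndarray, max_shift: int = 10,
               mask: np.ndarray | None = None) -> RegisteredMapPair:
    """Register ``map_b`` onto ``map_a`` by the integer translation (within
    ``max_shift`` per axis) maximizing the masked Pearson correlation.

    ``map_b`` is shifted (edge values rolled out are excluded via the overlap
    mask).  Raises if either image is flat.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValueError("maps must share a common grid")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("no registration signal: flat image")
    base = np.ones(a.shape, bool) if mask is None else np.asarray(mask, bool)

    best = (0,) * a.ndim
    best_r = -np.inf
    offsets = np.arange(-max_shift, max_shift + 1)
    grids = np.meshgrid(*([offsets] * a.ndim), indexing="ij")
    for off in zip(*(g.ravel() for g in grids)):
        shifted = np.roll(b, off, axis=tuple(range(a.ndim)))
        valid = np.ones(a.shape, bool)
        for ax, o in enumerate(off):
            sl = [slice(None)] * a.ndim
            if o > 0:
                sl[ax] = slice(0, o)
            elif o < 0:
                sl[ax] = slice(a.shape[ax] + o, None)
            else:
                continue
            valid[tuple(sl)] = False
        m = base & valid
        if m.sum() < 10:
            continue
        x, y = a[m], shifted[m]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if r > best_r:
            best_r, best = r, off
    if best_r < 0.2:
        warnings.warn(f"low attained registration correlation ({best_r:.2f})")
    registered = np.roll(b, best, axis=tuple(range(a.ndim)))
    return RegisteredMapPair(a, registered, base, tuple(int(o) for o in best),
                             float(best_r))


# ------------------------------------------------------------- runs test

def _runs_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the number of runs for n1 plus- and n2 minus-signs."""
    n = n1 + n2
    pmf = np.zeros(n + 1)
    denom = special.comb(n, n1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            val = 2 * special.comb(n1 - 1, k - 1) * special.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            val = (special.comb(n1 - 1, k) * special.comb(n2 - 1, k - 1)
                   + special.comb(n1 - 1, k - 1) * special.comb(n2 - 1, k))
        pmf[r] = val / denom
    return pmf


def runs_test(signs: np.ndarray, exact_max_n: int = 20) -> tuple[int, float]:
    """Wald-Wolfowitz runs test for too few runs (one-sided).

    ``signs`` is a boolean/sign sequence ordered by the covariate.  Exact
    null distribution for n <= ``exact_max_n``, normal approximation with
    continuity correction otherwise.  Returns (n_runs, p_value).
    """
    s = np.asarray(signs)
    s = s[s != 0] if s.dtype.kind in "if" else s
    x = s > 0
    n1 = int(x.sum())
    n2 = int(len(x) - n1)
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return (1 if n else 0), 1.0
    r = int(1 + np.count_nonzero(np.diff(x.astype(int))))
    if n <= exact_max_n:
        pmf = _runs_pmf(n1, n2)
        p = float(pmf[: r + 1].sum())
    else:
        mu = 1 + 2 * n1 * n2 / n
        var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n ** 2 * (n - 1))
        p = float(stats.norm.cdf((r + 0.5 - mu) / np.sqrt(var)))
    return r, min(p, 1.0)


# -------------------------------------------------------- density scatter

@dataclass
class DensityScatter:
    """Pixel-wise 2-D histogram with regression and linearity diagnostics."""

    hist: np.ndarray
    a_edges: np.ndarray
    b_edges: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    n_pixels: int
    runs: int
    runs_p: float
    pearson_r: float = np.nan


def _ols_with_runs(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int, float]:
    res = stats.linregress(a, b)
    order = np.argsort(a, kind="stable")
    resid = (b - (res.intercept + res.slope * a))[order]
    r_runs, p_runs = runs_test(np.sign(resid))
    return res.slope, res.intercept, res.rvalue ** 2, r_runs, p_runs


def density_scatter(pair: RegisteredMapPair, edge_erosion_px: int = 3,
                    bins: int = 64) -> DensityScatter:
    """Pixel-by-pixel comparison of the two maps inside the eroded mask.

    Erodes the mask to omit edge effects, builds the 2-D histogram, runs OLS
    of b on a, and a runs test on residual signs ordered by a to flag
    non-linearity.
    """
    mask = pair.mask
    if edge_erosion_px > 0:
        mask = ndi.binary_erosion(mask, iterations=edge_erosion_px)
    if mask.sum() < 10:
        raise ValueError("fewer than 10 masked pixels after erosion")
    a = pair.map_a[mask]
    b = pair.map_b[mask]
    hist, a_edges, b_edges = np.histogram2d(a, b, bins=bins)
    slope, intercept, r2, r_runs, p_runs = _ols_with_runs(a, b)
    r = np.corrcoef(a, b)[0, 1] if np.ptp(a) > 0 and np.ptp(b) > 0 else np.nan
    return DensityScatter(hist, a_edges, b_edges, float(slope), float(intercept),
                          float(r2), int(mask.sum()), r_runs, float(p_runs),
                          float(r))


# ------------------------------------------------------- voxel binning

def voxel_bin_analysis(pair: RegisteredMapPair, n_bins: int = 10,
                       alpha: float = 0.05) -> dict:
    """Equal-width binning of map_a with per-bin map_b statistics and a
    linear-range search.

    Bins are half-open [lo, hi) with the top bin right-closed; empty bins are
    merged with their left neighbour (logged via warning).  The linear range
    is the largest lower prefix of bins whose pooled voxels pass the runs
    test (p >= alpha) for the OLS fit of b on a; reports its upper bound,
    slope and R^2.
    """
    if n_bins < 3:
        raise ValueError("need >= 3 bins")
    a = pair.map_a[pair.mask]
    b = pair.map_b[pair.mask]
    edges = np.linspace(a.min(), a.max(), n_bins + 1)
    idx = np.clip(np.digitize(a, edges[1:-1]), 0, n_bins - 1)

    rows = []
    for i in range(n_bins):
        sel = idx == i
        if not sel.any():
            warnings.warn(f"empty bin {i}: merged with neighbour")
            continue
        rows.append({"bin": i, "a_low": edges[i], "a_high": edges[i + 1],
                     "n": int(sel.sum()), "b_mean": float(b[sel].mean()),
                     "b_sd": float(b[sel].std(ddof=1)) if sel.sum() > 1 else np.nan})
    table = pd.DataFrame(rows)

    best = None
    for k in range(n_bins - 1, 1, -1):
        sel = idx <= k
        if sel.sum() < 10:
            continue
        aa, bb = a[sel], b[sel]
        if np.ptp(aa) == 0:
            continue
        slope, intercept, r2, r_runs, p_runs = _ols_with_runs(aa, bb)
        if p_runs >= alpha:
            best = {"linear_up_to": float(edges[k + 1]), "last_bin": int(k),
                    "slope": slope, "intercept": intercept, "r_squared": r2,
                    "runs_p": p_runs, "n_voxels": int(sel.sum())}
            break
    if best is None:
        best = {"linear_up_to": np.nan, "last_bin": -1, "slope": np.nan,
                "intercept": np.nan, "r_squared": np.nan, "runs_p": np.nan,
                "n_voxels": 0}
    return {"bins": table, "linear_range": best, "edges": edges}
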