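"""Tumor-scale dosimetry: time-activity-curve fitting, cumulated activity,
and a Monte-Carlo sphere model for the absorbed dose.

The washout phase (samples at and after the peak) is fitted with a
mono-exponential A(t) = A0 * exp(-lambda_eff * t); the biological half-life
follows from 1/T_eff = 1/T_phys + 1/T_bio.  The sphere dose uses the same
straight-line CSDA electron transport as the cellular model, applied to a
uniform sphere, with an optional crude mean-chord photon term (off by
default: electrons dominate at mouse-tumor scale).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .celldose import MEV_TO_J, _deposit_in_sphere
from .nuclides import NuclideData, sample_electron_emission, _read_table

__all__ = [
    "TimeActivityCurve",
    "TacFit",
    "SphereDoseResult",
    "fit_monoexp",
    "cumulated_activity",
    "sphere_absorbed_dose",
]


@dataclass
class TimeActivityCurve:
    """Activity in a volume of interest over time."""

    times_h: np.ndarray
    activity_MBq: np.ndarray
    injected_MBq: float = np.nan
    volume_mL: float = np.nan
    density_g_mL: float = 1.03

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.activity_MBq = np.asarray(self.activity_MBq, float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activity_MBq < 0):
            raise ValueError("activity must be non-negative")
        if not np.isnan(self.volume_mL) and self.volume_mL <= 0:
            raise ValueError("volume must be positive")

    @classmethod
    def from_csv(cls, path, **kw) -> "TimeActivityCurve":
        df = pd.read_csv(path, comment="#")
        extra = {}
        if "volume_mL" in df.columns:
            extra["volume_mL"] = float(df["volume_mL"].iloc[0])
        if "injected_MBq" in df.columns:
            extra["injected_MBq"] = float(df["injected_MBq"].iloc[0])
        extra.update(kw)
        if "activity_MBq" in df.columns:
            act = df["activity_MBq"].to_numpy()
        elif "percent_id_per_mL" in df.columns:
            # %ID/mL * injected / 100 * volume, no decay correction
            act = (df["percent_id_per_mL"].to_numpy() / 100.0
                   * extra["injected_MBq"] * extra["volume_mL"])
        else:
            raise ValueError("need an activity_MBq or percent_id_per_mL column")
        return cls(times_h=df["time_h"].to_numpy(), activity_MBq=act, **extra)

    def percent_id_per_mL(self) -> np.ndarray:
        """%ID/mL, using the injected activity without decay correction."""
        return self.activity_MBq / self.injected_MBq * 100.0 / self.volume_mL


@dataclass
class TacFit:
    """Mono-exponential washout fit."""

    A0_MBq: float        # extrapolated activity at t = 0
    lambda_eff_per_h: float
    t_eff_h: float
    t_phys_h: float
    t_bio_h: float
    t_peak_h: float
    n_washout: int
    residual_rms: float
    #: regression diagnostics in log space, for cohort-level pooling
    log_rss: float = 0.0
    dof: int = 0
    s_tt_h2: float = np.nan  # sum of squared centred washout times

    def activity(self, t_h) -> np.ndarray:
        return self.A0_MBq * np.exp(-self.lambda_eff_per_h * np.asarray(t_h, float))


def fit_monoexp(tac: TimeActivityCurve, t_phys_h: float = 159.53) -> TacFit:
    """Least-squares mono-exponential fit of the washout phase.

    The peak is auto-detected as the maximum sample; samples at and after it
    form the washout.  The fit is linear regression on log activity, the
    maximum-likelihood estimate under multiplicative (lognormal) measurement
    noise typical of VOI activity data.  T_bio follows from
    1/T_eff = 1/T_phys + 1/T_bio.
    """
    i0 = int(np.argmax(tac.activity_MBq))
    t = tac.times_h[i0:]
    a = tac.activity_MBq[i0:]
    if len(t) < 3:
        raise ValueError("need >= 3 samples at/after the peak to fit washout")
    if np.any(np.diff(a) > 0):
        warnings.warn("non-monotone washout; fit proceeds")
    pos = a > 0
    if pos.sum() < 3:
        raise ValueError("need >= 3 positive washout samples")
    tt, y = t[pos], np.log(a[pos])

    X = np.column_stack([tt, np.ones_like(tt)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    lam = float(-coef[0])
    if lam <= 0:
        warnings.warn("non-decaying washout; clamping to a tiny decay constant")
        lam = 1e-9
    A0 = float(np.exp(coef[1]))
    resid = y - X @ coef
    dof = len(tt) - 2
    s_tt = float(((tt - tt.mean()) ** 2).sum())

    t_eff = np.log(2.0) / lam
    inv_bio = 1.0 / t_eff - 1.0 / t_phys_h
    t_bio = 1.0 / inv_bio if inv_bio > 1e-12 else np.inf
    rms = float(np.sqrt(np.mean((a - A0 * np.exp(-lam * t)) ** 2)))
    return TacFit(A0, lam, float(t_eff), t_phys_h, float(t_bio), float(t[0]),
                  len(t), rms, log_rss=float(resid @ resid), dof=dof,
                  s_tt_h2=s_tt)


def mean_effective_half_life(fits) -> float:
    """Cohort mean effective half-life with ratio-bias correction.

    T_eff = ln2 / lambda is convex in lambda, so averaging per-animal
    half-lives over a noisy cohort is biased high by ~CV(lambda)^2.  The
    residual variance is pooled across the cohort (stable even with few
    washout samples per animal) and each half-life divided by
    1 + Var(lambda_i)/lambda_i^2 before averaging.
    """
    fits = list(fits)
    total_dof = sum(f.dof for f in fits)
    s2 = (sum(f.log_rss for f in fits) / total_dof) if total_dof > 0 else 0.0
    # cohort-mean lambda in the CV, so the correction factor is not itself
    # correlated with the per-animal estimate
    lam_bar = float(np.mean([f.lambda_eff_per_h for f in fits]))
    vals = []
    for f in fits:
        var_lam = s2 / f.s_tt_h2 if np.isfinite(f.s_tt_h2) and f.s_tt_h2 > 0 else 0.0
        cv2 = var_lam / lam_bar ** 2 if lam_bar > 0 else 0.0
        vals.append(f.t_eff_h / (1.0 + cv2))
    return float(np.mean(vals))


def cumulated_activity(tac: TimeActivityCurve, fit: TacFit,
                       t_end_h: float = np.inf) -> float:
    """Cumulated activity (MBq.h): trapezoid over the samples plus an analytic
    mono-exponential tail from the last sample to ``t_end_h``."""
    t, a = tac.times_h, tac.activity_MBq
    if t_end_h < t[-1]:
        grid = np.unique(np.concatenate([t[t <= t_end_h], [t_end_h]]))
        return float(np.trapezoid(np.interp(grid, t, a), grid))
    base = float(np.trapezoid(a, t))
    lam = fit.lambda_eff_per_h
    a_last = fit.activity(t[-1])
    if np.isinf(t_end_h):
        tail = a_last / lam
    else:
        tail = a_last / lam * (1.0 - np.exp(-lam * (t_end_h - t[-1])))
    return base + float(tail)


@functools.lru_cache(maxsize=1)
def _muen_table():
    df = _read_table("water_mu_en.csv")
    return df["energy_keV"].to_numpy(float), df["mu_en_rho_cm2_g"].to_numpy(float)


@dataclass
class SphereDoseResult:
    dose_Gy: float
    phi_e: float
    phi_e_stderr: float
    phi_gamma: float
    electron_dose_Gy: float
    photon_dose_Gy: float
    radius_mm: float
    dose_rate_Gy_per_h: pd.DataFrame | None = None


def sphere_absorbed_dose(
    cumulated_conc_MBq_h_per_mL: float,
    volume_mL: float,
    nuclide: NuclideData,
    density_g_mL: float = 1.03,
    n_histories: int = 200_000,
    rng_seed: int = 0,
    include_photons: bool = False,
    fit: TacFit | None = None,
    rate_times_h=None,
) -> SphereDoseResult:
    """Absorbed dose (Gy) to a uniform activity sphere.

    The electron absorbed fraction phi_e is a Monte-Carlo estimate with the
    straight-line CSDA transport (uniform source point, isotropic direction,
    deposition up to the exit of the sphere).  The photon term is a crude
    mean-chord mu_en approximation and is off by default.  If a washout fit
    and sample times are given, the dose rate at those times is reported.
    """
    if volume_mL <= 0:
        raise ValueError("volume must be positive")
    if density_g_mL <= 0:
        raise ValueError("density must be positive")
    radius_um = (3.0 * volume_mL / (4.0 * np.pi)) ** (1 / 3) * 1e4  # mL -> cm -> um

    rng = np.random.default_rng(rng_seed)
    r = radius_um * np.cbrt(rng.random(n_histories))
    mu = rng.uniform(-1.0, 1.0, n_histories)
    e0 = sample_electron_emission(nuclide, rng, n_histories)
    dep = _deposit_in_sphere(e0, r, mu, radius_um, density_g_mL)
    phi_e = float(dep.sum() / e0.sum())
    # stderr of a ratio estimator via per-history deviations
    d = dep - phi_e * e0
    phi_se = float(np.sqrt(np.sum(d * d)) / e0.sum())

    phi_g = 0.0
    if include_photons:
        ek, muen = _muen_table()
        mean_chord_cm = 4.0 / 3.0 * radius_um * 1e-4
        e_lines = nuclide.photons["energy_keV"].to_numpy(float)
        y = nuclide.photons["yield"].to_numpy(float)
        mu_l = np.interp(e_lines, ek, muen) * density_g_mL
        phi_lines = 1.0 - np.exp(-mu_l * mean_chord_cm)
        w = e_lines * y
        phi_g = float((phi_lines * w).sum() / w.sum()) if w.sum() > 0 else 0.0

    cum_bq_s_per_mL = cumulated_conc_MBq_h_per_mL * 1e6 * 3600.0
    rho_kg_per_mL = density_g_mL * 1e-3
    e_dose = cum_bq_s_per_mL * phi_e * nuclide.mean_electron_energy_MeV * MEV_TO_J / rho_kg_per_mL
    g_dose = cum_bq_s_per_mL * phi_g * nuclide.mean_photon_energy_MeV * MEV_TO_J / rho_kg_per_mL

    rates = None
    if fit is not None and rate_times_h is not None:
        tt = np.asarray(rate_times_h, float)
        conc = fit.activity(tt) / volume_mL  # MBq/mL
        rate = (conc * 1e6 * 3600.0 * (phi_e * nuclide.mean_electron_energy_MeV
                                       + phi_g * nuclide.mean_photon_energy_MeV)
                * MEV_TO_J / rho_kg_per_mL)
        rates = pd.DataFrame({"time_h": tt, "dose_rate_Gy_per_h": rate})

    return SphereDoseResult(
        dose_Gy=float(e_dose + g_dose), phi_e=phi_e, phi_e_stderr=phi_se,
        phi_gamma=phi_g, electron_dose_Gy=float(e_dose),
        photon_dose_Gy=float(g_dose), radius_mm=radius_um / 1e3,
        dose_rate_Gy_per_h=rates)
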