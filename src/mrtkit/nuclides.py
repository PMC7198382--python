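"""Radionuclide physical data (Lu-177, In-111).

Decay constants, beta spectra, discrete conversion/Auger electron lines and
photon lines are shipped as plain-text tables under ``mrtkit/data`` and loaded
lazily.  Electron emission sampling uses inverse-CDF sampling on the tabulated
continuous spectrum mixed with the discrete lines.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NuclideData", "load_nuclide", "sample_electron_emission", "SUPPORTED_NUCLIDES"]

#: physical half-lives in hours (ICRP-107: 6.647 d, 2.8047 d)
_HALF_LIVES_H = {"Lu-177": 159.53, "In-111": 67.31}

SUPPORTED_NUCLIDES = tuple(sorted(_HALF_LIVES_H))

_ALIASES = {
    "lu177": "Lu-177", "lu-177": "Lu-177", "177lu": "Lu-177",
    "in111": "In-111", "in-111": "In-111", "111in": "In-111",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mrtkit").joinpath("data", name)))


def _read_table(fname: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(fname), comment="#")


@dataclass(frozen=True)
class NuclideData:
    """Physical decay data for a single radionuclide.

    Energies are MeV except photon line energies which are keV (matching the
    shipped tables); yields are per decay.
    """

    name: str
    half_life_h: float
    #: continuous beta spectrum: columns energy_MeV, density_per_MeV (may be empty)
    beta_spectrum: pd.DataFrame = field(repr=False)
    #: discrete conversion/Auger lines: columns energy_MeV, yield
    discrete_electrons: pd.DataFrame = field(repr=False)
    #: photon lines: columns energy_keV, yield
    photons: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be positive")

    @property
    def decay_constant_per_h(self) -> float:
        return np.log(2.0) / self.half_life_h

    @property
    def decay_constant_per_s(self) -> float:
        return self.decay_constant_per_h / 3600.0

    @property
    def beta_yield(self) -> float:
        """Beta particles emitted per decay (integral of the spectrum)."""
        if self.beta_spectrum.empty:
            return 0.0
        e = self.beta_spectrum["energy_MeV"].to_numpy()
        d = self.beta_spectrum["density_per_MeV"].to_numpy()
        return float(np.trapezoid(d, e))

    @property
    def mean_beta_energy_MeV(self) -> float:
        """Mean kinetic energy of one emitted beta particle (MeV)."""
        if self.beta_spectrum.empty:
            return 0.0
        e = self.beta_spectrum["energy_MeV"].to_numpy()
        d = self.beta_spectrum["density_per_MeV"].to_numpy()
        return float(np.trapezoid(d * e, e) / np.trapezoid(d, e))

    @property
    def mean_electron_energy_MeV(self) -> float:
        """Total electron energy emitted per decay, Delta_e (MeV/decay)."""
        e = self.beta_spectrum
        cont = 0.0
        if not e.empty:
            cont = float(np.trapezoid(
                e["density_per_MeV"].to_numpy() * e["energy_MeV"].to_numpy(),
                e["energy_MeV"].to_numpy(),
            ))
        disc = float((self.discrete_electrons["energy_MeV"]
                      * self.discrete_electrons["yield"]).sum())
        return cont + disc

    @property
    def mean_photon_energy_MeV(self) -> float:
        """Total photon energy emitted per decay, Delta_gamma (MeV/decay)."""
        return float((self.photons["energy_keV"] / 1000.0 * self.photons["yield"]).sum())

    @property
    def electron_yield(self) -> float:
        """Electrons (beta + discrete) emitted per decay."""
        return self.beta_yield + float(self.discrete_electrons["yield"].sum())

    @property
    def max_electron_energy_MeV(self) -> float:
        emax = 0.0
        if not self.beta_spectrum.empty:
            emax = float(self.beta_spectrum["energy_MeV"].max())
        if len(self.discrete_electrons):
            emax = max(emax, float(self.discrete_electrons["energy_MeV"].max()))
        return emax


def load_nuclide(name: str) -> NuclideData:
    """Load the shipped physical data for ``name`` (``Lu-177`` or ``In-111``).

    Loading is deterministic and idempotent (cached); aliases like ``lu177``
    resolve to the same object.
    """
    key = _ALIASES.get(name.strip().lower(), name.strip())
    if key not in _HALF_LIVES_H:
        raise ValueError(
            f"unsupported nuclide {name!r}; supported: {', '.join(SUPPORTED_NUCLIDES)}"
        )
    return _load_cached(key)


@functools.lru_cache(maxsize=None)
def _load_cached(key: str) -> NuclideData:
    tag = key.replace("-", "").lower()
    if key == "Lu-177":
        beta = _read_table(f"{tag}_beta_spectrum.csv")
    else:
        beta = pd.DataFrame(columns=["energy_MeV", "density_per_MeV"])
    return NuclideData(
        name=key,
        half_life_h=_HALF_LIVES_H[key],
        beta_spectrum=beta,
        discrete_electrons=_read_table(f"{tag}_electrons.csv"),
        photons=_read_table(f"{tag}_photons.csv"),
    )


def sample_electron_emission(
    nuclide: NuclideData,
    rng_seed: int | np.random.Generator,
    n: int,
) -> np.ndarray:
    """Draw ``n`` electron energies (MeV) from the mixed beta + discrete spectrum.

    The continuous component is sampled by inverse-CDF interpolation on the
    tabulated spectrum; discrete lines are sampled by yield.  Reproducible for
    a fixed integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    w_cont = nuclide.beta_yield
    lines_e = nuclide.discrete_electrons["energy_MeV"].to_numpy(float)
    lines_y = nuclide.discrete_electrons["yield"].to_numpy(float)
    w_disc = float(lines_y.sum())
    total = w_cont + w_disc
    if total <= 0:
        raise ValueError(f"nuclide {nuclide.name} has no electron emissions")

    pick_cont = rng.random(n) < (w_cont / total)
    out = np.empty(n, float)

    n_cont = int(pick_cont.sum())
    if n_cont:
        e = nuclide.beta_spectrum["energy_MeV"].to_numpy(float)
        d = nuclide.beta_spectrum["density_per_MeV"].to_numpy(float)
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(e) * 0.5 * (d[1:] + d[:-1]))])
        cdf /= cdf[-1]
        out[pick_cont] = np.interp(rng.random(n_cont), cdf, e)
    n_disc = n - n_cont
    if n_disc:
        idx = rng.choice(len(lines_e), size=n_disc, p=lines_y / w_disc)
        out[~pick_cont] = lines_e[idx]
    return out
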