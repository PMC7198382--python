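"""Monte-Carlo cellular S-values and nucleus absorbed dose.

A cell is modelled as concentric spheres (nucleus inside cytoplasm) with the
membrane as a thin source shell at the cell surface.  Electron transport is
straight-line CSDA (no scattering, no delta rays): energy deposited in the
target is the difference of the residual-range energies at the chord entry and
exit points.  This is the main approximation and is justified by cell
dimensions being much smaller than the beta range.  Photons are ignored at the
cellular scale.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclides import NuclideData, sample_electron_emission, _read_table

__all__ = [
    "CellGeometry",
    "CompartmentTimecourse",
    "SValue",
    "SValueSet",
    "electron_range",
    "energy_from_range",
    "compute_svalue",
    "compute_svalue_set",
    "suspension_cross_dose",
    "nucleus_dose",
]

MEV_TO_J = 1.602176634e-13
COMPARTMENTS = ("membrane", "cytoplasm", "nucleus")


# ---------------------------------------------------------------- geometry

@dataclass(frozen=True)
class CellGeometry:
    """Concentric-sphere cell model (micrometres, unit-density by default)."""

    r_nucleus_um: float = 5.0
    r_cell_um: float = 10.0
    membrane_thickness_um: float = 0.01
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.r_nucleus_um < self.r_cell_um):
            raise ValueError("need 0 < r_nucleus < r_cell")
        if self.membrane_thickness_um <= 0 or self.membrane_thickness_um > 0.1 * self.r_cell_um:
            raise ValueError("membrane thickness must be positive and << r_cell")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")

    def mass_kg(self, compartment: str) -> float:
        """Mass of a compartment in kg."""
        rho = self.density_g_cm3 * 1e3  # kg/m^3
        um3_to_m3 = 1e-18
        v_n = 4 / 3 * np.pi * self.r_nucleus_um ** 3
        v_c = 4 / 3 * np.pi * self.r_cell_um ** 3
        if compartment == "nucleus":
            v = v_n
        elif compartment == "cytoplasm":
            v = v_c - v_n
        elif compartment in ("membrane", "cell"):
            ro = self.r_cell_um + self.membrane_thickness_um
            v = (4 / 3 * np.pi * ro ** 3 - v_c) if compartment == "membrane" else v_c
        else:
            raise ValueError(f"unknown compartment {compartment!r}")
        return v * um3_to_m3 * rho

    @property
    def cell_volume_mL(self) -> float:
        return 4 / 3 * np.pi * self.r_cell_um ** 3 * 1e-12  # um^3 -> mL


# ------------------------------------------------- CSDA range <-> energy

@functools.lru_cache(maxsize=1)
def _csda_table() -> tuple[np.ndarray, np.ndarray]:
    df = _read_table("water_csda_range.csv")
    e = df["energy_MeV"].to_numpy(float)
    # g/cm^2 -> um at unit density: r[cm] = R/rho; 1 cm = 1e4 um
    r = df["csda_range_g_cm2"].to_numpy(float) * 1e4
    return e, r


def electron_range(energy_MeV, density_g_cm3: float = 1.0):
    """CSDA range (um) of electrons in water of the given density.

    Log-log interpolation of the shipped NIST table; power-law extrapolation
    below the 1 keV table floor.
    """
    e_tab, r_tab = _csda_table()
    energy = np.asarray(energy_MeV, float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive")
    if np.any(energy > 2.0):
        raise ValueError("energy above 2 MeV is outside the supported domain")
    out = np.exp(np.interp(np.log(energy), np.log(e_tab), np.log(r_tab)))
    # below table floor: range ~ E^k with k from the two lowest entries
    k = np.log(r_tab[1] / r_tab[0]) / np.log(e_tab[1] / e_tab[0])
    low = energy < e_tab[0]
    if np.any(low):
        out = np.where(low, r_tab[0] * (energy / e_tab[0]) ** k, out)
    out = out / density_g_cm3
    return float(out) if np.isscalar(energy_MeV) else out


def energy_from_range(range_um, density_g_cm3: float = 1.0):
    """Inverse of :func:`electron_range`: energy (MeV) of an electron whose
    residual CSDA range is ``range_um``.  Zero or negative range gives 0."""
    e_tab, r_tab = _csda_table()
    r = np.asarray(range_um, float) * density_g_cm3
    out = np.zeros_like(r)
    pos = r > 0
    if np.any(pos):
        out[pos] = np.exp(np.interp(np.log(r[pos]), np.log(r_tab), np.log(e_tab)))
        k = np.log(r_tab[1] / r_tab[0]) / np.log(e_tab[1] / e_tab[0])
        low = pos & (r < r_tab[0])
        out[low] = e_tab[0] * (r[low] / r_tab[0]) ** (1 / k)
    return float(out) if np.isscalar(range_um) else out


# ------------------------------------------------------------ S values

@dataclass(frozen=True)
class SValue:
    """One source -> target S value from the MC estimate."""

    source: str
    target: str
    s_gy_per_bq_s: float
    stderr: float
    absorbed_fraction: float
    af_stderr: float
    n_histories: int

    def __post_init__(self) -> None:
        if self.s_gy_per_bq_s < 0:
            raise ValueError("S value must be >= 0")


@dataclass
class SValueSet:
    """S values to the nucleus keyed by source compartment."""

    geometry: CellGeometry
    nuclide_name: str
    values: dict[str, SValue] = field(default_factory=dict)

    def __getitem__(self, source: str) -> SValue:
        return self.values[source]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"source": v.source, "target": v.target, "S_Gy_per_Bq_s": v.s_gy_per_bq_s,
             "stderr": v.stderr, "absorbed_fraction": v.absorbed_fraction,
             "af_stderr": v.af_stderr, "n_histories": v.n_histories}
            for v in self.values.values()
        ])


def _sample_source_radius(geom: CellGeometry, source: str, u: np.ndarray) -> np.ndarray:
    """Radii of points uniform-in-volume in the source compartment."""
    if source == "nucleus":
        lo, hi = 0.0, geom.r_nucleus_um
    elif source == "cytoplasm":
        lo, hi = geom.r_nucleus_um, geom.r_cell_um
    elif source == "membrane":
        lo, hi = geom.r_cell_um, geom.r_cell_um + geom.membrane_thickness_um
    else:
        raise ValueError(f"unknown compartment {source!r}; expected one of {COMPARTMENTS}")
    return np.cbrt(lo ** 3 + u * (hi ** 3 - lo ** 3))


def _chord(r: np.ndarray, mu: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit path lengths of the forward ray through a centred sphere.

    Source at distance ``r`` from the centre, direction cosine ``mu`` relative
    to the outward radial axis.  Returns (s_entry, s_exit), both 0 when the
    ray misses.
    """
    b = r * mu
    disc = b * b - (r * r - radius * radius)
    hit = disc > 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    s1 = -b - sq
    s2 = -b + sq
    inside = r < radius
    s_entry = np.where(inside, 0.0, np.maximum(s1, 0.0))
    s_exit = np.where(hit & (s2 > 0), s2, 0.0)
    s_entry = np.where(s_exit > 0, s_entry, 0.0)
    return s_entry, s_exit


def _deposit_in_sphere(e0, r, mu, radius, density) -> np.ndarray:
    """Energy (MeV) deposited inside a centred sphere by straight CSDA tracks."""
    s_in, s_out = _chord(r, mu, radius)
    r0 = electron_range(e0, density)
    e_in = energy_from_range(np.maximum(r0 - s_in, 0.0), density)
    e_out = energy_from_range(np.maximum(r0 - s_out, 0.0), density)
    dep = np.where(s_out > 0, e_in - e_out, 0.0)
    return np.maximum(dep, 0.0)


def compute_svalue(
    geometry: CellGeometry,
    source: str,
    nuclide: NuclideData,
    n_histories: int = 100_000,
    rng_seed: int = 0,
    target: str = "nucleus",
) -> SValue:
    """Monte-Carlo S value (Gy per Bq.s) from ``source`` to ``target``.

    Histories: uniform source point in the compartment, electron energy from
    the nuclide's mixed spectrum, isotropic direction, straight-line CSDA
    deposition along the chord through the target sphere (shell for a
    cytoplasm target).
    """
    if n_histories < 10_000:
        raise ValueError("n_histories must be >= 1e4 for a usable standard error")
    if target not in ("nucleus", "cytoplasm"):
        raise ValueError("target must be 'nucleus' or 'cytoplasm'")
    rng = np.random.default_rng(rng_seed)

    r = _sample_source_radius(geometry, source, rng.random(n_histories))
    mu = rng.uniform(-1.0, 1.0, n_histories)
    try:
        e0 = sample_electron_emission(nuclide, rng, n_histories)
    except ValueError:
        # no electron emissions at all -> S = 0 exactly
        return SValue(source, target, 0.0, 0.0, 0.0, 0.0, n_histories)

    rho = geometry.density_g_cm3
    dep = _deposit_in_sphere(e0, r, mu, geometry.r_nucleus_um, rho)
    if target == "cytoplasm":
        dep = _deposit_in_sphere(e0, r, mu, geometry.r_cell_um, rho) - dep

    # per-decay scaling: histories sample emissions; multiply by electrons/decay
    n_e = nuclide.electron_yield
    mean_dep = dep.mean() * n_e
    se_dep = dep.std(ddof=1) / np.sqrt(n_histories) * n_e

    m = geometry.mass_kg(target)
    s = mean_dep * MEV_TO_J / m
    se = se_dep * MEV_TO_J / m
    delta_e = nuclide.mean_electron_energy_MeV
    af = mean_dep / delta_e if delta_e > 0 else 0.0
    af_se = se_dep / delta_e if delta_e > 0 else 0.0
    return SValue(source, target, float(s), float(se), float(af), float(af_se), n_histories)


def compute_svalue_set(
    geometry: CellGeometry,
    nuclide: NuclideData,
    n_histories: int = 100_000,
    rng_seed: int = 0,
) -> SValueSet:
    """S values to the nucleus from all three source compartments."""
    out = SValueSet(geometry=geometry, nuclide_name=nuclide.name)
    for i, src in enumerate(COMPARTMENTS):
        out.values[src] = compute_svalue(
            geometry, src, nuclide, n_histories, rng_seed + i)
    return out


# ------------------------------------------------------ time courses & dose

@dataclass
class CompartmentTimecourse:
    """Per-cell compartment activities and medium concentration over time."""

    times_h: np.ndarray
    membrane_Bq: np.ndarray
    cytoplasm_Bq: np.ndarray
    nucleus_Bq: np.ndarray
    medium_Bq_per_mL: np.ndarray
    cell_density_per_mL: float = 1e6

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("membrane_Bq", "cytoplasm_Bq", "nucleus_Bq", "medium_Bq_per_mL"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.times_h.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)

    def compartment(self, name: str) -> np.ndarray:
        try:
            return {"membrane": self.membrane_Bq, "cytoplasm": self.cytoplasm_Bq,
                    "nucleus": self.nucleus_Bq}[name]
        except KeyError:
            raise ValueError(f"unknown compartment {name!r}") from None

    @classmethod
    def from_csv(cls, path, cell_density_per_mL: float = 1e6) -> "CompartmentTimecourse":
        df = pd.read_csv(path, comment="#")
        return cls(
            times_h=df["time_h"].to_numpy(),
            membrane_Bq=df["membrane_Bq"].to_numpy(),
            cytoplasm_Bq=df["cytoplasm_Bq"].to_numpy(),
            nucleus_Bq=df["nucleus_Bq"].to_numpy(),
            medium_Bq_per_mL=df["medium_Bq_per_mL"].to_numpy(),
            cell_density_per_mL=cell_density_per_mL,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_h": self.times_h, "membrane_Bq": self.membrane_Bq,
            "cytoplasm_Bq": self.cytoplasm_Bq, "nucleus_Bq": self.nucleus_Bq,
            "medium_Bq_per_mL": self.medium_Bq_per_mL,
        }).to_csv(path, index=False)


def _cumulated_bq_s(times_h: np.ndarray, activity: np.ndarray, t_end_h: float,
                    lam_per_h: float) -> float:
    """Time integral of activity (Bq.h -> Bq.s) up to t_end with a physical
    decay tail beyond the last sample."""
    t = times_h
    a = activity
    if t_end_h <= t[-1]:
        keep = t <= t_end_h
        grid = np.unique(np.concatenate([t[keep], [t_end_h]]))
        vals = np.interp(grid, t, a)
        integral_h = np.trapezoid(vals, grid)
    else:
        integral_h = np.trapezoid(a, t)
        if lam_per_h > 0:
            integral_h += a[-1] / lam_per_h * (1 - np.exp(-lam_per_h * (t_end_h - t[-1])))
        else:
            integral_h += a[-1] * (t_end_h - t[-1])
    return float(integral_h) * 3600.0


def suspension_cross_dose(
    tc: CompartmentTimecourse,
    nuclide: NuclideData,
    duration_h: float,
    geometry: CellGeometry | None = None,
) -> float:
    """Cross-dose (Gy) to a cell nucleus from activity in the surrounding
    suspension (medium + neighbouring cells) over ``duration_h``.

    Charged-particle-equilibrium approximation: time-integrated total activity
    concentration times Delta_e over density, minus the own cell's share of
    the cell-borne concentration (its volume fraction), which the self S
    values already count.
    """
    lam = nuclide.decay_constant_per_h
    delta_e_J = nuclide.mean_electron_energy_MeV * MEV_TO_J

    cum_medium = _cumulated_bq_s(tc.times_h, tc.medium_Bq_per_mL, duration_h, lam)
    per_cell = tc.membrane_Bq + tc.cytoplasm_Bq + tc.nucleus_Bq
    cum_cells = _cumulated_bq_s(tc.times_h, per_cell * tc.cell_density_per_mL,
                                duration_h, lam)
    geom = geometry or CellGeometry()
    self_fraction = min(geom.cell_volume_mL * tc.cell_density_per_mL, 1.0)
    cum_conc = cum_medium + cum_cells * (1.0 - self_fraction)  # Bq.s/mL

    rho_kg_per_mL = geom.density_g_cm3 * 1e-3
    return cum_conc * delta_e_J / rho_kg_per_mL


@dataclass(frozen=True)
class DoseBreakdown:
    """Nucleus absorbed dose split by source term (Gy)."""

    membrane: float
    cytoplasm: float
    nucleus: float
    cross: float

    @property
    def self_dose(self) -> float:
        return self.membrane + self.cytoplasm + self.nucleus

    @property
    def total(self) -> float:
        return self.self_dose + self.cross


def nucleus_dose(
    tc: CompartmentTimecourse,
    s: SValueSet,
    nuclide: NuclideData,
    t_end_h: float,
    include_cross: bool = True,
) -> DoseBreakdown:
    """Total nucleus dose = sum over compartments of cumulated activity x S,
    plus the suspension cross-dose."""
    missing = [c for c in COMPARTMENTS if c not in s.values]
    if missing:
        raise ValueError(f"S value set lacks compartments: {missing}")
    lam = nuclide.decay_constant_per_h
    parts = {}
    for src in COMPARTMENTS:
        cum = _cumulated_bq_s(tc.times_h, tc.compartment(src), t_end_h, lam)
        parts[src] = cum * s[src].s_gy_per_bq_s
    cross = (suspension_cross_dose(tc, nuclide, t_end_h, s.geometry)
             if include_cross else 0.0)
    return DoseBreakdown(parts["membrane"], parts["cytoplasm"], parts["nucleus"], cross)
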