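"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's Monte-Carlo code paths: S values are
computed by deterministic fixed-grid quadrature over source position,
direction and emission energy; the sphere absorbed fraction uses the analytic
chord-length distribution of a uniform isotropic source in a sphere.
"""

from __future__ import annotations

import numpy as np

MEV_TO_J = 1.602176634e-13


def _energy_grid(nuclide, n_cont: int = 150):
    """(energies, weights) quadrature for emissions per decay."""
    es, ws = [], []
    spec = nuclide.beta_spectrum
    if len(spec):
        e = spec["energy_MeV"].to_numpy(float)
        d = spec["density_per_MeV"].to_numpy(float)
        grid = np.linspace(e[0], e[-1], n_cont)
        dens = np.interp(grid, e, d)
        w = np.gradient(grid) * dens
        es.append(grid)
        ws.append(w)
    if len(nuclide.discrete_electrons):
        es.append(nuclide.discrete_electrons["energy_MeV"].to_numpy(float))
        ws.append(nuclide.discrete_electrons["yield"].to_numpy(float))
    return np.concatenate(es), np.concatenate(ws)


def _range_interp(energy, e_tab, r_tab):
    return np.exp(np.interp(np.log(np.maximum(energy, 1e-12)),
                            np.log(e_tab), np.log(r_tab)))


def _energy_interp(rng_um, e_tab, r_tab):
    out = np.zeros_like(rng_um)
    pos = rng_um > 0
    out[pos] = np.exp(np.interp(np.log(rng_um[pos]), np.log(r_tab), np.log(e_tab)))
    return out


def svalue_quadrature(r_nucleus_um, r_cell_um, source, nuclide, csda_table,
                      density=1.0, n_r=80, n_mu=400, shell_um=0.01):
    """Deterministic S value (Gy per Bq.s) to the nucleus by triple quadrature."""
    e_tab, r_tab = csda_table
    r_tab = r_tab / density
    if source == "nucleus":
        lo, hi = 0.0, r_nucleus_um
    elif source == "cytoplasm":
        lo, hi = r_nucleus_um, r_cell_um
    elif source == "membrane":
        lo, hi = r_cell_um, r_cell_um + shell_um
    else:
        raise ValueError(source)

    # volume-weighted radial quadrature nodes (midpoint on r^3)
    u = (np.arange(n_r) + 0.5) / n_r
    r_nodes = np.cbrt(lo ** 3 + u * (hi ** 3 - lo ** 3))
    mu = (np.arange(n_mu) + 0.5) / n_mu * 2.0 - 1.0

    E, wE = _energy_grid(nuclide)
    R0 = _range_interp(E, e_tab, r_tab)

    mean_dep = 0.0
    for r in r_nodes:
        b = r * mu
        disc = b * b - (r * r - r_nucleus_um ** 2)
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        s1 = np.where(r < r_nucleus_um, 0.0, np.maximum(-b - sq, 0.0))
        s2 = np.where(hit & (-b + sq > 0), -b + sq, 0.0)
        s1 = np.where(s2 > 0, s1, 0.0)
        # (n_mu, nE)
        rr_in = np.maximum(R0[None, :] - s1[:, None], 0.0)
        rr_out = np.maximum(R0[None, :] - s2[:, None], 0.0)
        dep = _energy_interp(rr_in, e_tab, r_tab) - _energy_interp(rr_out, e_tab, r_tab)
        dep = np.where((s2 > 0)[:, None], np.maximum(dep, 0.0), 0.0)
        mean_dep += (dep * wE[None, :]).sum() / n_mu
    mean_dep /= n_r  # MeV per decay

    m_n = 4 / 3 * np.pi * r_nucleus_um ** 3 * 1e-18 * density * 1e3  # kg
    return mean_dep * MEV_TO_J / m_n


def sphere_absorbed_fraction_chord(radius_um, nuclide, csda_table, density=1.0,
                                   n_x=2000):
    """Electron absorbed fraction of a uniform sphere from the analytic
    forward path-length distribution psi(x) = 1 - 3x/(4R) + x^3/(16R^3)."""
    e_tab, r_tab = csda_table
    r_tab = r_tab / density
    R = radius_um
    x = np.linspace(0, 2 * R, n_x)
    pdf = 3 / (4 * R) - 3 * x ** 2 / (16 * R ** 3)  # -psi'(x)
    E, wE = _energy_grid(nuclide)
    R0 = _range_interp(E, e_tab, r_tab)
    # deposit for exit at distance x: E - E(residual)
    rr = np.maximum(R0[None, :] - x[:, None], 0.0)
    dep = E[None, :] - _energy_interp(rr, e_tab, r_tab)
    mean_dep = np.trapezoid(pdf[:, None] * dep, x, axis=0)  # per emission energy
    return float((mean_dep * wE).sum() / (E * wE).sum())
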