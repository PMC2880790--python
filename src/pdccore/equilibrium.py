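"""Sedimentation-equilibrium simulation and mass analysis.

At equilibrium in the centrifuge cell the radial concentration profile of
an ideal species is exponential in r²: signal(r) = baseline +
Σ_i a_i exp[σ_i (r² − r_ref²)/2] with the reduced buoyant molar mass
σ_i = M_i (1 − v̄ρ) ω² / (R T).  This module simulates such profiles with
optical noise, fits one- or two-species models by nonlinear least squares
(optionally globally over several loading concentrations with a shared
mass), and extrapolates apparent masses to infinite dilution via the
linear 1/M_app-vs-c relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import AVOGADRO, BOLTZMANN_ERG
from .hydro import BuoyancyError, _buoyancy

__all__ = [
    "SEDataset",
    "SpeciesFit",
    "reduced_mass",
    "simulate_se",
    "fit_se",
    "fit_se_global",
    "extrapolate_Mw0",
    "rpm_to_omega",
]

_R_CGS = BOLTZMANN_ERG * AVOGADRO  # erg/(mol K)


def rpm_to_omega(rpm: float) -> float:
    """Rotor speed in rev/min → angular velocity in rad/s."""
    return rpm * 2.0 * np.pi / 60.0


def reduced_mass(M: float, vbar: float, rho: float, omega: float,
                 T: float) -> float:
    """σ = M(1−v̄ρ)ω²/(RT) in cm⁻² (M in Da, r in cm)."""
    return M * _buoyancy(M, vbar, rho) * omega**2 / (_R_CGS * T)


@dataclass
class SEDataset:
    """One radial equilibrium scan."""

    r: np.ndarray  # cm, increasing
    signal: np.ndarray  # fringes / absorbance
    omega: float  # rad/s
    T: float  # K
    r_ref: float  # cm
    loading_concentration: float = 1.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.r.shape != self.signal.shape or self.r.ndim != 1:
            raise ValueError("r and signal must be matching 1D arrays")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("radial positions must be strictly increasing")
        if self.r[0] < 5.8 or self.r[-1] > 7.3:
            raise ValueError("radial window outside the plausible cell range "
                             "(5.8–7.3 cm)")
        if self.omega <= 0 or self.T <= 0:
            raise ValueError("omega and T must be positive")


@dataclass
class SpeciesFit:
    """Converged one- or two-species equilibrium fit."""

    masses: np.ndarray  # Da, per species
    amplitudes: np.ndarray  # signal at r_ref, per species
    baseline: float
    rms: float
    n_species: int

    @property
    def fractions(self) -> np.ndarray:
        """Signal fraction per species (amplitudes normalized)."""
        tot = self.amplitudes.sum()
        return self.amplitudes / tot if tot > 0 else self.amplitudes

    @property
    def Mapp(self) -> float:
        """Apparent (signal-average) molar mass of the fit."""
        return float((self.fractions * self.masses).sum())


def simulate_se(species: Sequence[tuple[float, float, float]], omega: float,
                T: float, rho: float, r_grid: np.ndarray,
                noise_sd: float = 0.0, seed: Optional[int] = None,
                r_ref: Optional[float] = None, baseline: float = 0.0,
                loading_concentration: float = 1.0) -> SEDataset:
    """Synthetic equilibrium profile for a list of (M, v̄, amplitude).

    Adds i.i.d. Gaussian optical noise of ``noise_sd``; with noise a seed
    is required so every simulation is reproducible.
    """
    r = np.asarray(r_grid, dtype=float)
    if r_ref is None:
        r_ref = float(r[0])
    signal = np.full_like(r, baseline)
    for M, vbar, a in species:
        if M == 0:
            signal = signal + a
            continue
        sig = reduced_mass(M, vbar, rho, omega, T)
        signal = signal + a * np.exp(sig * (r**2 - r_ref**2) / 2.0)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("noisy simulation requires an explicit seed")
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd,
                                                             size=r.shape)
    return SEDataset(r, signal, omega=omega, T=T, r_ref=r_ref,
                     loading_concentration=loading_concentration)


def _se_model(params: np.ndarray, r: np.ndarray, r_ref: float,
              k: float, n_species: int) -> np.ndarray:
    """params = [baseline, a_1, M_1, ..., a_n, M_n]; k = (1−v̄ρ)ω²/(RT)."""
    out = np.full_like(r, params[0])
    x = (r**2 - r_ref**2) / 2.0
    for i in range(n_species):
        a, M = params[1 + 2 * i], params[2 + 2 * i]
        out = out + a * np.exp(np.clip(k * M * x, -700, 700))
    return out


def _init_mass(ds: SEDataset, k: float) -> float:
    """Log-linear slope of the upper third of the profile seeds M."""
    n = len(ds.r)
    sl = slice(2 * n // 3, n)
    y = ds.signal[sl] - ds.signal.min() + 1e-9
    x = (ds.r[sl] ** 2 - ds.r_ref**2) / 2.0
    good = y > 0
    if good.sum() < 2:
        return 1e5
    slope = np.polyfit(x[good], np.log(y[good]), 1)[0]
    return float(max(slope / k, 1e3))


def fit_se(dataset: SEDataset, vbar: float, rho: float,
           n_species: int = 1) -> SpeciesFit:
    """Nonlinear least-squares fit of a 1- or 2-species profile.

    Fits baseline plus per-species amplitude (at r_ref) and mass, with
    multi-start initialization: the first species is seeded from the
    log-linear slope of the upper third of the profile, the second at 2×
    and 4× the first.  Raises on non-convergence of every start.
    """
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    k = _buoyancy(1.0, vbar, rho) * dataset.omega**2 / (_R_CGS * dataset.T)
    M0 = _init_mass(dataset, k)
    span = dataset.signal.max() - dataset.signal.min()
    base0 = dataset.signal.min()

    starts = []
    if n_species == 1:
        for m in (M0, 0.5 * M0, 2.0 * M0):
            starts.append([base0, max(span, 1e-6), m])
    else:
        for m2 in (2.0 * M0, 4.0 * M0):
            starts.append([base0, max(span, 1e-6), M0, 0.05 * span, m2])

    best = None
    for p0 in starts:
        lb = [-np.inf] + [0.0, 1e2] * n_species
        ub = [np.inf] + [np.inf, 1e9] * n_species
        try:
            res = least_squares(
                lambda p: _se_model(p, dataset.r, dataset.r_ref, k,
                                    n_species) - dataset.signal,
                p0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("equilibrium fit failed to converge from any start")
    p = best.x
    masses = np.array([p[2 + 2 * i] for i in range(n_species)])
    amps = np.array([p[1 + 2 * i] for i in range(n_species)])
    order = np.argsort(-amps)  # predominant species first
    rms = float(np.sqrt(2.0 * best.cost / len(dataset.r)))
    return SpeciesFit(masses[order], amps[order], baseline=float(p[0]),
                      rms=rms, n_species=n_species)


def fit_se_global(datasets: Sequence[SEDataset], vbar: float, rho: float,
                  n_species: int = 1) -> list[SpeciesFit]:
    """Global fit over several loading concentrations with shared masses.

    Masses are common to all datasets; amplitudes and baselines are per
    dataset (interference offsets are arbitrary).  Returns one
    :class:`SpeciesFit` per dataset, all carrying the shared masses.
    """
    singles = [fit_se(ds, vbar, rho, n_species) for ds in datasets]
    M0 = np.mean([s.masses for s in singles], axis=0)

    def unpack(p):
        masses = p[:n_species]
        rest = p[n_species:].reshape(len(datasets), 1 + n_species)
        return masses, rest

    def resid(p):
        masses, rest = unpack(p)
        out = []
        for ds, row in zip(datasets, rest):
            k = _buoyancy(1.0, vbar, rho) * ds.omega**2 / (_R_CGS * ds.T)
            params = np.concatenate([[row[0]], np.ravel(
                np.column_stack([row[1:], masses]))])
            out.append(_se_model(params, ds.r, ds.r_ref, k, n_species)
                       - ds.signal)
        return np.concatenate(out)

    p0 = np.concatenate([M0] + [
        np.concatenate([[s.baseline], s.amplitudes]) for s in singles])
    lb = np.concatenate([[1e2] * n_species] + [
        [-np.inf] + [0.0] * n_species for _ in singles])
    ub = np.full_like(p0, np.inf)
    res = least_squares(resid, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise RuntimeError("global equilibrium fit failed to converge")
    masses, rest = unpack(res.x)
    fits = []
    for ds, row in zip(datasets, rest):
        k = _buoyancy(1.0, vbar, rho) * ds.omega**2 / (_R_CGS * ds.T)
        params = np.concatenate([[row[0]], np.ravel(
            np.column_stack([row[1:], masses]))])
        r = _se_model(params, ds.r, ds.r_ref, k, n_species) - ds.signal
        amps = np.asarray(row[1:], dtype=float)
        order = np.argsort(-amps)
        fits.append(SpeciesFit(np.asarray(masses)[order], amps[order],
                               baseline=float(row[0]),
                               rms=float(np.sqrt((r**2).mean())),
                               n_species=n_species))
    return fits


def extrapolate_Mw0(concentrations: Sequence[float],
                    Mapp_values: Sequence[float]) -> tuple[float, float]:
    """Infinite-dilution molar mass from the 1/M_app-vs-c line.

    Linear fit of 1/M_app against loading concentration; Mw⁰ is the
    reciprocal intercept, with first-order error propagation for its
    standard error.
    """
    c = np.asarray(concentrations, dtype=float)
    m = np.asarray(Mapp_values, dtype=float)
    if c.shape != m.shape or len(c) < 2:
        raise ValueError("need >= 2 matching (c, Mapp) points")
    if np.any(m <= 0):
        raise ValueError("apparent masses must be positive")
    if len(c) == 2:  # exact line, no residual dof for an error estimate
        slope = (1.0 / m[1] - 1.0 / m[0]) / (c[1] - c[0])
        coef = np.array([slope, 1.0 / m[0] - slope * c[0]])
        cov = np.full((2, 2), np.inf)
    else:
        coef, cov = np.polyfit(c, 1.0 / m, 1, cov=True)
    intercept = coef[1]
    if intercept <= 0:
        raise ValueError("non-positive intercept: unphysical extrapolation")
    Mw0 = 1.0 / intercept
    return float(Mw0), float(np.sqrt(cov[1, 1]) * Mw0**2)
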