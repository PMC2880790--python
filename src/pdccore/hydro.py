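"""Hydrodynamic characterization of the cores.

Implements the sedimentation-velocity-derived parameter set for a particle
of known mass M, partial specific volume v̄ and standardized sedimentation
coefficient s20,w⁰ (anhydrous sphere radius R0, friction f, frictional
ratio f/f0, Stokes radius/diameter, translational diffusion coefficient),
standardization of s to 20 °C water, infinite-dilution extrapolation,
cubic-grid coarse-graining of point models into hydrodynamic bead models,
rigid-body translational friction of bead models (Rotne–Prager–Yamakawa
supermatrix and Kirkwood double-sum approximations), and the hydration
conversion factor F = (v̄/(v̄+δ₁v₁⁰))^(1/3) that turns an anhydrous
computed s into its hydrated equivalent.

All interface units: Å, Da, S (1e-13 s), mL/g, poise, K; cgs internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .assembly import BeadModel
from .constants import (AVOGADRO, BOLTZMANN_ERG, CM_PER_ANGSTROM, SVEDBERG,
                        WATER20_DENSITY, WATER20_VISCOSITY)

__all__ = [
    "SolventConditions",
    "MolecularParams",
    "HydroResult",
    "BuoyancyError",
    "WATER_20C",
    "anhydrous_radius",
    "svedberg_params",
    "standardize_s",
    "extrapolate_s0",
    "coarse_grain",
    "bead_friction",
    "hydration_factor",
    "model_sedimentation",
]


class BuoyancyError(ValueError):
    """Raised when (1 − v̄ρ) ≤ 0: the particle would float, not sediment."""


@dataclass(frozen=True)
class SolventConditions:
    """Solvent state: temperature (K), density (g/mL), viscosity (poise)."""

    T: float = 293.15
    rho: float = WATER20_DENSITY
    eta: float = WATER20_VISCOSITY
    v1_0: Optional[float] = None  # solvent specific volume, mL/g

    def __post_init__(self) -> None:
        if min(self.T, self.rho, self.eta) <= 0:
            raise ValueError("solvent T, rho, eta must all be positive")
        if self.v1_0 is None:
            object.__setattr__(self, "v1_0", 1.0 / self.rho)
        elif self.v1_0 <= 0:
            raise ValueError("solvent specific volume must be positive")


#: Standard water at 20 °C (the reference state for s20,w).
WATER_20C = SolventConditions()


@dataclass(frozen=True)
class MolecularParams:
    """Molar mass (Da), partial specific volume (mL/g), hydration (g/g)."""

    M: float
    vbar: float
    delta1: float = 0.4

    def __post_init__(self) -> None:
        if self.M <= 0 or self.vbar <= 0 or self.delta1 < 0:
            raise ValueError("M, vbar must be positive and delta1 >= 0")
        if not 0.5 < self.vbar < 1.0:
            warnings.warn(
                f"vbar={self.vbar} outside the usual protein window (0.5–1.0)",
                stacklevel=3)


@dataclass
class HydroResult:
    """Derived hydrodynamic parameter set for one assembly."""

    M: float
    vbar: float
    s20w0: Optional[float] = None  # S
    R0: Optional[float] = None  # Å
    f: Optional[float] = None  # g/s
    f_over_f0: Optional[float] = None
    Rs: Optional[float] = None  # Å
    Ds: Optional[float] = None  # Å (= 2 Rs)
    Dt: Optional[float] = None  # cm²/s
    F: Optional[float] = None  # hydration conversion factor
    s_anh: Optional[float] = None  # S, bead-model anhydrous
    s_hyd: Optional[float] = None  # S, = F·s_anh

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _buoyancy(M: float, vbar: float, rho: float) -> float:
    b = 1.0 - vbar * rho
    if b <= 0:
        raise BuoyancyError(
            f"(1 - vbar*rho) = {b:.4g} <= 0: particle is neutrally or "
            "positively buoyant")
    return b


def anhydrous_radius(params: MolecularParams) -> float:
    """Radius (Å) of the anhydrous sphere of equal mass and v̄.

    R0 = (3 M v̄ / (4π N_A))^(1/3).
    """
    v_cm3 = params.M * params.vbar / AVOGADRO
    return (3.0 * v_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0) / CM_PER_ANGSTROM


def hydration_factor(vbar: float, delta1: float, v1_0: float) -> float:
    """Hydration conversion factor F = (v̄ / (v̄ + δ₁·v₁⁰))^(1/3).

    Multiplies an anhydrous computed sedimentation coefficient to give its
    hydrated equivalent; F = 1 for δ₁ = 0 and decreases with hydration.
    """
    if vbar <= 0 or v1_0 <= 0 or delta1 < 0:
        raise ValueError("vbar, v1_0 must be positive and delta1 >= 0")
    return (vbar / (vbar + delta1 * v1_0)) ** (1.0 / 3.0)


def svedberg_params(params: MolecularParams, s20w0: float,
                    solvent: SolventConditions = WATER_20C) -> HydroResult:
    """Full Svedberg-derived parameter set from (M, v̄, s).

    f = M(1−v̄ρ)/(N_A·s);  Rs = f/(6πη);  Ds = 2Rs;  Dt = k_B T/f;
    f0 = 6πη·R0 with R0 the anhydrous-sphere radius; f/f0 = f/f0.
    """
    if s20w0 <= 0:
        raise ValueError("sedimentation coefficient must be positive")
    b = _buoyancy(params.M, params.vbar, solvent.rho)
    s_sec = s20w0 * SVEDBERG
    f = params.M * b / (AVOGADRO * s_sec)  # g/s
    R0 = anhydrous_radius(params)
    f0 = 6.0 * np.pi * solvent.eta * R0 * CM_PER_ANGSTROM
    Rs = f / (6.0 * np.pi * solvent.eta) / CM_PER_ANGSTROM
    Dt = BOLTZMANN_ERG * solvent.T / f
    F = hydration_factor(params.vbar, params.delta1, solvent.v1_0)
    return HydroResult(M=params.M, vbar=params.vbar, s20w0=s20w0, R0=R0,
                       f=f, f_over_f0=f / f0, Rs=Rs, Ds=2.0 * Rs, Dt=Dt, F=F)


def standardize_s(s_obs: float, experimental: SolventConditions, vbar: float,
                  standard: SolventConditions = WATER_20C) -> float:
    """Correct an observed s to standard conditions (water, 20 °C).

    s20,w = s_obs · (η_exp/η_20,w) · ((1−v̄ρ)_20,w / (1−v̄ρ)_exp).
    """
    b_exp = _buoyancy(1.0, vbar, experimental.rho)
    b_std = _buoyancy(1.0, vbar, standard.rho)
    return s_obs * (experimental.eta / standard.eta) * (b_std / b_exp)


def extrapolate_s0(concentrations: Sequence[float], s_values: Sequence[float],
                   errors: Optional[Sequence[float]] = None,
                   reciprocal: bool = False) -> tuple[float, float]:
    """Infinite-dilution sedimentation coefficient from s(c).

    Weighted linear fit of s vs c (default) or of 1/s vs c
    (``reciprocal=True``); returns (s0, stderr of s0).  A single point is
    returned as-is with infinite stderr and a warning.
    """
    c = np.asarray(concentrations, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if c.shape != s.shape or c.ndim != 1:
        raise ValueError("concentrations and s_values must match")
    if len(c) < 2:
        warnings.warn("single concentration: s0 is the lone point",
                      stacklevel=2)
        return float(s[0]), float("inf")
    y = 1.0 / s if reciprocal else s
    w = None
    if errors is not None:
        err = np.asarray(errors, dtype=float)
        w = 1.0 / (err / s**2 if reciprocal else err)
    if len(c) == 2:  # exact line, no residual dof for an error estimate
        slope = (y[1] - y[0]) / (c[1] - c[0])
        coef = np.array([slope, y[0] - slope * c[0]])
        cov = np.full((2, 2), np.inf)
    else:
        coef, cov = np.polyfit(c, y, 1, w=w,
                               cov="unscaled" if w is not None else True)
    intercept, err0 = coef[1], float(np.sqrt(cov[1, 1]))
    if reciprocal:
        s0 = 1.0 / intercept
        return float(s0), float(err0 * s0**2)
    return float(intercept), err0


def coarse_grain(points: BeadModel | np.ndarray, grid_spacing: float,
                 target_volume: float,
                 weights: Optional[np.ndarray] = None) -> BeadModel:
    """Cubic-grid coarse-graining of a point/bead model into an HBM.

    A cubic grid of spacing ``grid_spacing`` is laid over the bounding
    box; all points in a cell collapse to one bead at their weighted
    centroid, with bead volume proportional to the cell's point mass and
    radii set so the total bead volume equals ``target_volume`` exactly
    (the anhydrous particle volume M·v̄/N_A).
    """
    if grid_spacing <= 0 or target_volume <= 0:
        raise ValueError("grid spacing and target volume must be positive")
    if isinstance(points, BeadModel):
        xyz = points.coords
        w = points.weights * points.volumes
    else:
        xyz = np.atleast_2d(np.asarray(points, dtype=float))
        if xyz.size == 0:
            raise ValueError("empty input")
        w = np.ones(len(xyz)) if weights is None else np.asarray(weights, float)
    if len(xyz) == 0:
        raise ValueError("empty input")

    cells = np.floor((xyz - xyz.min(axis=0)) / grid_spacing).astype(np.int64)
    _, inverse = np.unique(cells, axis=0, return_inverse=True)
    n_cells = inverse.max() + 1
    mass = np.bincount(inverse, weights=w, minlength=n_cells)
    centres = np.column_stack([
        np.bincount(inverse, weights=w * xyz[:, k], minlength=n_cells)
        for k in range(3)
    ]) / mass[:, None]
    vol = target_volume * mass / mass.sum()
    radii = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    return BeadModel(centres, radii, label="coarse-grained")


def _rpy_blocks(coords_cm: np.ndarray, radii_cm: np.ndarray,
                eta: float) -> np.ndarray:
    """3N×3N RPY mobility supermatrix (non-overlapping beads)."""
    n = len(coords_cm)
    M = np.zeros((3 * n, 3 * n))
    for i in range(n):
        M[3 * i:3 * i + 3, 3 * i:3 * i + 3] = np.eye(3) / (
            6.0 * np.pi * eta * radii_cm[i])
    for i in range(n):
        for j in range(i + 1, n):
            rij = coords_cm[j] - coords_cm[i]
            r = np.linalg.norm(rij)
            rr = np.outer(rij, rij) / r**2
            a2 = radii_cm[i] ** 2 + radii_cm[j] ** 2
            T = (1.0 / (8.0 * np.pi * eta * r)) * (
                (1.0 + a2 / (3.0 * r**2)) * np.eye(3)
                + (1.0 - a2 / r**2) * rr)
            M[3 * i:3 * i + 3, 3 * j:3 * j + 3] = T
            M[3 * j:3 * j + 3, 3 * i:3 * i + 3] = T
    return M


def _resolve_overlaps(coords: np.ndarray, radii: np.ndarray,
                      policy: str) -> np.ndarray:
    """Shrink radii uniformly to the largest non-overlapping scale."""
    if len(coords) < 2:
        return radii
    d = pdist(coords)
    i, j = np.triu_indices(len(coords), k=1)
    ratio = d / (radii[i] + radii[j])
    worst = ratio.min()
    if worst >= 1.0:
        return radii
    if policy == "reject":
        raise ValueError("bead model contains overlapping beads")
    warnings.warn(
        f"overlapping beads: radii uniformly scaled by {worst:.3f} for the "
        "supermatrix friction computation", stacklevel=3)
    return radii * worst * 0.999999


def bead_friction(model: BeadModel, solvent: SolventConditions = WATER_20C,
                  method: str = "supermatrix",
                  overlap_policy: str = "shrink") -> float:
    """Rigid-body translational friction coefficient f_t (g/s).

    ``method="supermatrix"`` builds the 3N×3N Rotne–Prager–Yamakawa
    mobility matrix, solves for bead forces under unit uniform velocity
    and averages the total force over the three axes.  ``method=
    "kirkwood"`` uses the double-sum approximation (orientationally
    averaged pair mobilities), cheaper and typically within ~10%.
    Both are invariant under rigid motion of the model.  Rotation–
    translation coupling is neglected (no centre-of-resistance search).
    """
    coords = model.coords * CM_PER_ANGSTROM
    radii = model.radii * CM_PER_ANGSTROM
    eta = solvent.eta
    zeta = 6.0 * np.pi * eta * radii

    if model.n_beads == 1:
        return float(zeta[0])

    if method == "supermatrix":
        radii = _resolve_overlaps(coords, radii, overlap_policy)
        M = _rpy_blocks(coords, radii, eta)
        n = model.n_beads
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"singular mobility matrix: {exc}") from exc
        # f_t per axis = total force under unit velocity; average over axes
        K = Minv.reshape(n, 3, n, 3).sum(axis=(0, 2))
        return float(np.trace(K) / 3.0)
    if method == "kirkwood":
        # D_t = kT/(3 N^2) * Tr Σ_ij M_ij  →  f_t = N² / H
        M = _rpy_blocks(coords, radii, eta)
        n = model.n_beads
        H = np.trace(M.reshape(n, 3, n, 3).sum(axis=(0, 2))) / 3.0
        return float(n**2 / H)
    raise ValueError("method must be 'supermatrix' or 'kirkwood'")


def model_sedimentation(model: BeadModel, params: MolecularParams,
                        solvent: SolventConditions = WATER_20C,
                        method: str = "supermatrix") -> tuple[float, float]:
    """Anhydrous and hydrated sedimentation coefficients of a bead model.

    s_anh = M(1−v̄ρ)/(N_A·f_t) from the bead-model friction;
    s_hyd = F·s_anh with the hydration conversion factor at δ₁ = params.delta1.
    Returns (s_anh, s_hyd) in Svedbergs.
    """
    b = _buoyancy(params.M, params.vbar, solvent.rho)
    f_t = bead_friction(model, solvent, method=method)
    s_anh = params.M * b / (AVOGADRO * f_t) / SVEDBERG
    F = hydration_factor(params.vbar, params.delta1, solvent.v1_0)
    return float(s_anh), float(F * s_anh)
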