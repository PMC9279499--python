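"""Dielectrophoresis (DEP) physics: complex permittivities, the Clausius-Mossotti
factor, point-dipole and surface DEP forces, CM spectra and the crossover frequency.

The time-averaged DEP force on a spherical particle that is small compared with the
field non-uniformity is

    F_DEP = 2 pi a^3 eps_m Re(f_cm) grad(E_rms^2)

with f_cm = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*) and complex permittivities
eps* = eps - i sigma / omega.  Permittivities entering the force and the CM factor
are absolute (relative permittivity times eps_0); conductivities are in S/m.

Re(f_cm) is bounded in [-0.5, 1] for passive materials: positive values mean
positive DEP (attraction to high-field regions, pearl-chain formation), negative
values mean negative DEP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Vacuum permittivity, F/m (CODATA 2018).
EPSILON_0 = 8.8541878128e-12


@dataclass(frozen=True)
class DielectricMaterial:
    """A homogeneous dielectric with relative permittivity and conductivity.

    Parameters
    ----------
    epsilon_rel : float
        Relative permittivity (dimensionless, > 0).
    sigma : float
        Electrical conductivity in S/m (>= 0).
    """

    epsilon_rel: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.epsilon_rel > 0:
            raise ValueError(f"epsilon_rel must be > 0, got {self.epsilon_rel}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def epsilon_abs(self) -> float:
        """Absolute permittivity, F/m."""
        return self.epsilon_rel * EPSILON_0


@dataclass(frozen=True)
class DielectricSystem:
    """A spherical particle suspended in a medium under an AC field.

    `radius` is the particle radius in meters; `omega` the angular frequency
    of the applied field in rad/s.
    """

    particle: DielectricMaterial
    medium: DielectricMaterial
    radius: float
    omega: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


def complex_permittivity(material: DielectricMaterial, omega: float) -> complex:
    """Complex absolute permittivity eps* = eps_rel*eps_0 - i*sigma/omega.

    Parameters
    ----------
    material : DielectricMaterial
    omega : float
        Angular frequency in rad/s, must be positive.
    """
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    return material.epsilon_abs - 1j * material.sigma / omega


def clausius_mossotti(system: DielectricSystem) -> complex:
    """Complex Clausius-Mossotti factor (eps_p* - eps_m*)/(eps_p* + 2 eps_m*).

    The real part sets the sign and strength of the DEP force.  Raises
    ZeroDivisionError if the denominator vanishes (only possible for active,
    i.e. non-physical, material combinations).
    """
    ep = complex_permittivity(system.particle, system.omega)
    em = complex_permittivity(system.medium, system.omega)
    denom = ep + 2 * em
    if denom == 0:
        raise ZeroDivisionError("singular Clausius-Mossotti denominator")
    return (ep - em) / denom


def dep_force_dipole(system: DielectricSystem, grad_e2: float) -> float:
    """Point-dipole DEP force magnitude 2 pi a^3 eps_m Re(f_cm) grad(E_rms^2).

    `grad_e2` is the gradient of the squared RMS field, V^2/m^3 (user supplied;
    this module does not solve for fields).  The result is in newtons and carries
    the sign of Re(f_cm) for positive `grad_e2`.
    """
    fcm = clausius_mossotti(system)
    return (
        2.0
        * np.pi
        * system.radius**3
        * system.medium.epsilon_abs
        * fcm.real
        * grad_e2
    )


@dataclass(frozen=True)
class SurfaceFieldPoint:
    """Field quantities at one point of a particle surface.

    E is the field magnitude (V/m), e_n its component along the outward unit
    normal `n_hat`, and `epsilon_e` the relative permittivity of the medium.
    """

    e: float
    e_n: float
    n_hat: tuple[float, float, float]
    epsilon_e: float

    def __post_init__(self) -> None:
        n = np.asarray(self.n_hat, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("n_hat must be a unit vector")
        if abs(self.e_n) > abs(self.e) * (1 + 1e-12):
            raise ValueError("|e_n| cannot exceed |e|")


def dep_force_surface(point: SurfaceFieldPoint) -> np.ndarray:
    """Surface-form DEP force density eps_E*eps_0*E*E_n - (1/2)*eps_E*eps_0*E^2,
    directed along the surface normal.

    Evaluated pointwise; no surface integration is attempted (micrograph-based
    field reconstruction on textile electrodes is too irregular for that).
    """
    n = np.asarray(point.n_hat, dtype=float)
    scale = point.epsilon_e * EPSILON_0
    magnitude = scale * point.e * point.e_n - 0.5 * scale * point.e**2
    return magnitude * n


def cm_spectrum(
    particle: DielectricMaterial,
    medium: DielectricMaterial,
    omega_grid: np.ndarray,
) -> np.ndarray:
    """Re(f_cm) evaluated on a grid of angular frequencies.

    The spectrum interpolates between the DC (conductivity-dominated) limit
    (sigma_p - sigma_m)/(sigma_p + 2 sigma_m) and the high-frequency
    (permittivity-dominated) limit (eps_p - eps_m)/(eps_p + 2 eps_m).
    """
    omega = np.asarray(omega_grid, dtype=float)
    if omega.size and not np.all(omega > 0):
        raise ValueError("omega_grid must be strictly positive")
    if omega.size > 1 and not np.all(np.diff(omega) > 0):
        raise ValueError("omega_grid must be sorted ascending")
    ep = particle.epsilon_abs - 1j * particle.sigma / omega
    em = medium.epsilon_abs - 1j * medium.sigma / omega
    return np.real((ep - em) / (ep + 2 * em))


def cm_limits(
    particle: DielectricMaterial, medium: DielectricMaterial
) -> tuple[float, float]:
    """Closed-form (DC, high-frequency) limits of Re(f_cm)."""
    lo = (particle.sigma - medium.sigma) / (particle.sigma + 2 * medium.sigma)
    hi = (particle.epsilon_abs - medium.epsilon_abs) / (
        particle.epsilon_abs + 2 * medium.epsilon_abs
    )
    return lo, hi


def crossover_frequency(
    particle: DielectricMaterial, medium: DielectricMaterial
) -> float | None:
    """Angular frequency where Re(f_cm) changes sign, or None if it never does.

    Closed form:  omega_c^2 = -(sigma_p - sigma_m)(sigma_p + 2 sigma_m)
                              / ((eps_p - eps_m)(eps_p + 2 eps_m))
    with absolute permittivities.  A real crossover exists only when the DC and
    high-frequency limits of Re(f_cm) have opposite signs.
    """
    num = -(particle.sigma - medium.sigma) * (particle.sigma + 2 * medium.sigma)
    den = (particle.epsilon_abs - medium.epsilon_abs) * (
        particle.epsilon_abs + 2 * medium.epsilon_abs
    )
    if den == 0:
        return None
    w2 = num / den
    if w2 <= 0:
        return None
    return float(np.sqrt(w2))
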