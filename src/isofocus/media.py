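"""Acoustic and transport properties of iodixanol/cell-medium mixtures.

Iso-acoustic focusing works by suspending cells in mixtures of cell medium
and iodixanol (OptiPrep) whose acoustic impedance Z = rho*c = sqrt(rho/kappa)
increases monotonically with iodixanol concentration.  This module models
those mixtures, computes the monopole/dipole acoustic contrast factor of a
small particle, and locates the concentration of zero contrast -- the
particle's iso-acoustic point (IAP), at which Z_med equals the particle's
effective acoustic impedance.

Concentrations are expressed throughout on the percentage scale used for
OptiPrep dilutions: 60% iodixanol = undiluted stock, 0% = plain diluent
(DPBS + 2% FBS).  All other quantities are SI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq

__all__ = [
    "AcousticProperties",
    "ParticleProperties",
    "MixtureModel",
    "ConversionPolynomial",
    "ZeroContrast",
    "NoIsoAcousticPointError",
    "impedance",
    "contrast_factor",
    "medium_from_concentration",
    "zero_contrast_concentration",
    "fit_conversion_polynomial",
]

CONCENTRATION_RANGE = (0.0, 60.0)


class NoIsoAcousticPointError(ValueError):
    """The particle's contrast factor does not change sign in the valid range.

    ``direction`` is ``"high"`` when the contrast stays positive (effective
    impedance above the range, the particle would focus to the channel
    center) and ``"low"`` when it stays negative (particle rests at a wall).
    """

    def __init__(self, direction: str):
        self.direction = direction
        super().__init__(f"no iso-acoustic point in range (impedance {direction})")


@dataclass(frozen=True)
class AcousticProperties:
    """Density, adiabatic compressibility and dynamic viscosity of a liquid."""

    density: float  # kg m^-3
    compressibility: float  # Pa^-1
    viscosity: float  # Pa s

    def __post_init__(self) -> None:
        for name in ("density", "compressibility", "viscosity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sound_speed(self) -> float:
        """c0 = 1/sqrt(rho*kappa), in m s^-1."""
        return 1.0 / np.sqrt(self.density * self.compressibility)

    @property
    def acoustic_impedance(self) -> float:
        """Z = rho*c0 = sqrt(rho/kappa), in Pa s m^-1."""
        return np.sqrt(self.density / self.compressibility)


@dataclass(frozen=True)
class ParticleProperties:
    """A small spherical particle in the long-wavelength (Rayleigh) limit."""

    radius: float  # m
    density: float  # kg m^-3
    compressibility: float  # Pa^-1

    def __post_init__(self) -> None:
        for name in ("radius", "density", "compressibility"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def check_long_wavelength(self, wavenumber: float) -> None:
        """Warn when k*a grows beyond the Rayleigh-regime assumption."""
        if wavenumber * self.radius > 0.5:
            warnings.warn(
                "particle radius is not small compared to the wavelength; "
                "the monopole/dipole contrast expression degrades",
                stacklevel=2,
            )


def impedance(props: AcousticProperties) -> float:
    """Characteristic acoustic impedance Z = sqrt(rho/kappa) in Pa s m^-1."""
    return props.acoustic_impedance


def contrast_factor(particle: ParticleProperties, medium: AcousticProperties) -> float:
    """Acoustic contrast factor Phi of a particle in a standing plane wave.

    Phi = (1 - kappa_tilde)/3 + (rho_tilde - 1)/(2*rho_tilde + 1) with
    kappa_tilde = kappa_p/kappa_0 and rho_tilde = rho_p/rho_0.  The sign of
    Phi sets the direction of the radiation force: positive-contrast
    particles focus to the pressure node, negative-contrast particles to the
    antinodes at the walls.  Phi = 0 defines the iso-acoustic point.
    """
    kt = particle.compressibility / medium.compressibility
    rt = particle.density / medium.density
    return float((1.0 - kt) / 3.0 + (rt - 1.0) / (2.0 * rt + 1.0))


# --- printed anchors used to calibrate the default mixture model ------------
# PIV fit in 10% iodixanol: local pressure amplitude 0.39 MPa at a fitted
# energy density of 16.27 J m^-3, so rho0*c0^2 = p_a^2/(4*E_ac); the same
# medium gives the 2.23 um polystyrene bead a contrast factor of 0.199.
_PA_ANCHOR = 0.39e6  # Pa
_EAC_ANCHOR = 16.27  # J m^-3
_PHI_ANCHOR = 0.199
_ANCHOR_CONC = 10.0  # %
POLYSTYRENE_BEAD = ParticleProperties(radius=2.23e-6, density=1050.0, compressibility=1.65e-10)

_DILUENT_DENSITY = 1005.0  # DPBS + 2% FBS
_DILUENT_SOUND_SPEED = 1500.0
_STOCK_DENSITY = 1320.0  # 60% iodixanol (OptiPrep)
_STOCK_SOUND_SPEED = 1620.0


def _calibrated_anchor_point() -> tuple[float, float]:
    """(rho, c0) of 10% iodixanol solving both printed anchors exactly."""
    rho_c2 = _PA_ANCHOR**2 / (4.0 * _EAC_ANCHOR)  # rho0 * c0^2
    kappa = 1.0 / rho_c2
    kt = POLYSTYRENE_BEAD.compressibility / kappa
    dipole = _PHI_ANCHOR - (1.0 - kt) / 3.0
    rho_tilde = (1.0 + dipole) / (1.0 - 2.0 * dipole)
    rho = POLYSTYRENE_BEAD.density / rho_tilde
    return rho, float(np.sqrt(rho_c2 / rho))


@dataclass(frozen=True)
class MixtureModel:
    """Iodixanol concentration -> liquid properties, via per-property polynomials.

    Coefficients are ascending-power polynomials in concentration (percent).
    The default model interpolates density and sound speed quadratically
    between the diluent, a calibrated 10% point (pinned to the printed
    polystyrene contrast factor and pressure-amplitude anchors), and the 60%
    stock; viscosity is linear.  ``default()`` caches a single instance.
    """

    density_coeffs: tuple[float, ...]
    sound_speed_coeffs: tuple[float, ...]
    viscosity_coeffs: tuple[float, ...]
    valid_range: tuple[float, float] = CONCENTRATION_RANGE

    def density(self, c):
        return npoly.polyval(c, self.density_coeffs)

    def sound_speed(self, c):
        return npoly.polyval(c, self.sound_speed_coeffs)

    def viscosity(self, c):
        return npoly.polyval(c, self.viscosity_coeffs)

    def compressibility(self, c):
        return 1.0 / (self.density(c) * self.sound_speed(c) ** 2)

    def impedance(self, c):
        """Z_med(c) = rho(c) * c0(c), vectorized over c."""
        return self.density(c) * self.sound_speed(c)

    def properties_at(self, c: float) -> AcousticProperties:
        return AcousticProperties(
            density=float(self.density(c)),
            compressibility=float(self.compressibility(c)),
            viscosity=float(self.viscosity(c)),
        )

    def is_impedance_monotone(self, step: float = 0.1) -> bool:
        lo, hi = self.valid_range
        grid = np.arange(lo, hi + step / 2, step)
        return bool(np.all(np.diff(self.impedance(grid)) > 0))

    @classmethod
    def default(cls) -> "MixtureModel":
        global _DEFAULT_MODEL
        if _DEFAULT_MODEL is None:
            rho10, c10 = _calibrated_anchor_point()
            concs = [0.0, _ANCHOR_CONC, 60.0]
            rho_coeffs = npoly.polyfit(concs, [_DILUENT_DENSITY, rho10, _STOCK_DENSITY], 2)
            c0_coeffs = npoly.polyfit(concs, [_DILUENT_SOUND_SPEED, c10, _STOCK_SOUND_SPEED], 2)
            # eta(0)=1.0 mPa s, eta(10%)=1.3 mPa s, linear
            visc_coeffs = (1.0e-3, 3.0e-5)
            _DEFAULT_MODEL = cls(
                density_coeffs=tuple(rho_coeffs),
                sound_speed_coeffs=tuple(c0_coeffs),
                viscosity_coeffs=visc_coeffs,
            )
        return _DEFAULT_MODEL

    def to_dict(self) -> dict:
        return {
            "density_coeffs": list(self.density_coeffs),
            "sound_speed_coeffs": list(self.sound_speed_coeffs),
            "viscosity_coeffs": list(self.viscosity_coeffs),
            "valid_range": list(self.valid_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            density_coeffs=tuple(d["density_coeffs"]),
            sound_speed_coeffs=tuple(d["sound_speed_coeffs"]),
            viscosity_coeffs=tuple(d["viscosity_coeffs"]),
            valid_range=tuple(d.get("valid_range", CONCENTRATION_RANGE)),
        )


_DEFAULT_MODEL: MixtureModel | None = None


def medium_from_concentration(model: MixtureModel, c: float) -> AcousticProperties:
    """Liquid properties of a c% iodixanol mixture under ``model``."""
    lo, hi = model.valid_range
    if not (lo <= c <= hi):
        raise ValueError(f"concentration {c}% outside valid range [{lo}, {hi}]%")
    return model.properties_at(c)


@dataclass(frozen=True)
class ZeroContrast:
    """Root of Phi(c): the particle's iso-acoustic medium condition."""

    concentration: float  # %
    impedance: float  # Pa s m^-1 -- the particle's effective acoustic impedance


def zero_contrast_concentration(
    particle: ParticleProperties,
    model: MixtureModel | None = None,
    tol: float = 1e-6,
) -> ZeroContrast:
    """Concentration at which the particle's acoustic contrast vanishes.

    Because Z_med(c) is strictly increasing while the particle is fixed,
    Phi(c) crosses zero at most once; the medium impedance at the root is the
    particle's effective acoustic impedance ("at the IAP, Z_cell = Z_med").

    Raises :class:`NoIsoAcousticPointError` when Phi has one sign over the
    whole range -- the particle would end up at the channel center ("high")
    or at a wall ("low").
    """
    model = model or MixtureModel.default()
    lo, hi = model.valid_range

    def phi(c: float) -> float:
        return contrast_factor(particle, model.properties_at(c))

    phi_lo, phi_hi = phi(lo), phi(hi)
    if phi_lo == 0.0:
        root = lo
    elif phi_hi == 0.0:
        root = hi
    elif phi_lo > 0 and phi_hi > 0:
        raise NoIsoAcousticPointError("high")
    elif phi_lo < 0 and phi_hi < 0:
        raise NoIsoAcousticPointError("low")
    else:
        root = brentq(phi, lo, hi, xtol=tol)
    return ZeroContrast(concentration=float(root), impedance=float(model.impedance(root)))


@dataclass(frozen=True)
class ConversionPolynomial:
    """Degree-2 map from iodixanol concentration (%) to impedance (Pa s m^-1).

    Mirrors the experimental calibration in which standard iodixanol/dye
    solutions are fitted with a second-degree polynomial to convert the
    normalized tracer intensity into medium acoustic impedance.
    """

    coeffs: tuple[float, float, float]  # ascending powers
    valid_range: tuple[float, float]
    rms_residual: float = 0.0
    monotone: bool = True

    def __call__(self, c):
        return npoly.polyval(c, self.coeffs)


def fit_conversion_polynomial(
    concentrations, impedances, valid_range: tuple[float, float] | None = None
) -> ConversionPolynomial:
    """Least-squares degree-2 fit of Z(c) through calibration samples.

    Requires at least three distinct concentrations.  A fit that is not
    strictly increasing over the validity range is flagged (``monotone``
    False) and a warning is issued, since inversion of intensity to
    impedance then becomes ambiguous.
    """
    c = np.asarray(concentrations, dtype=float)
    z = np.asarray(impedances, dtype=float)
    if c.shape != z.shape:
        raise ValueError("concentration and impedance arrays must match")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations for a degree-2 fit")
    coeffs = npoly.polyfit(c, z, 2)
    resid = z - npoly.polyval(c, coeffs)
    rms = float(np.sqrt(np.mean(resid**2)))
    rng = valid_range or (float(c.min()), float(c.max()))
    grid = np.linspace(rng[0], rng[1], 256)
    monotone = bool(np.all(np.diff(npoly.polyval(grid, coeffs)) > 0))
    if not monotone:
        warnings.warn("fitted conversion polynomial is not monotone over its range", stacklevel=2)
    return ConversionPolynomial(
        coeffs=tuple(float(x) for x in coeffs),
        valid_range=rng,
        rms_residual=rms,
        monotone=monotone,
    )


def conversion_polynomial_from_model(
    model: MixtureModel, c_lo: float, c_hi: float, n: int = 9
) -> ConversionPolynomial:
    """Fit the standard calibration polynomial to a mixture model's Z(c)."""
    grid = np.linspace(c_lo, c_hi, n)
    return fit_conversion_polynomial(grid, model.impedance(grid), valid_range=(c_lo, c_hi))
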