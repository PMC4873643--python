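"""Half-wave standing-wave field model and the two field calibrations.

The resonator sustains a half-wavelength pressure standing wave across the
channel width W, with the pressure node on the centerline (y = W/2, with
y = 0 at the left wall).  A particle of contrast factor Phi experiences the
time-averaged radiation force

    F_rad(y) = 4 pi Phi k_y a^3 E_ac sin(2 k_y y),

balanced by Stokes drag so that the transverse velocity is
u(y) = u0 + F_rad/(6 pi eta a), where u0 is a constant bulk offset
(the fitted remnant of boundary-driven streaming/drift).

Two calibrations are implemented the way they are done experimentally:

* :func:`fit_piv_profile` -- nonlinear least squares of stop-flow micro-PIV
  bead velocities u(y) for (u0, E_ac, k_y);
* :func:`calibrate_voltage_energy` -- inversion of observed furthest bead
  penetration at several transducer voltages to E_ac(U), then a one-parameter
  fit E_ac = k U^2 through the origin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import optimize, stats

from .media import AcousticProperties, ParticleProperties, contrast_factor

__all__ = [
    "StandingWaveField",
    "VoltageCalibration",
    "PIVFit",
    "UnidentifiableFitError",
    "SaturatedObservationError",
    "pressure_amplitude",
    "energy_from_pressure",
    "energy_from_voltage",
    "radiation_force",
    "radiation_velocity",
    "fit_piv_profile",
    "calibrate_voltage_energy",
]


class UnidentifiableFitError(RuntimeError):
    """The data do not constrain the field parameters (e.g. zero contrast)."""


class SaturatedObservationError(ValueError):
    """A bead observed at the channel center carries no energy information."""


@dataclass(frozen=True)
class StandingWaveField:
    """Parameters of the transverse half-wave resonance."""

    energy_density: float  # E_ac, J m^-3
    wavenumber: float  # k_y, m^-1
    width: float  # channel width W, m
    offset_velocity: float = 0.0  # u0, m s^-1

    def __post_init__(self) -> None:
        if self.energy_density < 0:
            raise ValueError("energy density must be non-negative")
        if self.wavenumber <= 0 or self.width <= 0:
            raise ValueError("wavenumber and width must be positive")
        wavelength = 2.0 * math.pi / self.wavenumber
        if abs(wavelength / 2.0 - self.width) / self.width > 0.1:
            warnings.warn(
                "wavenumber is more than 10% off the half-wave resonance "
                f"condition (lambda/2 = {wavelength / 2:.3g} m vs W = {self.width:.3g} m)",
                stacklevel=2,
            )

    @property
    def wavelength(self) -> float:
        return 2.0 * math.pi / self.wavenumber

    @classmethod
    def half_wave(cls, width: float, energy_density: float, offset_velocity: float = 0.0):
        """Nominal resonance with the node pinned at the channel centerline."""
        return cls(
            energy_density=energy_density,
            wavenumber=math.pi / width,
            width=width,
            offset_velocity=offset_velocity,
        )


@dataclass(frozen=True)
class VoltageCalibration:
    """E_ac = k U^2 relation between transducer voltage and energy density."""

    k: float  # J m^-3 V^-2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("voltage calibration coefficient must be positive")


def pressure_amplitude(energy_density: float, medium: AcousticProperties) -> float:
    """Pressure amplitude p_a of a 1D standing wave, from E_ac = p_a^2/(4 rho c^2)."""
    if energy_density < 0:
        raise ValueError("energy density must be non-negative")
    return 2.0 * medium.sound_speed * math.sqrt(medium.density * energy_density)


def energy_from_pressure(pressure: float, medium: AcousticProperties) -> float:
    """Inverse of :func:`pressure_amplitude`."""
    return pressure**2 / (4.0 * medium.density * medium.sound_speed**2)


def energy_from_voltage(cal: VoltageCalibration, voltage: float) -> float:
    if voltage < 0:
        raise ValueError("voltage must be non-negative")
    return cal.k * voltage**2


def radiation_force(
    field: StandingWaveField,
    particle: ParticleProperties,
    medium: AcousticProperties,
    y,
):
    """Transverse radiation force (N) at position(s) y from the left wall."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > field.width)):
        raise ValueError("position outside the channel")
    phi = contrast_factor(particle, medium)
    force = (
        4.0
        * math.pi
        * phi
        * field.wavenumber
        * particle.radius**3
        * field.energy_density
        * np.sin(2.0 * field.wavenumber * y)
    )
    return force if force.ndim else float(force)


def radiation_velocity(
    field: StandingWaveField,
    particle: ParticleProperties,
    medium: AcousticProperties,
    y,
):
    """Stokes-drag-limited transverse velocity u(y) = u0 + F_rad/(6 pi eta a)."""
    if medium.viscosity <= 0:
        raise ValueError("viscosity must be positive")
    drag = 6.0 * math.pi * medium.viscosity * particle.radius
    u = field.offset_velocity + np.asarray(radiation_force(field, particle, medium, y)) / drag
    return u if u.ndim else float(u)


@dataclass
class PIVFit:
    """Result of the stop-flow micro-PIV velocity-profile fit."""

    offset_velocity: float  # u0
    energy_density: float  # E_ac
    wavenumber: float  # k_y
    ci95: dict = dataclass_field(default_factory=dict)  # parameter -> (lo, hi)
    residuals: np.ndarray | None = None
    rms: float = float("nan")
    covariance: np.ndarray | None = None
    identifiable: bool = True

    def as_field(self, width: float) -> StandingWaveField:
        return StandingWaveField(
            energy_density=self.energy_density,
            wavenumber=self.wavenumber,
            width=width,
            offset_velocity=self.offset_velocity,
        )


def fit_piv_profile(
    y,
    u,
    particle: ParticleProperties,
    medium: AcousticProperties,
    width: float,
    max_iterations: int = 500,
) -> PIVFit:
    """Fit u(y) = u0 + 4 pi Phi k a^3 E sin(2 k y)/(6 pi eta a) for (u0, E, k).

    Initialization follows the structure of the model: u0 = 0, k = pi/W
    (nominal half-wave), and E from the closed-form amplitude relation at
    max|u|.  95% confidence intervals come from the Jacobian-based parameter
    covariance.  A degenerate all-zero velocity sample yields E -> 0 with an
    unbounded wavenumber interval and is flagged non-identifiable.
    """
    y = np.asarray(y, dtype=float)
    u = np.asarray(u, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 PIV samples")
    if np.ptp(y) < width / 2:
        raise ValueError("PIV samples must span at least half the channel width")
    phi = contrast_factor(particle, medium)
    if phi == 0.0:
        raise UnidentifiableFitError("zero acoustic contrast: energy density unidentifiable")

    a = particle.radius
    eta = medium.viscosity
    amp_per_E = 2.0 * phi * a**2 / (3.0 * eta)  # u = u0 + amp_per_E * k * E * sin(2ky)

    def model(yy, u0, e_ac, k):
        return u0 + amp_per_E * k * e_ac * np.sin(2.0 * k * yy)

    k0 = math.pi / width
    umax = float(np.max(np.abs(u)))
    e0 = max(umax / abs(amp_per_E * k0), 1e-12)
    p0 = (0.0, e0, k0)

    if umax == 0.0:
        return PIVFit(
            offset_velocity=0.0,
            energy_density=0.0,
            wavenumber=k0,
            ci95={"wavenumber": (0.0, float("inf"))},
            residuals=np.zeros_like(u),
            rms=0.0,
            identifiable=False,
        )

    try:
        popt, pcov = optimize.curve_fit(
            model,
            y,
            u,
            p0=p0,
            maxfev=max_iterations * 4,
            bounds=([-np.inf, 0.0, 0.1 * k0], [np.inf, np.inf, 10.0 * k0]),
        )
    except RuntimeError as exc:  # pragma: no cover - exercised only on pathological data
        raise UnidentifiableFitError(f"PIV fit did not converge: {exc}") from exc

    resid = u - model(y, *popt)
    dof = max(y.size - 3, 1)
    tval = stats.t.ppf(0.975, dof)
    names = ("offset_velocity", "energy_density", "wavenumber")
    se = np.sqrt(np.diag(pcov))
    ci = {n: (float(p - tval * s), float(p + tval * s)) for n, p, s in zip(names, popt, se)}
    return PIVFit(
        offset_velocity=float(popt[0]),
        energy_density=float(popt[1]),
        wavenumber=float(popt[2]),
        ci95=ci,
        residuals=resid,
        rms=float(np.sqrt(np.mean(resid**2))),
        covariance=pcov,
        identifiable=bool(np.all(np.isfinite(se))),
    )


def stop_flow_penetration(
    energy_density: float,
    exposure_time: float,
    particle: ParticleProperties,
    medium: AcousticProperties,
    width: float,
    y0: float,
    offset_velocity: float = 0.0,
) -> float:
    """Furthest transverse penetration of a bead after ``exposure_time``.

    For u0 = 0 the stop-flow trajectory in a homogeneous medium has the
    closed form tan(k y(t)) = tan(k y0) exp(2 k u_s t) with
    u_s = 2 Phi k a^2 E/(3 eta); otherwise the ODE is integrated.
    """
    from scipy.integrate import solve_ivp

    k = math.pi / width
    phi = contrast_factor(particle, medium)
    u_s = 2.0 * phi * k * particle.radius**2 * energy_density / (3.0 * medium.viscosity)
    if offset_velocity == 0.0:
        t = math.tan(k * y0) * math.exp(2.0 * k * u_s * exposure_time)
        return math.atan(t) / k
    sol = solve_ivp(
        lambda _t, yy: offset_velocity + u_s * np.sin(2.0 * k * np.clip(yy, 0, width)),
        (0.0, exposure_time),
        [y0],
        rtol=1e-9,
        atol=1e-13,
    )
    return float(np.clip(sol.y[0, -1], 0.0, width))


def calibrate_voltage_energy(
    observations,
    exposure_time: float,
    particle: ParticleProperties,
    medium: AcousticProperties,
    width: float,
    y0: float = 10e-6,
    saturation_tol: float = 1e-6,
    e_tol: float = 1e-8,
) -> VoltageCalibration:
    """Invert furthest-penetration observations to E_ac(U) and fit E = k U^2.

    ``observations`` is a sequence of (voltage, furthest-penetration y)
    pairs, with the penetration measured from the wall the beads start near.
    Each observation is inverted to an energy density by bisection on the
    simulated penetration (which is strictly increasing in E_ac); the
    quadratic coefficient k is then the least-squares solution through the
    origin.  A bead observed at the channel center is saturated -- any
    sufficiently large energy reproduces it -- and raises
    :class:`SaturatedObservationError`.
    """
    obs = [(float(U), float(yobs)) for U, yobs in observations]
    if len(obs) < 1:
        raise ValueError("need at least one (voltage, penetration) observation")
    node = width / 2.0
    energies = []
    for U, yobs in obs:
        if yobs >= node - saturation_tol:
            raise SaturatedObservationError(
                f"bead at {U} V reached the channel center: energy unbounded from below the data"
            )
        if yobs <= y0:
            raise ValueError("observed penetration does not exceed the release position")

        def pen(e: float, _y=yobs) -> float:
            return stop_flow_penetration(e, exposure_time, particle, medium, width, y0) - _y

        e_hi = 1.0
        while pen(e_hi) < 0:
            e_hi *= 2.0
            if e_hi > 1e7:
                raise RuntimeError("penetration failed to reach the observation")
        energies.append(optimize.brentq(pen, 0.0, e_hi, xtol=e_tol))
    u2 = np.array([U**2 for U, _ in obs])
    e = np.array(energies)
    k = float(np.dot(u2, e) / np.dot(u2, u2))
    return VoltageCalibration(k=k)
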