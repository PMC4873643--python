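"""Cross-channel solute concentration profiles and their diffusive evolution.

At the trifurcation inlet the central stream (high iodixanol) is laminated
between two side streams (low iodixanol), producing a top-hat concentration
profile across the channel width.  As the liquid flows downstream the
profile relaxes by molecular diffusion; under plug flow the downstream
position x maps to a diffusion time t = W H x / Q_tot.  The resulting
impedance profile Z_med(y) is what cells equilibrate in.

The diffusion solve uses a cosine-spectral (DCT-II) representation on a
cell-centered grid, which enforces the no-flux walls exactly, conserves mass
to round-off, is unconditionally stable, and satisfies the semigroup
property exactly (evolution just multiplies modal amplitudes by
exp(-D k_n^2 t)).

A dense central layer is gravitationally unstable; the acoustic field
stabilizes it when the acoustic energy density exceeds the destabilizing
hydrostatic pressure scale.  :func:`stability_margin` evaluates that
criterion as the ratio E_ac / (Delta-rho g H).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.fft import dct, idct

from .media import MixtureModel

if TYPE_CHECKING:  # pragma: no cover
    from .acoustics import StandingWaveField

__all__ = [
    "ChannelGeometry",
    "FlowConfig",
    "ConcentrationProfile",
    "StabilityResult",
    "D_IODIXANOL",
    "D_DEXTRAN",
    "initial_profile",
    "evolve",
    "residence_time",
    "stability_margin",
    "impedance_profile",
]

D_IODIXANOL = 2.5e-10  # m^2 s^-1
D_DEXTRAN = 2.2e-10  # m^2 s^-1, 3 kDa dextran tracer
STANDARD_GRAVITY = 9.81  # m s^-2


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular resonator channel; defaults match the IAF device."""

    width: float = 375e-6  # m
    height: float = 150e-6  # m
    length: float = 25e-3  # m
    imaging_position: float = 20e-3  # m downstream of the inlet

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.length <= 0:
            raise ValueError("channel dimensions must be positive")
        if not (0 < self.imaging_position <= self.length):
            raise ValueError("imaging position must lie within the channel")

    @property
    def cross_section(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class FlowConfig:
    """Total and central-inlet volume flow rates (m^3 s^-1)."""

    total: float
    central: float

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total flow rate must be positive")
        if not (0 <= self.central <= self.total):
            raise ValueError("central flow rate must lie in [0, total]")

    @property
    def central_fraction(self) -> float:
        return self.central / self.total


@dataclass(frozen=True)
class ConcentrationProfile:
    """Solute concentration (%) on a uniform cell-centered y grid over [0, W]."""

    y: np.ndarray  # m, cell centers
    values: np.ndarray  # %
    diffusivity: float  # m^2 s^-1
    time: float = 0.0  # elapsed diffusion time, s

    def __post_init__(self) -> None:
        if self.y.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be non-negative")

    @property
    def width(self) -> float:
        # cell-centered grid: y_i = (i + 1/2) * dy
        return float(self.y[-1] + self.y[0])

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def interpolate(self, y_query):
        return np.interp(np.clip(y_query, 0.0, self.width), self.y, self.values)


def initial_profile(
    flow: FlowConfig,
    geom: ChannelGeometry,
    c_side: float,
    c_center: float,
    diffusivity: float = D_IODIXANOL,
    n: int = 512,
) -> ConcentrationProfile:
    """Plug-flow top-hat at the inlet: central band width (Q_c/Q_tot) W."""
    dy = geom.width / n
    y = (np.arange(n) + 0.5) * dy
    half_band = 0.5 * flow.central_fraction * geom.width
    values = np.where(np.abs(y - geom.width / 2.0) < half_band, c_center, c_side).astype(float)
    return ConcentrationProfile(y=y, values=values, diffusivity=diffusivity, time=0.0)


class _SpectralEvolver:
    """Caches the DCT of a profile so c(y, t) is a modal damping + inverse DCT."""

    def __init__(self, profile: ConcentrationProfile):
        self.profile = profile
        self.y = profile.y
        n = profile.y.size
        self._coeffs = dct(profile.values, type=2, norm="ortho")
        self._kn2 = (np.arange(n) * math.pi / profile.width) ** 2
        self._d = profile.diffusivity
        self._last: tuple[float, np.ndarray] | None = None

    def values_at(self, dt: float) -> np.ndarray:
        """Profile values after an additional diffusion time dt >= 0."""
        if self._last is not None and self._last[0] == dt:
            return self._last[1]
        damped = self._coeffs * np.exp(-self._d * self._kn2 * dt)
        vals = idct(damped, type=2, norm="ortho")
        self._last = (dt, vals)
        return vals


def evolve(profile: ConcentrationProfile, dt: float) -> ConcentrationProfile:
    """Advance the no-flux diffusion equation dc/dt = D d2c/dy2 by dt seconds."""
    if dt < 0:
        raise ValueError("time increment must be non-negative")
    if dt == 0.0:
        return profile
    vals = _SpectralEvolver(profile).values_at(dt)
    return replace(profile, values=vals, time=profile.time + dt)


def residence_time(geom: ChannelGeometry, q_total: float, x: float | None = None) -> float:
    """Plug-flow diffusion time to downstream position x: t = W H x / Q_tot."""
    if x is None:
        x = geom.imaging_position
    if not (0 <= x <= geom.length):
        raise ValueError("x must lie within the channel")
    return geom.cross_section * x / q_total


@dataclass(frozen=True)
class StabilityResult:
    """Acoustic stabilization of a dense central layer against gravity."""

    margin: float  # E_ac / (Delta-rho g H); inf when the profile is homogeneous
    stable: bool
    collapse: bool  # gravitational collapse expected (margin < 1 or no field)

    @property
    def unconditionally_stable(self) -> bool:
        return math.isinf(self.margin)


def stability_margin(
    profile: ConcentrationProfile,
    model: MixtureModel,
    field: "StandingWaveField",
    geom: ChannelGeometry,
) -> StabilityResult:
    """Ratio of acoustic energy density to the hydrostatic pressure scale.

    The stabilizing criterion is E_ac > Delta-rho g H, with Delta-rho the
    density span across the profile and H the full channel depth (the
    hydrostatic scale of the densest-over-lightest configuration).  A margin
    above one means the laminated gradient is held in place by the field;
    below one (or with the sound off) the dense central layer collapses to
    the channel floor.
    """
    density = model.density(profile.values)
    delta_rho = float(np.max(density) - np.min(density))
    if delta_rho == 0.0:
        return StabilityResult(margin=float("inf"), stable=True, collapse=False)
    margin = field.energy_density / (delta_rho * STANDARD_GRAVITY * geom.height)
    return StabilityResult(margin=float(margin), stable=margin > 1.0, collapse=margin <= 1.0)


def impedance_profile(profile: ConcentrationProfile, model: MixtureModel) -> np.ndarray:
    """Pointwise medium impedance Z_med(y) (Pa s m^-1) on the profile grid."""
    lo, hi = model.valid_range
    vals = profile.values
    if np.any(vals < lo - 1e-9) or np.any(vals > hi + 1e-9):
        raise ValueError("profile concentrations outside the mixture model's range")
    return np.asarray(model.impedance(vals), dtype=float)


def save_profile_csv(profile: ConcentrationProfile, path) -> None:
    """Write (y_m, concentration_percent) rows."""
    np.savetxt(
        path,
        np.column_stack([profile.y, profile.values]),
        delimiter=",",
        header="y_m,concentration_percent",
        comments="",
    )


def load_profile_csv(path, diffusivity: float = D_IODIXANOL, time: float = 0.0) -> ConcentrationProfile:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return ConcentrationProfile(
        y=data[:, 0], values=data[:, 1], diffusivity=diffusivity, time=time
    )


def plot_profiles(profiles, labels, path) -> None:
    """Save a PNG comparing normalized cross-channel profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for prof, label in zip(profiles, labels):
        span = np.max(prof.values) - np.min(prof.values)
        norm = (prof.values - np.min(prof.values)) / (span if span else 1.0)
        ax.plot(prof.y * 1e6, norm, label=label)
    ax.set_xlabel("y (um)")
    ax.set_ylabel("normalized concentration")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
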