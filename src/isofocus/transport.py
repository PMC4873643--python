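"""Cell trajectories in the evolving impedance gradient and their IAPs.

A cell at transverse position y moves with

    dy/dt = u0 + (2/3) Phi(y, t) k_y a^2 E_ac sin(2 k_y y) / eta(y, t),

where the contrast factor Phi and viscosity eta are evaluated from the local
iodixanol concentration c(y, t), itself diffusing on the same clock (the
concentration field is advanced spectrally, so c(y, t) is exact in time).
A cell with positive contrast climbs the impedance gradient toward the
channel center until Phi crosses zero at its iso-acoustic point; migration is
self-stabilizing because Phi is a decreasing function of concentration.

Trajectories are 1D in y: sedimentation in depth and axial velocity profiles
are outside the model.  Walls are absorbing in the sense that the kinematics
stall there (the force vanishes at the antinodes) and cells resting at a wall
or at the center are flagged censored -- their impedance lies below or above
the gradient's measurable span.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .gradient import ConcentrationProfile, _SpectralEvolver, impedance_profile
from .media import MixtureModel, ParticleProperties
from .acoustics import StandingWaveField

__all__ = [
    "CellModel",
    "Track",
    "SimulationConfig",
    "IAPCrossings",
    "TimeToIAP",
    "migrate",
    "find_iap",
    "time_to_iap",
    "simulate_population",
]

Z_SANITY_BAND = (1.0e6, 2.5e6)  # Pa s m^-1


@dataclass(frozen=True)
class CellModel:
    """A cell as a Rayleigh particle with an effective acoustic impedance.

    ``z_cell`` is the impedance of the medium in which the cell's acoustic
    contrast vanishes; when constructed via :meth:`from_impedance` the
    compressibility is solved so that the zero-contrast condition holds at
    exactly that impedance under the given mixture model.
    """

    particle: ParticleProperties
    label: str = "cell"
    z_cell: float | None = None  # Pa s m^-1
    y0: float | None = None  # start position, m

    def __post_init__(self) -> None:
        if self.z_cell is not None and not (Z_SANITY_BAND[0] <= self.z_cell <= Z_SANITY_BAND[1]):
            import warnings

            warnings.warn(
                f"effective impedance {self.z_cell:.3g} Pa s m^-1 outside the "
                f"physiological sanity band {Z_SANITY_BAND}",
                stacklevel=2,
            )

    @classmethod
    def from_impedance(
        cls,
        z_cell: float,
        model: MixtureModel | None = None,
        radius: float = 4.0e-6,
        density: float = 1060.0,
        label: str = "cell",
        y0: float | None = None,
    ) -> "CellModel":
        """Build a cell whose zero-contrast medium impedance equals ``z_cell``.

        The density is prescribed (effective whole-cell value); the
        compressibility is then fixed by requiring the monopole and dipole
        terms to cancel at the concentration c* where Z_med(c*) = z_cell.
        """
        model = model or MixtureModel.default()
        lo, hi = model.valid_range
        z_lo, z_hi = float(model.impedance(lo)), float(model.impedance(hi))
        if not (z_lo <= z_cell <= z_hi):
            raise ValueError(
                f"target impedance {z_cell:.4g} outside the model's span [{z_lo:.4g}, {z_hi:.4g}]"
            )
        c_star = brentq(lambda c: float(model.impedance(c)) - z_cell, lo, hi, xtol=1e-9)
        rho_m = float(model.density(c_star))
        rho_t = density / rho_m
        dipole = (rho_t - 1.0) / (2.0 * rho_t + 1.0)
        kappa_p = float(model.compressibility(c_star)) * (1.0 + 3.0 * dipole)
        particle = ParticleProperties(radius=radius, density=density, compressibility=kappa_p)
        return cls(particle=particle, label=label, z_cell=float(z_cell), y0=y0)


@dataclass(frozen=True)
class Track:
    """Time series of a cell's transverse position."""

    t: np.ndarray  # s, strictly increasing
    y: np.ndarray  # m, within [0, W]
    frame_rate: float | None = None  # Hz
    cell_id: str = ""
    meta: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same shape")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def velocities(self) -> np.ndarray:
        """Central finite differences of y over t (one-sided at the ends)."""
        return np.gradient(self.y, self.t)


@dataclass(frozen=True)
class SimulationConfig:
    rtol: float = 1e-7
    atol: float = 1e-11  # m
    plateau_tol: float | None = None  # eps_y; default W/200 at call time
    n_samples: int = 201
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.plateau_tol is not None and self.plateau_tol <= 0:
            raise ValueError("plateau tolerance must be positive")


def _velocity(y, dt, cells, field, model, evolver, width, freeze):
    """Vectorized transverse velocity of all cells at elapsed time dt."""
    yy = np.clip(y, 0.0, width)
    c = np.interp(yy, evolver.y, evolver.values_at(0.0 if freeze else dt))
    rho_m = model.density(c)
    kap_m = model.compressibility(c)
    eta = model.viscosity(c)
    kt = cells["kappa"] / kap_m
    rt = cells["rho"] / rho_m
    phi = (1.0 - kt) / 3.0 + (rt - 1.0) / (2.0 * rt + 1.0)
    return field.offset_velocity + (
        (2.0 / 3.0)
        * phi
        * field.wavenumber
        * cells["a"] ** 2
        * field.energy_density
        * np.sin(2.0 * field.wavenumber * yy)
        / eta
    )


def _cell_arrays(cells) -> dict:
    return {
        "rho": np.array([c.particle.density for c in cells]),
        "kappa": np.array([c.particle.compressibility for c in cells]),
        "a": np.array([c.particle.radius for c in cells]),
    }


def migrate(
    cell: CellModel,
    field: StandingWaveField,
    profile0: ConcentrationProfile,
    model: MixtureModel,
    t_span: float,
    cfg: SimulationConfig | None = None,
    y0: float | None = None,
    freeze_gradient: bool = False,
) -> Track:
    """Integrate a single cell's trajectory over ``t_span`` seconds.

    ``profile0`` is the concentration profile at the moment the cell enters
    the field; it keeps diffusing during the migration unless
    ``freeze_gradient`` is set (useful for Lyapunov-style analyses).
    """
    cfg = cfg or SimulationConfig()
    start = y0 if y0 is not None else cell.y0
    if start is None:
        raise ValueError("no start position: pass y0 or set CellModel.y0")
    width = field.width
    if not (0.0 < start < width):
        raise ValueError("start position must lie strictly inside the channel")
    evolver = _SpectralEvolver(profile0)
    arrays = _cell_arrays([cell])

    sol = solve_ivp(
        lambda t, y: _velocity(y, t, arrays, field, model, evolver, width, freeze_gradient),
        (0.0, t_span),
        [start],
        rtol=cfg.rtol,
        atol=cfg.atol,
        dense_output=True,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    ts = np.linspace(0.0, t_span, cfg.n_samples)
    ys = np.clip(sol.sol(ts)[0], 0.0, width)
    return Track(t=ts, y=ys, cell_id=cell.label, meta={"y0": float(start)})


class IAPCrossings(NamedTuple):
    """Iso-acoustic positions on each side of the channel (None if absent)."""

    left: float | None
    right: float | None
    flag: str  # "in range" | "out of range low" | "out of range high"


def find_iap(y_grid, z_profile, z_cell: float, tol: float = 1e-9) -> IAPCrossings:
    """Locate where Z_med(y) = z_cell on each monotone half-profile.

    The profile must increase from each wall toward the center (the
    configuration the laminated gradient produces).  A cell whose impedance
    lies below the wall value rests at a wall ("out of range low"); one above
    the center value collects at the channel center ("out of range high").
    """
    y_grid = np.asarray(y_grid, dtype=float)
    z = np.asarray(z_profile, dtype=float)
    mid = y_grid.size // 2
    left_z, right_z = z[:mid], z[mid:][::-1]
    for half in (left_z, right_z):
        if np.any(np.diff(half) < -tol * max(1.0, float(np.max(np.abs(z))))):
            raise ValueError("half-profile is not monotone from wall to center")
    z_wall = max(left_z[0], right_z[0])
    z_center = min(left_z[-1], right_z[-1])
    if z_cell < z_wall:
        return IAPCrossings(None, None, "out of range low")
    if z_cell > z_center:
        return IAPCrossings(None, None, "out of range high")
    left = float(np.interp(z_cell, left_z, y_grid[:mid]))
    right = float(np.interp(z_cell, right_z, y_grid[mid:][::-1]))
    return IAPCrossings(left, right, "in range")


class TimeToIAP(NamedTuple):
    time: float  # s; NaN when the track never plateaus
    converged: bool


def time_to_iap(track: Track, eps_y: float) -> TimeToIAP:
    """First time after which the track stays within eps_y of its final value."""
    if len(track) < 3:
        raise ValueError("track too short to assess a plateau")
    y_final = track.y[-1]
    dev = np.abs(track.y - y_final)
    outside = np.where(dev >= eps_y)[0]
    if outside.size == 0:
        return TimeToIAP(0.0, True)
    idx = outside[-1] + 1
    if idx >= len(track):  # pragma: no cover - cannot happen (final deviation is 0)
        return TimeToIAP(float("nan"), False)
    if idx == len(track) - 1:
        # only the final sample is settled: no plateau observed
        return TimeToIAP(float("nan"), False)
    return TimeToIAP(float(track.t[idx]), True)


def simulate_population(
    cells,
    field: StandingWaveField,
    profile0: ConcentrationProfile,
    model: MixtureModel,
    t_span: float,
    cfg: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Vectorized migration of a whole population; one row per cell.

    Columns: cell_id, label, y0_m, y_final_m, z_inferred_Pa_s_per_m (the
    medium impedance at the final position in the final-time profile),
    residual_Pa_s_per_m (|z_inferred - z_cell| when z_cell is known),
    censored ("" | "wall" | "center"), error (per-cell integration failure
    message, normally empty).
    """
    cells = list(cells)
    cfg = cfg or SimulationConfig()
    if not cells:
        return pd.DataFrame(
            columns=[
                "cell_id",
                "label",
                "y0_m",
                "y_final_m",
                "z_inferred_Pa_s_per_m",
                "residual_Pa_s_per_m",
                "censored",
                "error",
            ]
        )
    width = field.width
    y0 = np.array([c.y0 if c.y0 is not None else np.nan for c in cells], dtype=float)
    if np.any(np.isnan(y0)) or np.any((y0 <= 0) | (y0 >= width)):
        raise ValueError("every cell needs a start position strictly inside the channel")
    evolver = _SpectralEvolver(profile0)
    arrays = _cell_arrays(cells)
    errors = [""] * len(cells)

    def rhs(t, y):
        return _velocity(y, t, arrays, field, model, evolver, width, False)

    sol = solve_ivp(rhs, (0.0, t_span), y0, rtol=cfg.rtol, atol=cfg.atol)
    if sol.success:
        y_final = np.clip(sol.y[:, -1], 0.0, width)
    else:  # fall back to per-cell integration so one bad cell cannot sink the batch
        y_final = np.full(len(cells), np.nan)
        for i, cell in enumerate(cells):
            try:
                track = migrate(cell, field, profile0, model, t_span, cfg)
                y_final[i] = track.y[-1]
            except Exception as exc:  # pragma: no cover
                errors[i] = str(exc)

    final_vals = evolver.values_at(t_span)
    final_profile = ConcentrationProfile(
        y=profile0.y, values=final_vals, diffusivity=profile0.diffusivity,
        time=profile0.time + t_span,
    )
    z_prof = impedance_profile(final_profile, model)
    c_final = np.interp(y_final, final_profile.y, final_vals)
    z_inferred = np.asarray(model.impedance(c_final), dtype=float)

    eps = cfg.plateau_tol if cfg.plateau_tol is not None else width / 200.0
    censored = np.where(
        (y_final < 2 * eps) | (y_final > width - 2 * eps),
        "wall",
        np.where(np.abs(y_final - width / 2.0) < 2 * eps, "center", ""),
    )
    z_cell = np.array([c.z_cell if c.z_cell is not None else np.nan for c in cells])
    residual = np.abs(z_inferred - z_cell)
    return pd.DataFrame(
        {
            "cell_id": [f"{c.label}_{i}" for i, c in enumerate(cells)],
            "label": [c.label for c in cells],
            "y0_m": y0,
            "y_final_m": y_final,
            "z_inferred_Pa_s_per_m": z_inferred,
            "residual_Pa_s_per_m": residual,
            "censored": censored,
            "error": errors,
        }
    )
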