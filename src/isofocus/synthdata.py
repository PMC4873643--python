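"""Seeded generators for every input the toolkit consumes.

The generators emulate the structure of the experiments: cell populations
with normally distributed effective impedance (truncated to the physical
band), stop-flow trajectory sets mixing positive/negative/zero-contrast
templates, micro-PIV velocity samples, and gradient/background/reference/
cell image sets rendered from a concentration profile.  Every generator is
a pure function of its spec and seed.

Default population parameters follow the measured anchors: a BA-F3-like
line at 1.68 MPa s m^-1 median with 0.014 MPa s m^-1 spread, and an
MCF7-like line with 1.5x the radius and a lower impedance.  Zero-contrast
stop-flow tracks are generated from a toy streaming vortex (a sinusoidal
oscillation about the release position) since streaming, not radiation,
dominates their motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from . import transport
from .acoustics import StandingWaveField, radiation_velocity
from .gradient import ChannelGeometry, ConcentrationProfile, FlowConfig, initial_profile
from .iapread import ImageSet, IntensityCalibration
from .media import AcousticProperties, MixtureModel, ParticleProperties
from .transport import CellModel, SimulationConfig, Track

__all__ = [
    "PopulationSpec",
    "NoiseSpec",
    "BA_F3",
    "MCF7",
    "make_population",
    "make_piv_samples",
    "make_tracks",
    "render_images",
]

Z_PHYSICAL_BAND = (1.2e6, 2.4e6)  # Pa s m^-1, truncation for sampled impedances


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of a cell population."""

    label: str
    z_median: float  # Pa s m^-1
    z_sd: float
    radius_median: float  # m
    radius_sd: float = 0.0
    density: float = 1060.0  # kg m^-3, effective whole-cell value
    n: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0 or self.z_sd < 0 or self.radius_sd < 0:
            raise ValueError("counts and spreads must be non-negative")


# Measured anchors: BA-F3 median 1.68 MPa s m^-1, sd 0.014; MCF7 ~1.5x larger
# in diameter with a lower (not printed) impedance -- 1.63 MPa s m^-1 default.
BA_F3 = PopulationSpec(label="BA-F3", z_median=1.68e6, z_sd=0.014e6, radius_median=4.0e-6)
MCF7 = PopulationSpec(label="MCF7", z_median=1.63e6, z_sd=0.020e6, radius_median=6.0e-6, density=1055.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise levels per signal."""

    position: float = 0.0  # m
    velocity: float = 0.0  # m s^-1
    intensity: float = 0.0  # fraction of the rendering gain

    def __post_init__(self) -> None:
        if min(self.position, self.velocity, self.intensity) < 0:
            raise ValueError("noise sigmas must be non-negative")


def _truncated_normal(rng, median, sd, lo, hi, n):
    if sd == 0:
        return np.full(n, median)
    a, b = (lo - median) / sd, (hi - median) / sd
    dist = sstats.truncnorm(a, b, loc=median, scale=sd)
    return dist.rvs(size=n, random_state=rng)


def make_population(
    spec: PopulationSpec,
    model: MixtureModel | None = None,
    geom: ChannelGeometry | None = None,
    flow: FlowConfig | None = None,
    seed: int | None = None,
    wall_clearance: float = 0.05,
) -> list[CellModel]:
    """Draw a seeded population of cells with side-inlet start positions.

    Impedances and radii are truncated normals; start positions are uniform
    in the two side-inlet bands (outside the central stream), half the cells
    on each side, with a small clearance from the walls.
    """
    model = model or MixtureModel.default()
    geom = geom or ChannelGeometry()
    flow = flow or FlowConfig(total=2.0, central=1.0)  # only the ratio matters here
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    if spec.n == 0:
        return []
    z = _truncated_normal(rng, spec.z_median, spec.z_sd, *Z_PHYSICAL_BAND, spec.n)
    radii = _truncated_normal(
        rng, spec.radius_median, spec.radius_sd, 0.25 * spec.radius_median, 4 * spec.radius_median, spec.n
    )
    w = geom.width
    band_hi = 0.5 * (1.0 - flow.central_fraction) * w  # side band: [0, band_hi]
    lo = wall_clearance * w
    if band_hi <= lo:
        raise ValueError("side-inlet band narrower than the wall clearance")
    y_left = rng.uniform(lo, band_hi, size=spec.n)
    side = rng.integers(0, 2, size=spec.n).astype(bool)
    y0 = np.where(side, w - y_left, y_left)
    return [
        CellModel.from_impedance(
            z_cell=float(z[i]),
            model=model,
            radius=float(radii[i]),
            density=spec.density,
            label=spec.label,
            y0=float(y0[i]),
        )
        for i in range(spec.n)
    ]


def make_piv_samples(
    field: StandingWaveField,
    particle: ParticleProperties,
    medium: AcousticProperties,
    n: int,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    window: tuple[float, float] = (0.05, 0.95),
):
    """(y, u) bead-velocity samples across an interior window of the channel."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    y = rng.uniform(window[0] * field.width, window[1] * field.width, size=n)
    u = np.asarray(radiation_velocity(field, particle, medium, y))
    if noise.velocity > 0:
        u = u + rng.normal(0.0, noise.velocity, size=n)
    return y, u


def _sample_track(track: Track, n_frames: int, frame_rate: float, rng, sigma: float, cell_id: str, true_class: str) -> Track:
    ts = np.arange(n_frames) / frame_rate
    ys = np.interp(ts, track.t, track.y)
    if sigma > 0:
        ys = ys + rng.normal(0.0, sigma, size=n_frames)
    return Track(
        t=ts,
        y=np.clip(ys, 0.0, None),
        frame_rate=frame_rate,
        cell_id=cell_id,
        meta={"true_class": true_class},
    )


def make_tracks(
    counts: dict,
    geom: ChannelGeometry | None = None,
    model: MixtureModel | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    n_frames: int = 30,
    frame_rate: float = 3.0,
    energy_density: float = 43.0,
    cell: CellModel | None = None,
    positive_concentration: float = 10.0,
    negative_concentration: float = 25.0,
    vortex_amplitude: float = 30e-6,
    vortex_period: float = 8.0,
) -> list[Track]:
    """Stop-flow track set with known ground truth.

    ``counts`` maps class names ("positive", "negative", "zero") to track
    counts.  Positive and negative templates are simulated trajectories of a
    BA-F3-like cell in homogeneous low/high-concentration media (where its
    contrast is positive/negative); zero templates follow a toy streaming
    vortex, y(t) = y_c + A sin(2 pi t/T + phase), whose velocity changes sign
    with comparable excursions both ways.  Defaults are 30 frames at 3 Hz,
    matching stop-flow acquisition.  Ground truth is stored in
    ``track.meta["true_class"]``.
    """
    geom = geom or ChannelGeometry()
    model = model or MixtureModel.default()
    rng = np.random.default_rng(seed)
    cell = cell or CellModel.from_impedance(
        BA_F3.z_median, model, radius=BA_F3.radius_median, density=BA_F3.density, label="BA-F3"
    )
    w = geom.width
    field = StandingWaveField.half_wave(width=w, energy_density=energy_density)
    t_span = (n_frames - 1) / frame_rate
    cfg = SimulationConfig(n_samples=max(4 * n_frames, 64))
    flow = FlowConfig(total=2.0, central=1.0)
    tracks: list[Track] = []
    idx = 0
    for cls_name, count in counts.items():
        for _ in range(int(count)):
            cell_id = f"{cls_name}_{idx}"
            idx += 1
            if cls_name == "zero":
                y_c = 0.30 * w
                phase = rng.uniform(0.0, 2.0 * np.pi)
                ts = np.arange(n_frames) / frame_rate
                ys = y_c + vortex_amplitude * np.sin(2.0 * np.pi * ts / vortex_period + phase)
                if noise.position > 0:
                    ys = ys + rng.normal(0.0, noise.position, size=n_frames)
                tracks.append(
                    Track(t=ts, y=np.clip(ys, 0.0, w), frame_rate=frame_rate,
                          cell_id=cell_id, meta={"true_class": "zero"})
                )
                continue
            conc = positive_concentration if cls_name == "positive" else negative_concentration
            profile = initial_profile(flow, geom, c_side=conc, c_center=conc)
            y0 = float(rng.uniform(0.12 * w, 0.38 * w))
            if rng.integers(0, 2):
                y0 = w - y0
            sim = transport.migrate(cell, field, profile, model, t_span, cfg, y0=y0)
            tracks.append(
                _sample_track(sim, n_frames, frame_rate, rng, noise.position, cell_id, cls_name)
            )
    return tracks


def render_images(
    profile: ConcentrationProfile,
    cal: IntensityCalibration,
    cell_positions,
    geom: ChannelGeometry | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    pixel_size: float = 1e-6,
    n_x: int = 128,
    gain: float = 3000.0,
    offset: float = 400.0,
    cell_peak: float = 2000.0,
    psf_sigma: float = 2.0,  # px
    cells_per_frame: int = 6,
) -> ImageSet:
    """Render a synthetic image set consistent with a concentration profile.

    The gradient image maps the tracer ratio r(y) = (c - c_side)/(c_center -
    c_side) affinely to intensity; background and reference images realize
    r = 0 and r = 1.  Cells are Gaussian spots at their transverse positions
    (random x), split over multiple frames.  Intensity noise is additive
    Gaussian with sigma = noise.intensity * gain.
    """
    geom = geom or ChannelGeometry()
    rng = np.random.default_rng(seed)
    n_y = int(round(geom.width / pixel_size))
    rows_y = (np.arange(n_y) + 0.5) * pixel_size
    conc = profile.interpolate(rows_y)
    r = np.clip((conc - cal.c_side) / (cal.c_center - cal.c_side), 0.0, 1.0)

    sigma_i = noise.intensity * gain

    def noisy(base):
        img = base if sigma_i == 0 else base + rng.normal(0.0, sigma_i, size=base.shape)
        return img

    column = offset + gain * r
    gradient = noisy(np.repeat(column[:, None], n_x, axis=1))
    background = noisy(np.full((n_y, n_x), offset))
    reference = noisy(np.full((n_y, n_x), offset + gain))

    cell_positions = np.asarray(list(cell_positions), dtype=float)
    cell_images = []
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    for start in range(0, cell_positions.size, cells_per_frame):
        batch = cell_positions[start : start + cells_per_frame]
        frame = np.full((n_y, n_x), offset, dtype=float)
        for y_m in batch:
            cy = y_m / pixel_size - 0.5
            cx = rng.uniform(4 * psf_sigma, n_x - 4 * psf_sigma)
            frame += cell_peak * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * psf_sigma**2)))
        cell_images.append(noisy(frame))
    return ImageSet(
        gradient=gradient,
        background=background,
        reference=reference,
        cell_images=cell_images,
        pixel_size=pixel_size,
        channel_extent=(0, n_y),
    )
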