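"""Image-based inference of cell iso-acoustic points.

At the downstream imaging region the device alternates between imaging the
fluorescent dextran tracer gradient and the cells.  Gradient images I are
background-subtracted (channel filled with tracer-free side medium) and
normalized against background-subtracted reference images I_max (channel
filled with central medium and tracer) so the ratio r = (I - I_bg) /
(I_max - I_bg) runs from 0 to 1.  Because the tracer intensity is taken as
linear in iodixanol concentration, r maps affinely to concentration,
c = c_side + r (c_center - c_side), and a second-degree calibration
polynomial converts concentration to acoustic impedance.  Reading r at a
detected cell's transverse position assigns the medium impedance at the
cell's iso-acoustic point to the cell itself.

The normalization cancels any global affine gain/offset of the camera,
which is what makes the readout quantitative without absolute intensity
calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import stats
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sklabel, regionprops

from .media import ConversionPolynomial

__all__ = [
    "ImageSet",
    "IntensityCalibration",
    "IAPResult",
    "ColumnProfile",
    "Detection",
    "DetectionParams",
    "PopulationStats",
    "normalize_gradient",
    "column_profile",
    "detect_cells",
    "infer_cell_impedance",
    "population_stats",
]


@dataclass
class ImageSet:
    """Gradient/background/reference/cell images sharing one camera geometry.

    Arrays are 2D with axis 0 = y (across the channel) and axis 1 = x (along
    the flow).  ``channel_extent`` gives the (first, last+1) rows spanned by
    the channel so pixel rows map to physical y.
    """

    gradient: np.ndarray
    background: np.ndarray
    reference: np.ndarray
    cell_images: list = dataclass_field(default_factory=list)
    pixel_size: float = 1e-6  # m per pixel
    channel_extent: tuple[int, int] | None = None  # rows; default full frame

    def __post_init__(self) -> None:
        shape = self.gradient.shape
        for name in ("background", "reference"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} image shape differs from gradient image")
        for img in self.cell_images:
            if img.shape != shape:
                raise ValueError("cell image shape differs from gradient image")
        if self.channel_extent is None:
            self.channel_extent = (0, shape[0])
        if np.mean(self.reference) <= np.mean(self.background):
            raise ValueError("reference image must be brighter than background on average")

    def row_to_y(self, row) -> np.ndarray:
        """Physical y (m) of (possibly fractional) pixel rows, from the channel edge."""
        return (np.asarray(row, dtype=float) - self.channel_extent[0] + 0.5) * self.pixel_size


@dataclass(frozen=True)
class IntensityCalibration:
    """Tracer/iodixanol calibration tying intensity ratio to impedance."""

    polynomial: ConversionPolynomial  # % -> Pa s m^-1
    c_side: float = 10.0  # % iodixanol, side-inlet medium
    c_center: float = 36.0  # % iodixanol, central medium (with tracer)
    tracer_concentration: float = 3.0  # ug ml^-1 dextran, reference condition

    def concentration(self, r):
        """Linear intensity->concentration map, r in [0, 1]."""
        return self.c_side + np.asarray(r) * (self.c_center - self.c_side)

    def impedance(self, r):
        return self.polynomial(self.concentration(r))


def normalize_gradient(images: ImageSet, floor: float | None = None, clip_warn: float = 0.05):
    """Pixelwise ratio field r = (I - I_bg)/(I_max - I_bg), masked and clipped.

    Pixels whose reference-minus-background difference falls below ``floor``
    (default: 10% of the median difference) carry no usable signal and are
    masked.  r is clipped to [0, 1]; a clip rate above ``clip_warn`` raises a
    data-quality warning (it usually indicates drift between the calibration
    and gradient acquisitions).
    """
    num = images.gradient.astype(float) - images.background.astype(float)
    den = images.reference.astype(float) - images.background.astype(float)
    if floor is None:
        floor = 0.1 * float(np.median(den))
    mask = den <= max(floor, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mask, 0.0, num / np.where(mask, 1.0, den))
    clipped = (~mask) & ((r < 0.0) | (r > 1.0))
    clip_rate = float(np.mean(clipped[~mask])) if (~mask).any() else 0.0
    if clip_rate > clip_warn:
        warnings.warn(
            f"{clip_rate:.1%} of ratio pixels clipped to [0, 1]; check background/reference drift",
            stacklevel=2,
        )
    r = np.clip(r, 0.0, 1.0)
    return np.ma.MaskedArray(r, mask=mask)


@dataclass(frozen=True)
class ColumnProfile:
    """Ratio profile r(y) averaged along the flow direction."""

    rows: np.ndarray  # pixel row indices
    values: np.ndarray  # mean r per row; NaN in gaps
    counts: np.ndarray  # unmasked pixels per row
    has_gaps: bool

    def at_row(self, row) -> np.ndarray:
        """Interpolate r at (fractional) rows, skipping gap rows."""
        good = self.counts > 0
        if not good.any():
            raise ValueError("profile is fully masked")
        return np.interp(np.asarray(row, dtype=float), self.rows[good], self.values[good])


def column_profile(r) -> ColumnProfile:
    """Average the ratio field along x, excluding masked pixels per row."""
    r = np.ma.asarray(r)
    counts = (~np.ma.getmaskarray(r)).sum(axis=1)
    means = np.ma.mean(r, axis=1)
    values = np.where(counts > 0, np.ma.filled(means, np.nan), np.nan)
    return ColumnProfile(
        rows=np.arange(r.shape[0]),
        values=values,
        counts=counts,
        has_gaps=bool(np.any(counts == 0)),
    )


@dataclass(frozen=True)
class DetectionParams:
    blur_sigma: float = 2.0  # px
    min_area: int = 4  # px
    max_eccentricity: float = 0.97
    threshold: float | None = None  # absolute; default Otsu on the blurred image
    typical_area: float | None = None  # px; enables merged-spot flagging
    merged_area_factor: float = 1.6


@dataclass(frozen=True)
class Detection:
    y_px: float  # sub-pixel, intensity-weighted
    x_px: float
    total_intensity: float  # background-subtracted sum over the region
    area: int
    merged: bool = False


def detect_cells(image: np.ndarray, params: DetectionParams | None = None) -> list[Detection]:
    """Detect fluorescent cells as bright spots; centroids are sub-pixel.

    Gaussian blur -> global (Otsu) threshold -> connected components ->
    intensity-weighted centroid, with minimum-area and eccentricity filters.
    Two cells closer than the blur scale merge into one region; when a
    typical single-cell area is supplied, oversized regions are flagged
    ``merged`` and a warning is issued.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.max() - img.min() <= 0:
        return []
    blurred = gaussian(img, sigma=params.blur_sigma, preserve_range=True)
    thr = params.threshold if params.threshold is not None else threshold_otsu(blurred)
    mask = blurred > thr
    if not mask.any():
        return []
    labels = sklabel(mask)
    background = float(np.median(img[~mask])) if (~mask).any() else 0.0
    net = np.clip(img - background, 0.0, None)
    detections: list[Detection] = []
    for region in regionprops(labels, intensity_image=net):
        if region.area < params.min_area:
            continue
        if region.eccentricity > params.max_eccentricity:
            continue
        merged = bool(
            params.typical_area is not None
            and region.area > params.merged_area_factor * params.typical_area
        )
        if merged:
            warnings.warn(
                "detected region much larger than a single cell; possible merged detection",
                stacklevel=2,
            )
        cy, cx = region.centroid_weighted
        detections.append(
            Detection(
                y_px=float(cy),
                x_px=float(cx),
                total_intensity=float(region.image_intensity.sum()),
                area=int(region.area),
                merged=merged,
            )
        )
    return detections


@dataclass(frozen=True)
class IAPResult:
    cell_id: str
    y_px: float
    y_m: float
    ratio: float
    concentration: float  # %
    z_cell: float  # Pa s m^-1
    censored: str  # "" | "at wall" | "at center"
    time: float | None = None  # acquisition time, s
    total_intensity: float | None = None


def infer_cell_impedance(
    detection: Detection,
    profile: ColumnProfile,
    cal: IntensityCalibration,
    images: ImageSet,
    cell_id: str = "",
    time: float | None = None,
    wall_margin: float = 0.05,
    center_margin: float = 0.05,
) -> IAPResult:
    """Assign the local medium impedance at a cell's position to the cell.

    A cell sitting within ``wall_margin`` (fraction of the channel width) of
    a wall, or within ``center_margin`` of the centerline, is censored: its
    impedance lies below or above the gradient's measurable span and the
    returned value is only a bound.
    """
    lo, hi = images.channel_extent
    if not (lo <= detection.y_px < hi):
        raise ValueError("cell centroid outside the channel rows")
    if profile.counts[int(round(detection.y_px))] == 0:
        raise ValueError("gradient profile is masked at the cell position")
    r = float(profile.at_row(detection.y_px))
    conc = float(cal.concentration(r))
    z = float(cal.impedance(r))
    width = (hi - lo) * images.pixel_size
    y_m = float(images.row_to_y(detection.y_px))
    censored = ""
    if y_m < wall_margin * width or y_m > (1 - wall_margin) * width:
        censored = "at wall"
    elif abs(y_m - width / 2.0) < center_margin * width:
        censored = "at center"
    return IAPResult(
        cell_id=cell_id,
        y_px=detection.y_px,
        y_m=y_m,
        ratio=r,
        concentration=conc,
        z_cell=z,
        censored=censored,
        time=time,
        total_intensity=detection.total_intensity,
    )


@dataclass(frozen=True)
class PopulationStats:
    """Robust summary of an inferred-impedance population.

    Percentiles use numpy's default linear interpolation between order
    statistics.  When acquisition times are present, a least-squares drift
    regression of impedance on time is reported (slope in Pa s m^-1 per s,
    i.e. Pa m^-1, with its Pearson correlation and 95% CI).
    """

    n: int
    median: float
    p5: float
    p95: float
    sd: float
    drift_slope: float | None = None  # Pa m^-1
    drift_correlation: float | None = None
    drift_slope_ci95: tuple[float, float] | None = None
    empty: bool = False


def population_stats(results) -> PopulationStats:
    """Summarize in-range (non-censored) results; all-censored input is flagged."""
    in_range = [r for r in results if not r.censored]
    if len(in_range) < 2:
        return PopulationStats(
            n=len(in_range),
            median=float("nan"),
            p5=float("nan"),
            p95=float("nan"),
            sd=float("nan"),
            empty=True,
        )
    z = np.array([r.z_cell for r in in_range])
    out = {
        "n": len(in_range),
        "median": float(np.median(z)),
        "p5": float(np.percentile(z, 5)),
        "p95": float(np.percentile(z, 95)),
        "sd": float(np.std(z, ddof=1)),
    }
    times = [r.time for r in in_range]
    if all(t is not None for t in times) and np.ptp(times) > 0:
        t = np.array(times, dtype=float)
        fit = stats.linregress(t, z)
        tval = stats.t.ppf(0.975, len(t) - 2)
        out.update(
            drift_slope=float(fit.slope),
            drift_correlation=float(fit.rvalue),
            drift_slope_ci95=(
                float(fit.slope - tval * fit.stderr),
                float(fit.slope + tval * fit.stderr),
            ),
        )
    return PopulationStats(**out)
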