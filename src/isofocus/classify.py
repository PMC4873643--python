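"""Stop-flow trajectory classification of acoustic contrast.

With the flow stopped and the sound switched on, a cell of positive contrast
migrates to the pressure node at the channel center, a cell of negative
contrast to either wall, and a zero-contrast cell -- dominated by the slow
streaming rotation of the bulk liquid rather than by radiation force --
oscillates without settling.  The classifier applies those rules in strict
priority order on per-track finite-difference velocities:

0. tracks shorter than a minimum frame count are excluded;
1. *zero*: starts away from both the center and the walls, and either the
   velocity changes sign with comparable excursions in both directions
   (weaker directional extreme > 20% of the stronger), or the cell crosses
   the central region without stopping in it;
2. *positive*: not zero, starts away from the center, ends inside the
   central region;
3. *negative*: not zero, starts away from the walls, ends within the wall
   margin;
4. otherwise *unknown*.

The paper's "central region" and "near a wall" are qualitative; here they
are explicit fractions of the channel width, exposed as parameters.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .transport import Track

__all__ = ["ContrastClass", "ClassifierParams", "ClassSummary", "classify_track", "summarize_population"]


class ContrastClass(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    ZERO = "zero"
    UNKNOWN = "unknown"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ClassifierParams:
    width: float  # channel width W, m
    min_track_length: int = 20  # frames
    velocity_ratio_threshold: float = 0.20
    central_halfwidth: float = 0.10  # fraction of W on each side of the centerline
    wall_margin: float = 0.10  # fraction of W
    crossing_speed_fraction: float = 0.10  # "does not stop": exit speed vs track max
    velocity_median_window: int = 5  # frames; 1 disables the robustifying filter
    frame_rate: float | None = None  # Hz, informational

    def __post_init__(self) -> None:
        if self.min_track_length < 2:
            raise ValueError("minimum track length must be at least 2 frames")
        for name in ("velocity_ratio_threshold", "central_halfwidth", "wall_margin"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    def in_central(self, y) -> np.ndarray:
        return np.abs(np.asarray(y) - self.width / 2.0) <= self.central_halfwidth * self.width

    def near_wall(self, y) -> np.ndarray:
        y = np.asarray(y)
        m = self.wall_margin * self.width
        return (y <= m) | (y >= self.width - m)


def _oscillation_rule(v: np.ndarray, threshold: float) -> bool:
    """Sign-changing velocity with comparable excursions in both directions."""
    v_pos = float(np.max(v))
    v_neg = float(np.min(v))
    if not (v_pos > 0 and v_neg < 0):
        return False
    weaker, stronger = sorted([v_pos, -v_neg])
    return stronger > 0 and weaker / stronger > threshold


def _crossing_rule(y: np.ndarray, v: np.ndarray, params: ClassifierParams) -> bool:
    """Enters and leaves the central region still moving (no stop at the node)."""
    inside = params.in_central(y)
    if not inside.any() or inside[0] or inside[-1]:
        return False
    vmax = float(np.max(np.abs(v)))
    if vmax == 0:
        return False
    exits = np.where(inside[:-1] & ~inside[1:])[0] + 1
    return any(abs(v[i]) > params.crossing_speed_fraction * vmax for i in exits)


def classify_track(track: Track, params: ClassifierParams) -> ContrastClass:
    """Assign a contrast class to one stop-flow track."""
    if np.any(np.diff(track.t) <= 0):  # Track enforces this, but re-check raw inputs
        raise ValueError("track timestamps must be strictly increasing")
    if len(track) < params.min_track_length:
        return ContrastClass.EXCLUDED
    y = np.asarray(track.y, dtype=float)
    if np.any((y < 0) | (y > params.width)):
        raise ValueError("track positions outside the channel")
    v = track.velocities()
    trim = 0
    if params.velocity_median_window > 1:
        # single-frame tracking jitter must not masquerade as flow reversal;
        # genuine streaming oscillations span many consecutive frames
        v = median_filter(v, size=params.velocity_median_window, mode="nearest")
        # the one-sided endpoint estimates carry twice the noise and the
        # filter spreads them one half-width inward; keep them out of the
        # reversal test
        trim = params.velocity_median_window // 2
    v_interior = v[trim : len(v) - trim] if trim and len(v) > 2 * trim + 2 else v

    starts_away_center = not bool(params.in_central(y[0]))
    starts_away_wall = not bool(params.near_wall(y[0]))

    if starts_away_center and starts_away_wall:
        if _oscillation_rule(v_interior, params.velocity_ratio_threshold) or _crossing_rule(y, v, params):
            return ContrastClass.ZERO
    if starts_away_center and bool(params.in_central(y[-1])):
        return ContrastClass.POSITIVE
    if starts_away_wall and bool(params.near_wall(y[-1])):
        return ContrastClass.NEGATIVE
    return ContrastClass.UNKNOWN


@dataclass(frozen=True)
class ClassSummary:
    counts: dict  # ContrastClass -> int (includes EXCLUDED)
    fractions: dict  # class value -> fraction of non-excluded tracks
    n_analyzed: int
    empty: bool

    def to_dict(self) -> dict:
        return {
            "n_analyzed": self.n_analyzed,
            "counts": {k.value: v for k, v in self.counts.items()},
            "fractions": dict(self.fractions),
            "empty": self.empty,
        }


def summarize_population(tracks, params: ClassifierParams) -> ClassSummary:
    """Class counts and fractions over a set of tracks.

    Fractions are computed over non-excluded tracks and sum to one; an
    all-excluded input is flagged empty.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    counts = Counter(classify_track(t, params) for t in tracks)
    n_analyzed = sum(v for k, v in counts.items() if k is not ContrastClass.EXCLUDED)
    if n_analyzed == 0:
        return ClassSummary(counts=dict(counts), fractions={}, n_analyzed=0, empty=True)
    fractions = {
        k.value: counts.get(k, 0) / n_analyzed
        for k in (ContrastClass.POSITIVE, ContrastClass.NEGATIVE, ContrastClass.ZERO, ContrastClass.UNKNOWN)
    }
    return ClassSummary(counts=dict(counts), fractions=fractions, n_analyzed=n_analyzed, empty=False)
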