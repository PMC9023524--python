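"""Striation periodicity and two-channel spatial colocalization.

Intensity profiles are sampled along a user-placed line (bilinear
interpolation, averaged across a sampling width).  Periodicity is read from
the first autocorrelation peak beyond 0.5 um with prominence > 0.1 -- the
autocorrelation is preferred over an FFT argmax for the short profiles
typical of single cells.  Colocalization is Pearson correlation of two
profiles on the same grid plus the lag maximizing their normalized
cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .io import FluorescenceImage

MIN_PERIOD_LAG_UM = 0.5
PROMINENCE_THRESHOLD = 0.1


@dataclass
class SpatialProfile:
    positions_um: np.ndarray
    values: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_um.size < 16:
            raise ValueError("profile needs at least 16 samples")
        steps = np.diff(self.positions_um)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("positions must be uniformly increasing")

    @property
    def step_um(self) -> float:
        return float(self.positions_um[1] - self.positions_um[0])


@dataclass
class PeriodicityResult:
    period_um: float | None
    peak_prominence: float
    is_striated: bool


@dataclass
class ColocalizationResult:
    pearson_r: float | None
    best_lag_um: float | None
    qc_flags: list[str] = field(default_factory=list)


def spatial_profile(image: FluorescenceImage, p0: tuple[float, float],
                    p1: tuple[float, float], width_um: float = 1.0,
                    channel_label: str | None = None) -> SpatialProfile:
    """Mean-intensity profile along the line p0 -> p1 (physical um coords).

    Sampled at pixel_size steps via bilinear interpolation, averaged across
    ``width_um`` perpendicular to the line.
    """
    px = image.pixel_size_um
    h, w = image.shape
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= w * px and 0 <= p[1] <= h * px):
            raise ValueError("line endpoint outside the image")
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("zero-length profile line")
    u = d / length
    perp = np.array([-u[1], u[0]])

    n = int(length / px) + 1
    s = np.arange(n) * px
    n_off = max(int(round(width_um / px)), 1)
    offsets = (np.arange(n_off) - (n_off - 1) / 2.0) * px

    img = np.asarray(image.pixels, dtype=float)
    vals = np.zeros(n)
    for off in offsets:
        pts = p0[None, :] + s[:, None] * u[None, :] + off * perp[None, :]
        rows = pts[:, 1] / px - 0.5  # pixel-center convention
        cols = pts[:, 0] / px - 0.5
        vals += map_coordinates(img, [rows, cols], order=1, mode="nearest")
    vals /= n_off
    return SpatialProfile(positions_um=s, values=vals,
                          channel_label=channel_label or image.channel_label)


def detect_period(profile: SpatialProfile,
                  min_lag_um: float = MIN_PERIOD_LAG_UM,
                  prominence: float = PROMINENCE_THRESHOLD,
                  min_height: float = 0.2) -> PeriodicityResult:
    """Striation period from the first prominent autocorrelation peak.

    The minimum lag of 0.5 um excludes the PSF-induced zero-lag shoulder.
    Besides prominence > 0.1 the peak must reach an autocorrelation of
    ``min_height``: on finite white-noise profiles chance peaks routinely
    clear the prominence bar alone, while genuine striations correlate far
    above 0.2 period-to-period.
    """
    x = profile.values - profile.values.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return PeriodicityResult(period_um=None, peak_prominence=0.0, is_striated=False)
    acf = np.correlate(x, x, mode="full")[x.size - 1:] / denom
    peaks, props = find_peaks(acf, prominence=prominence)
    step = profile.step_um
    min_idx = int(np.ceil(min_lag_um / step))
    for p, prom in zip(peaks, props["prominences"]):
        if p >= min_idx and acf[p] >= min_height:
            return PeriodicityResult(period_um=float(p * step),
                                     peak_prominence=float(prom),
                                     is_striated=True)
    return PeriodicityResult(period_um=None, peak_prominence=0.0, is_striated=False)


def colocalize(profile_a: SpatialProfile, profile_b: SpatialProfile
               ) -> ColocalizationResult:
    """Pearson correlation and best cross-correlation lag of two profiles."""
    if profile_a.positions_um.shape != profile_b.positions_um.shape or \
            not np.allclose(profile_a.positions_um, profile_b.positions_um):
        raise ValueError("profiles must share the same sampling grid")
    a = profile_a.values.astype(float)
    b = profile_b.values.astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ColocalizationResult(pearson_r=None, best_lag_um=None,
                                    qc_flags=["constant_profile"])
    r = float(np.corrcoef(a, b)[0, 1])

    step = profile_a.step_um
    period = detect_period(profile_a).period_um
    max_lag = int(round((period if period else a.size * step / 4.0) / step))
    max_lag = min(max(max_lag, 1), a.size - 2)
    best_lag, best_c = 0, -np.inf
    # ties (e.g. perfectly periodic profiles) resolve to the smallest |lag|
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            aa, bb = a[lag:], b[:b.size - lag]
        else:
            aa, bb = a[:a.size + lag], b[-lag:]
        if aa.size < 3 or np.ptp(aa) == 0 or np.ptp(bb) == 0:
            continue
        c = float(np.corrcoef(aa, bb)[0, 1])
        if c > best_c:
            best_c, best_lag = c, lag
    return ColocalizationResult(pearson_r=r, best_lag_um=best_lag * step)
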