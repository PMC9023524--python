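"""Synthetic striated T-tubule network images.

The generator lays down an idealised tubule skeleton -- transverse elements
on a ~2 um lattice perpendicular to the cell long axis (the image x-axis by
construction) plus sparse longitudinal connectors -- then renders it through
a Gaussian PSF with Poisson photon noise.  Ground-truth transverse and
longitudinal skeleton lengths are book-kept from the geometric segments
before rasterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line

from ..io import FluorescenceImage

# transverse tubules are generated as chains of ~1 um elements so that
# dropout acts per unit length, as in patchy tubule loss
_ELEMENT_UM = 1.0


@dataclass(frozen=True)
class TTSimConfig:
    image_size_um: tuple[float, float] = (40.0, 20.0)  # (width, height)
    pixel_size_um: float = 0.1
    striation_period_um: float = 2.0
    transverse_dropout: float = 0.0
    longitudinal_density: float = 0.0  # expected longitudinal length (um) per um^2
    jitter_um: float = 0.05
    psf_sigma_um: float = 0.15
    photons_peak: float = 100.0
    background_photons: float = 10.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.striation_period_um <= 0:
            raise ValueError("striation_period_um must be positive")
        if not 0.0 <= self.transverse_dropout <= 1.0:
            raise ValueError("transverse_dropout must be in [0, 1]")
        if self.longitudinal_density < 0 or self.jitter_um < 0:
            raise ValueError("densities and jitter must be non-negative")
        if self.psf_sigma_um < 0 or self.photons_peak <= 0 or self.background_photons < 0:
            raise ValueError("invalid optics/photon parameters")


@dataclass
class TTGroundTruth:
    transverse_length_um: float
    longitudinal_length_um: float
    true_transverse_fraction: float
    true_longitudinal_fraction: float
    # (x0, y0, x1, y1, class) in um; the bookkeeping oracle re-sums these
    segments: list[tuple[float, float, float, float, str]] = field(default_factory=list)


def _generate_segments(config: TTSimConfig, rng: np.random.Generator
                       ) -> list[tuple[float, float, float, float, str]]:
    width, height = config.image_size_um
    period = config.striation_period_um
    segments: list[tuple[float, float, float, float, str]] = []

    # transverse loci at period/2 + k*period, jittered in x, axis-aligned
    x = period / 2.0
    loci = []
    while x < width:
        loci.append(x)
        x += period
    for x0 in loci:
        xj = x0 + (rng.normal(0.0, config.jitter_um) if config.jitter_um > 0 else 0.0)
        xj = float(np.clip(xj, 0.0, width - 1e-9))
        y = 0.0
        while y < height - 1e-9:
            y1 = min(y + _ELEMENT_UM, height)
            if rng.random() >= config.transverse_dropout:
                segments.append((xj, y, xj, y1, "transverse"))
            y = y1

    # longitudinal connectors: Poisson count of fixed-length axial segments
    seg_len = min(period, width)
    lam = config.longitudinal_density * width * height / seg_len
    n_long = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n_long):
        x0 = rng.uniform(0.0, width - seg_len)
        y0 = rng.uniform(0.0, height)
        segments.append((x0, y0, x0 + seg_len, y0, "longitudinal"))
    return segments


def _rasterize(segments, config: TTSimConfig) -> np.ndarray:
    width, height = config.image_size_um
    p = config.pixel_size_um
    ncols = int(round(width / p))
    nrows = int(round(height / p))
    canvas = np.zeros((nrows, ncols), dtype=float)

    def to_idx(x: float, y: float) -> tuple[int, int]:
        # pixel center at (i + 0.5) * p
        c = int(np.clip(np.floor(x / p), 0, ncols - 1))
        r = int(np.clip(np.floor(y / p), 0, nrows - 1))
        return r, c

    for x0, y0, x1, y1, _cls in segments:
        r0, c0 = to_idx(x0, y0)
        r1, c1 = to_idx(x1, y1)
        rr, cc = draw_line(r0, c0, r1, c1)
        canvas[rr, cc] = 1.0
    return canvas


def make_ttubule_image(config: TTSimConfig, seed: int
                       ) -> tuple[FluorescenceImage, TTGroundTruth]:
    """Render a synthetic T-tubule image and its geometric ground truth.

    RNG sub-streams are split in the order geometry -> noise so the segment
    list can be replayed independently of the rendering noise.
    """
    width, height = config.image_size_um
    if width < config.striation_period_um or height < config.striation_period_um:
        raise ValueError("image must span at least one striation period in each axis")

    ss = np.random.SeedSequence(seed)
    s_geom, s_noise = ss.spawn(2)
    rng_geom = np.random.default_rng(s_geom)
    rng_noise = np.random.default_rng(s_noise)

    segments = _generate_segments(config, rng_geom)
    t_len = sum(abs(s[3] - s[1]) + abs(s[2] - s[0])
                for s in segments if s[4] == "transverse")
    l_len = sum(abs(s[3] - s[1]) + abs(s[2] - s[0])
                for s in segments if s[4] == "longitudinal")
    total = t_len + l_len
    truth = TTGroundTruth(
        transverse_length_um=t_len,
        longitudinal_length_um=l_len,
        true_transverse_fraction=(t_len / total) if total > 0 else 0.0,
        true_longitudinal_fraction=(l_len / total) if total > 0 else 0.0,
        segments=segments,
    )

    canvas = _rasterize(segments, config)
    sigma_px = config.psf_sigma_um / config.pixel_size_um
    blurred = gaussian_filter(canvas, sigma_px) if sigma_px > 0 else canvas
    peak = blurred.max()
    signal = np.full_like(blurred, config.background_photons)
    if peak > 0:
        # scale so the brightest tubule pixel averages photons_peak counts
        signal += (config.photons_peak - config.background_photons) * blurred / peak
    noisy = rng_noise.poisson(np.clip(signal, 0, None)).astype(np.uint16)
    image = FluorescenceImage(pixels=noisy, pixel_size_um=config.pixel_size_um,
                              channel_label="ttubule")
    return image, truth
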