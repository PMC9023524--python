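"""Transverse / longitudinal T-tubule fraction analysis.

Pipeline: estimate the cell long axis from the striation peak of the 2-D
power spectrum, segment tubules (top-hat background subtraction + Otsu),
skeletonize, break the skeleton at branch points, classify each segment by
the angle of its principal axis relative to the cell long axis (> 45 deg =
transverse, ties transverse), and report length-weighted fractions.

Angle convention: orientations are measured in (row, col) array coordinates
as atan2(d_row, d_col), reduced modulo 180 deg; the same convention is used
for the spectral axis estimate and for skeleton segments, so relative
angles are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, remove_small_objects, skeletonize, white_tophat

from .io import FluorescenceImage

DEFAULT_ANGLE_THRESHOLD_DEG = 45.0
MIN_SEGMENT_PIXELS = 3


@dataclass
class SkeletonSegment:
    coords: np.ndarray          # (n, 2) pixel (row, col)
    length_um: float
    angle_deg: float            # relative to cell long axis, in [0, 90]
    cls: str                    # "transverse" | "longitudinal"


@dataclass
class TTubuleSkeleton:
    segments: list[SkeletonSegment] = field(default_factory=list)
    cell_axis_deg: float = 0.0


@dataclass
class TTubuleMetrics:
    transverse_fraction: float
    longitudinal_fraction: float
    total_skeleton_length_um: float
    cell_axis_deg: float
    qc_flags: list[str] = field(default_factory=list)


def _spectral_peak(image: FluorescenceImage, min_period_um: float = 1.0,
                   max_period_um: float = 4.0):
    """Dominant periodic component of the image: (angle_deg, period_um, peak ratio).

    The power spectrum is Hann-windowed and lightly smoothed; the peak is
    searched in an annulus of physically plausible striation frequencies and
    scored against the median power in that band.
    """
    img = np.asarray(image.pixels, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("no structure: constant image")
    win = np.outer(np.hanning(img.shape[0]), np.hanning(img.shape[1]))
    f = np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))
    power = ndimage.gaussian_filter(np.abs(f) ** 2, 1.0)
    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0], d=image.pixel_size_um))
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1], d=image.pixel_size_um))
    # the search band covers physiological sarcomere repeats (~1-4 um);
    # outside it low-frequency cell-shape power dominates disrupted images
    fr = np.hypot(fy[:, None], fx[None, :])
    band = (fr >= 1.0 / max_period_um) & (fr <= 1.0 / min_period_um)
    if not band.any():
        raise ValueError("no structure: image smaller than one striation period")
    band_power = np.where(band, power, 0.0)
    r, c = np.unravel_index(int(np.argmax(band_power)), power.shape)
    ratio = power[r, c] / max(np.median(power[band]), 1e-300)
    angle = np.degrees(np.arctan2(fy[r], fx[c])) % 180.0
    period = 1.0 / fr[r, c]
    return angle, period, ratio


def estimate_cell_axis(image: FluorescenceImage, min_peak_ratio: float = 10.0) -> float:
    """Cell long-axis orientation (deg, [0, 180)) from the striation spectrum.

    The dominant spectral peak's frequency vector points along the striation
    repeat direction, i.e. along the cell long axis for a striated myocyte.
    """
    angle, _period, ratio = _spectral_peak(image)
    if ratio < min_peak_ratio:
        raise ValueError("no structure: no dominant periodic component")
    return angle


def estimate_striation_period(image: FluorescenceImage) -> float:
    """Striation period estimate (um) from the same spectral peak."""
    _angle, period, _ratio = _spectral_peak(image)
    return period


def segment_ttubules(image: FluorescenceImage, period_um: float | None = None,
                     tophat_factor: float = 1.5, min_area_um2: float = 0.2
                     ) -> tuple[np.ndarray, list[str]]:
    """Binary tubule mask via top-hat background subtraction + Otsu.

    Structuring-element radius = tophat_factor x striation period estimate.
    Returns the mask and QC flags ('empty_mask', 'mask_area_gt_60pct').
    """
    img = np.asarray(image.pixels, dtype=float)
    qc: list[str] = []
    if period_um is None:
        try:
            period_um = estimate_striation_period(image)
        except ValueError:
            period_um = 2.0
    radius_px = max(int(round(tophat_factor * period_um / image.pixel_size_um)), 1)
    radius_px = min(radius_px, min(img.shape) // 2)  # never exceed image scale
    th = white_tophat(img, footprint=disk(radius_px))
    if np.ptp(th) == 0:
        return np.zeros_like(img, dtype=bool), ["empty_mask"]
    mask = th > threshold_otsu(th)
    min_px = max(int(round(min_area_um2 / image.pixel_size_um ** 2)), 1)
    mask = remove_small_objects(mask, max_size=min_px - 1)
    if not mask.any():
        qc.append("empty_mask")
    elif mask.mean() > 0.6:
        qc.append("mask_area_gt_60pct")
    return mask, qc


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _trace_length_um(coords: np.ndarray, pixel_size_um: float) -> float:
    """Sum of inter-pixel step lengths (1 or sqrt(2)) along a skeleton path."""
    cset = {tuple(c) for c in coords}
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {c: [] for c in cset}
    for (r, c) in cset:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in cset:
                    adj[(r, c)].append((r + dr, c + dc))
    ends = [c for c, nb in adj.items() if len(nb) <= 1]
    start = ends[0] if ends else next(iter(cset))
    visited = {start}
    length = 0.0
    cur = start
    while True:
        nxt = [n for n in adj[cur] if n not in visited]
        if not nxt:
            break
        # prefer 4-connected steps to avoid double-counting corner pixels
        nxt.sort(key=lambda n: abs(n[0] - cur[0]) + abs(n[1] - cur[1]))
        n = nxt[0]
        length += np.hypot(n[0] - cur[0], n[1] - cur[1])
        visited.add(n)
        cur = n
    # unvisited leftovers (rare side spurs within a segment) add their steps
    for c in cset - visited:
        length += 1.0
    return length * pixel_size_um


def _segment_angle_deg(coords: np.ndarray) -> float:
    """Orientation of the segment's principal axis, array convention, [0, 180)."""
    xy = coords.astype(float)
    xy -= xy.mean(axis=0)
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]  # (d_row, d_col)
    return float(np.degrees(np.arctan2(v[0], v[1])) % 180.0)


def skeletonize_and_classify(mask: np.ndarray, cell_axis_deg: float,
                             pixel_size_um: float,
                             angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
                             min_pixels: int = MIN_SEGMENT_PIXELS) -> TTubuleSkeleton:
    """Skeletonize a tubule mask and classify segments by orientation.

    The skeleton is broken at branch points (pixels with > 2 neighbours);
    remaining 8-connected components are simple paths.  A segment is
    transverse when its angle to the cell long axis is >= the threshold
    (exact ties are transverse); segments shorter than ``min_pixels`` are
    discarded as PSF-scale spurs.
    """
    skel = skeletonize(mask.astype(bool))
    if not skel.any():
        return TTubuleSkeleton(segments=[], cell_axis_deg=cell_axis_deg)
    nb = ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL,
                          mode="constant", cval=0)
    branch = skel & (nb > 2)
    branch_set = {tuple(c) for c in np.argwhere(branch)}
    labels = label(skel & ~branch, connectivity=2)
    segments: list[SkeletonSegment] = []
    for idx in range(1, labels.max() + 1):
        coords = np.argwhere(labels == idx)
        if len(coords) < min_pixels:
            continue
        length = _trace_length_um(coords, pixel_size_um)
        # restore the step into each removed branch pixel: cutting a crossing
        # costs every arm exactly one step, so each (segment pixel, adjacent
        # branch pixel) pair adds its step length back
        cset = {tuple(c) for c in coords}
        for (r, c) in cset:
            for (br, bc) in branch_set:
                if abs(br - r) <= 1 and abs(bc - c) <= 1:
                    length += np.hypot(br - r, bc - c) * pixel_size_um
        # half-pixel end caps at free endpoints: a path of n pixels spans
        # n * pixel_size of physical length, not (n - 1) steps
        for (r, c) in cset:
            deg = sum((r + dr, c + dc) in cset
                      for dr in (-1, 0, 1) for dc in (-1, 0, 1) if dr or dc)
            near_branch = any(abs(br - r) <= 1 and abs(bc - c) <= 1
                              for (br, bc) in branch_set)
            if deg <= 1 and not near_branch:
                length += 0.5 * pixel_size_um
        ang = _segment_angle_deg(coords)
        rel = abs(ang - cell_axis_deg) % 180.0
        rel = min(rel, 180.0 - rel)
        cls = "transverse" if rel >= angle_threshold_deg else "longitudinal"
        segments.append(SkeletonSegment(
            coords=coords,
            length_um=length,
            angle_deg=rel,
            cls=cls,
        ))
    return TTubuleSkeleton(segments=segments, cell_axis_deg=cell_axis_deg)


def compute_tt_fractions(skeleton: TTubuleSkeleton,
                         qc_flags: list[str] | None = None) -> TTubuleMetrics:
    """Length-weighted transverse / longitudinal fractions of a skeleton."""
    qc = list(qc_flags or [])
    t_len = sum(s.length_um for s in skeleton.segments if s.cls == "transverse")
    l_len = sum(s.length_um for s in skeleton.segments if s.cls == "longitudinal")
    total = t_len + l_len
    if total <= 0:
        qc.append("empty_skeleton")
        return TTubuleMetrics(0.0, 0.0, 0.0, skeleton.cell_axis_deg, qc)
    return TTubuleMetrics(
        transverse_fraction=t_len / total,
        longitudinal_fraction=l_len / total,
        total_skeleton_length_um=total,
        cell_axis_deg=skeleton.cell_axis_deg,
        qc_flags=qc,
    )


def analyze_ttubule_image(image: FluorescenceImage, axis_deg: float | None = None,
                          angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
                          period_um: float | None = None) -> TTubuleMetrics:
    """Full analysis of one image: axis -> mask -> skeleton -> fractions."""
    if axis_deg is None:
        axis_deg = estimate_cell_axis(image)
    mask, qc = segment_ttubules(image, period_um=period_um)
    skel = skeletonize_and_classify(mask, axis_deg, image.pixel_size_um,
                                    angle_threshold_deg=angle_threshold_deg)
    return compute_tt_fractions(skel, qc_flags=qc)
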