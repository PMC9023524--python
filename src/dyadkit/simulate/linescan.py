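"""Synthetic Ca2+ line-scan kymographs with dyad-site ground truth.

Models a confocal line scan across a paced cardiomyocyte expressing a
dyad-localised Ca2+ sensor: dyad sites on a ~2 um lattice, evoked release
drawn Bernoulli(p_couple) per site per stimulus, spontaneous sparks as a
per-site Poisson process, optional caffeine episode for SR-content
estimation.  The rendered field is F0 * (1 + dF/F0) with Poisson photon
noise; every event and the full site x stimulus activation matrix are
logged as ground truth.

Spark kernel: amplitude * exp(-(x-x0)^2 / 2 sigma_x^2) * g(t), with g a
linear rise over spark_rise_ms followed by exponential decay with
tau = spark_decay_ms, so the kernel peak equals the configured dF/F0
amplitude in closed form.

Evoked release at a site is rendered as a raised-cosine bump of support
equal to dyad_spacing centred on the site (neighbouring supports tile the
scan line without overlap), scaled so that the spatial-mean dF/F0 peak under
full activation equals transient_amplitude_dff exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..io import LineScanKymograph

_EVOKED_LATENCY_MS = 5.0  # fixed E-C coupling latency after field stimulus


@dataclass(frozen=True)
class ScanSimConfig:
    scan_length_um: float = 40.0
    pixel_size_um: float = 0.1
    line_interval_ms: float = 3.78
    duration_s: float = 10.0
    dyad_spacing_um: float = 2.0
    pacing_hz: float = 1.0          # 0 disables pacing
    p_couple: float = 1.0
    spark_rate_per_site_per_s: float = 0.0
    spark_amplitude_dff: float = 1.0
    spark_fwhm_um: float = 2.0
    spark_rise_ms: float = 8.0
    spark_decay_ms: float = 30.0
    transient_amplitude_dff: float = 2.0
    transient_rise_ms: float = 15.0
    transient_decay_ms: float = 150.0
    f0_counts: float = 100.0
    caffeine_mode: bool = False
    caffeine_time_s: float = 5.0
    caffeine_depletion_frac: float = 0.4  # fractional signal drop at store_scale 1
    caffeine_rise_s: float = 0.3
    store_scale: float = 1.0        # relative SR content, 1.0 = reference

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_couple <= 1.0:
            raise ValueError("p_couple must be in [0, 1]")
        if self.line_interval_ms <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibration parameters must be positive")
        if self.spark_rate_per_site_per_s < 0 or self.pacing_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.store_scale <= 0:
            raise ValueError("store_scale must be positive")
        if self.f0_counts <= 0 or self.duration_s <= 0 or self.scan_length_um <= 0:
            raise ValueError("invalid scan geometry/photon parameters")
        if not 0.0 <= self.caffeine_depletion_frac < 1.0:
            raise ValueError("caffeine_depletion_frac must be in [0, 1)")


@dataclass
class ScanGroundTruth:
    site_positions_um: list[float]
    spark_events: list[tuple[float, float, float]]  # (position_um, time_s, amplitude_dff)
    pacing_times_s: list[float]
    activation_matrix: np.ndarray  # (n_sites, n_stimuli) bool
    store_scale: float
    f0_counts: float = 100.0


def _site_positions(config: ScanSimConfig) -> np.ndarray:
    s = config.dyad_spacing_um
    pos = np.arange(s / 2.0, config.scan_length_um, s)
    return pos


def _pacing_times(config: ScanSimConfig) -> list[float]:
    if config.pacing_hz <= 0:
        return []
    period = 1.0 / config.pacing_hz
    t = 0.5  # settle time before the first stimulus
    out = []
    stop = config.caffeine_time_s if config.caffeine_mode else config.duration_s
    while t < stop:
        out.append(round(t, 9))
        t += period
    return out


def _temporal_kernel(times_s: np.ndarray, t0_s: float, rise_ms: float,
                     decay_ms: float) -> np.ndarray:
    dt = (times_s - t0_s) * 1000.0  # ms
    g = np.zeros_like(dt)
    rise = np.maximum(rise_ms, 1e-9)
    up = (dt >= 0) & (dt < rise)
    g[up] = dt[up] / rise
    down = dt >= rise
    g[down] = np.exp(-(dt[down] - rise) / decay_ms)
    return g


def _cosine_bump(x_um: np.ndarray, x0: float, halfwidth: float) -> np.ndarray:
    d = np.abs(x_um - x0)
    out = np.zeros_like(x_um)
    inside = d < halfwidth
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / halfwidth))
    return out


def make_linescan(config: ScanSimConfig, seed: int
                  ) -> tuple[LineScanKymograph, ScanGroundTruth]:
    """Render a kymograph and its event-level ground truth.

    RNG sub-streams are split in the order geometry -> events -> noise; within
    the event stream the draw order is (activation matrix, per-site spark
    counts, per-site spark times), so replay oracles are possible.
    """
    ss = np.random.SeedSequence(seed)
    s_geom, s_events, s_noise = ss.spawn(3)
    _rng_geom = np.random.default_rng(s_geom)  # reserved; site lattice is deterministic
    rng_events = np.random.default_rng(s_events)
    rng_noise = np.random.default_rng(s_noise)

    sites = _site_positions(config)
    pacing = _pacing_times(config)
    n_sites, n_stim = len(sites), len(pacing)

    if config.pacing_hz > 0 and 1000.0 / config.pacing_hz < (
            config.spark_rise_ms + config.spark_decay_ms):
        warnings.warn("pacing period is shorter than the spark decay window; "
                      "evoked responses will overlap", stacklevel=2)

    x = (np.arange(int(round(config.scan_length_um / config.pixel_size_um))) + 0.5) \
        * config.pixel_size_um
    t = (np.arange(int(round(config.duration_s * 1000.0 / config.line_interval_ms)))
         + 0.5) * config.line_interval_ms / 1000.0

    activation = rng_events.random((n_sites, n_stim)) < config.p_couple \
        if n_sites * n_stim else np.zeros((n_sites, n_stim), dtype=bool)

    spark_counts = rng_events.poisson(
        config.spark_rate_per_site_per_s * config.duration_s, size=n_sites) \
        if n_sites else np.zeros(0, dtype=int)
    spark_events: list[tuple[float, float, float]] = []
    for i, pos in enumerate(sites):
        for ts in np.sort(rng_events.uniform(0.0, config.duration_s, size=spark_counts[i])):
            spark_events.append((float(pos), float(ts), config.spark_amplitude_dff))

    dff = np.zeros((x.size, t.size), dtype=float)

    if config.caffeine_mode:
        # SR-trapped low-affinity dye readout: caffeine empties the store and
        # the signal *drops* by depletion_frac * store_scale; cytosolic spark
        # and transient signal is not reported by the luminal dye.
        drop = config.caffeine_depletion_frac * config.store_scale
        h = np.zeros_like(t)
        after = t >= config.caffeine_time_s
        h[after] = 1.0 - np.exp(-(t[after] - config.caffeine_time_s) / config.caffeine_rise_s)
        dff -= drop * h[None, :]
    else:
        # evoked dyadic release
        amp_site = 2.0 * config.transient_amplitude_dff  # bump spatial mean = 1/2
        for j, tp in enumerate(pacing):
            g = _temporal_kernel(t, tp + _EVOKED_LATENCY_MS / 1000.0,
                                 config.transient_rise_ms, config.transient_decay_ms)
            cols = np.nonzero(g > 1e-4)[0]
            if cols.size == 0:
                continue
            for i, pos in enumerate(sites):
                if activation[i, j]:
                    bump = _cosine_bump(x, pos, config.dyad_spacing_um / 2.0)
                    dff[:, cols] += amp_site * bump[:, None] * g[None, cols]
        # spontaneous sparks
        sigma_x = config.spark_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        for pos, ts, amp in spark_events:
            g = _temporal_kernel(t, ts, config.spark_rise_ms, config.spark_decay_ms)
            cols = np.nonzero(g > 1e-4)[0]
            if cols.size == 0:
                continue
            prof = np.exp(-((x - pos) ** 2) / (2.0 * sigma_x ** 2))
            dff[:, cols] += amp * prof[:, None] * g[None, cols]

    f = config.f0_counts * (1.0 + dff)
    noisy = rng_noise.poisson(np.clip(f, 0.0, None)).astype(np.uint16)

    kymo = LineScanKymograph(
        pixels=noisy,
        pixel_size_um=config.pixel_size_um,
        line_interval_ms=config.line_interval_ms,
        pacing_times_s=list(pacing),
        dye_label="Fluo5N" if config.caffeine_mode else "ASPH-G6f",
        caffeine_time_s=config.caffeine_time_s if config.caffeine_mode else None,
    )
    truth = ScanGroundTruth(
        site_positions_um=[float(p) for p in sites],
        spark_events=spark_events,
        pacing_times_s=list(pacing),
        activation_matrix=activation,
        store_scale=config.store_scale,
        f0_counts=config.f0_counts,
    )
    return kymo, truth
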