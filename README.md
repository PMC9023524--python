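# dyadkit

Quantification toolkit for cardiac **dyad** architecture and function — the
nanodomains where transverse (T-) tubules appose junctional sarcoplasmic
reticulum (jSR) and excitation–contraction coupling happens. It is written
for cell physiologists and imaging scientists who need the measurements
behind a dyad-disruption phenotype to be reproducible: given fluorescence
images, Ca²⁺ line-scan kymographs, traced electron-microscopy contours, or
BioID proximity-proteomics intensity tables, it produces the standard
readouts, and it ships a synthetic-data generator with exact ground truth
so every readout can be validated end to end.

## What it measures

| Modality | Readout |
|---|---|
| Confocal T-tubule image | transverse / longitudinal skeleton-length fractions, cell axis, striation period |
| Ca²⁺ line scan (space × time) | F₀ baseline, ΔF/F₀, spark detection (amplitude, FWHM, duration), spark frequency per 100 µm·s, evoked transient amplitude, caffeine-based SR-content estimate, per-dyad coupling fidelity |
| Traced EM dyad cross-section | circularity 4πA/P², T-tubule–SR coupling ratio, junction–Z-line distance |
| BioID intensity table | mean-sensor/control enrichment ratio ranking with zero-control grouping and strict ratio > 5 retention |

Key statistics, in the field's notation:

- **ΔF/F₀** = (F − F₀)/F₀ with F₀ the per-position 10th percentile of the
  temporally smoothed quiet signal. Sparks are 8-connected regions where
  the smoothed ΔF/F₀ exceeds *k*·σ (σ = 1.4826·MAD, *k* = 3.8).
- **Coupling fidelity**: a dyad site is activated on a stimulus when its
  local ΔF/F₀ peak within ±0.75 µm and 150 ms post-stimulus clears a
  threshold; the number of site–stimulus pairs without release over three
  consecutive transients, divided by scan length in 100 µm units, is the
  missed-coupling rate. Sites with both hits and misses are the
  *inconsistently coupled* dyads.
- **Circularity** = 4πA/P² (shoelace area, polygon perimeter);
  **coupling ratio** = fraction of T-tubule perimeter within 15 nm of a
  jSR trace (the dyadic cleft is ~12 nm); **junction–Z distance** =
  perpendicular distance from the Z-line to the arc-midpoint of the
  largest coupled perimeter run.
- **Enrichment ratio** = ((sensor_A + sensor_B)/2) / control; proteins
  absent from the control arm rank first, and retention requires ratio
  strictly > 5.

## Worked example

```python
from dyadkit.simulate import ScanSimConfig, make_linescan
from dyadkit import caflux

# 40 um line scan, 3.78 ms/line, 1 Hz pacing, dyads every 2 um,
# 80% per-stimulus coupling probability
kymo, truth = make_linescan(ScanSimConfig(duration_s=8.0, p_couple=0.8), seed=1)
f0, _ = caflux.estimate_baseline(kymo)
dff = caflux.normalize_dff(kymo, f0)
res = caflux.score_dyad_coupling(dff, kymo.pacing_times_s,
                                 kymo.pixel_size_um, kymo.line_interval_ms)
print(len(res.site_positions_um), res.missed_rate_per_100um,
      len(res.inconsistent_sites))
```

prints

```
17 27.5 14
```

meaning 17 dyad sites were auto-detected on the 40 µm line (sites that
fired rarely in this short scan stay below the detection profile), the
worst window of three consecutive transients had 11 missed site–stimulus
releases (11 / 0.4 hundred-µm = 27.5 per 100 µm), and 14 dyads were
inconsistently coupled — the expected picture for an 80% per-stimulus
coupling probability.

The numbered scripts under `analysis/` run the same machinery as small
narrative studies (enrichment screen, striation colocalization, T-tubule
fractions, Ca²⁺ phenotyping, dyad morphometry, full benchmark), each
writing its tables under `results/`. A `dyadkit` CLI wraps the library:
`dyadkit simulate <kind>`, `dyadkit analyze <kind>`, and
`dyadkit pipeline --config run.json` for seeded end-to-end runs with a
reproducibility manifest.

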