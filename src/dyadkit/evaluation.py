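"""Self-contained benchmark suite: recovery of generator ground truth by
every analysis stage, detector operating characteristics, and paired
direction-of-effect contrasts between reference and disrupted-dyad
("KO-like") study arms.

Every function derives its randomness from a single base seed, so a whole
benchmark run is reproducible end to end.  Problem sizes (seeds per
condition, scan durations, image sizes) are chosen so each block runs in
tens of seconds on one CPU.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
from scipy import stats

from . import caflux, dyadgeom, striation, ttubule
from .io import FluorescenceImage
from .simulate import (BioidSimConfig, EMSimConfig, ScanSimConfig, TTSimConfig,
                       make_bioid_table, make_em_scene, make_linescan,
                       make_ttubule_image)
from .bioid import rank_table


def _sub_seeds(base_seed: int, label: str, n: int) -> list[int]:
    """Independent 31-bit seeds for one benchmark block."""
    ss = np.random.SeedSequence([base_seed, zlib.crc32(label.encode()) % (2 ** 31)])
    return [int(s % (2 ** 31)) for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------- geometry

def geometry_identities(seed: int = 0) -> dict:
    """Closed-form circularity checks plus arc/distance recovery."""
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    out = {
        "circularity_unit_square": dyadgeom.circularity(square),
        "circularity_unit_square_error": abs(
            dyadgeom.circularity(square) - math.pi / 4),
    }
    ngon_vals = []
    for n in (8, 16, 32, 64, 256, 1024, 4096):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ngon_vals.append(dyadgeom.circularity(
            np.column_stack([100 * np.cos(t), 100 * np.sin(t)])))
    out["ngon_circularity_monotone"] = float(
        all(b > a for a, b in zip(ngon_vals, ngon_vals[1:])))
    out["circularity_4096gon"] = ngon_vals[-1]

    seeds = _sub_seeds(seed, "geometry", 8)
    arc_err = []
    for i, frac in enumerate((0.0, 0.3, 0.6, 1.0)):
        scene = make_em_scene(EMSimConfig(jsr_arc_fraction=frac), seeds[i])
        arc_err.append(abs(dyadgeom.coupling_ratio(scene.ttubule, scene.jsr)
                           - frac))
    out["coupling_ratio_max_abs_error"] = max(arc_err)

    z_err = []
    for i, zd in enumerate((0.0, 20.0, 40.0, 60.0)):
        scene = make_em_scene(EMSimConfig(zline_distance_nm=zd), seeds[4 + i])
        z_err.append(abs(dyadgeom.junction_z_distance(
            scene.ttubule, scene.jsr, scene.zline) - zd))
    out["junction_z_max_abs_error_nm"] = max(z_err)
    return out


# ---------------------------------------------------------------- T-tubule

TT_RECOVERY_CONFIGS = (
    TTSimConfig(),                                                    # ~1.0
    TTSimConfig(transverse_dropout=0.15, longitudinal_density=0.08),  # ~0.8
    TTSimConfig(transverse_dropout=0.3, longitudinal_density=0.15),   # ~0.7
    TTSimConfig(transverse_dropout=0.45, longitudinal_density=0.35),  # ~0.4
)


def tt_fraction_recovery(seed: int = 0, n_seeds: int = 10,
                         configs=TT_RECOVERY_CONFIGS) -> dict:
    """Mean |measured - true| transverse fraction per config, plus rotation."""
    errors = []
    for ci, cfg in enumerate(configs):
        errs = []
        for s in _sub_seeds(seed, f"tt{ci}", n_seeds):
            img, truth = make_ttubule_image(cfg, s)
            m = ttubule.analyze_ttubule_image(img)
            errs.append(abs(m.transverse_fraction - truth.true_transverse_fraction))
        errors.append(float(np.mean(errs)))

    rot_deltas = []
    for s in _sub_seeds(seed, "ttrot", 2):
        img, _ = make_ttubule_image(configs[2], s)
        m0 = ttubule.analyze_ttubule_image(img)
        m90 = ttubule.analyze_ttubule_image(FluorescenceImage(
            np.ascontiguousarray(np.rot90(img.pixels)), img.pixel_size_um))
        rot_deltas.append(abs(m90.transverse_fraction - m0.transverse_fraction))
    return {
        "per_config_mean_abs_error": errors,
        "max_mean_abs_error": max(errors),
        "rotation_max_delta": float(max(rot_deltas)),
        "n_seeds": n_seeds,
    }


# ------------------------------------------------------------------ sparks

def spark_benchmark(seed: int = 0, n_null: int = 10, n_rec: int = 10,
                    n_freq: int = 20) -> dict:
    """Null false-positive rate, recall/amplitude accuracy, and frequency CI."""
    fp, area = 0, 0.0
    for s in _sub_seeds(seed, "null", n_null):
        kymo, _ = make_linescan(ScanSimConfig(pacing_hz=0.0, duration_s=8.0), s)
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        fp += len(caflux.detect_sparks(dff, kymo.pixel_size_um,
                                       kymo.line_interval_ms))
        area += kymo.scan_length_um / 100.0 * kymo.duration_s

    n_true = n_det = 0
    amp_err = []
    for s in _sub_seeds(seed, "recall", n_rec):
        cfg = ScanSimConfig(pacing_hz=0.0, spark_rate_per_site_per_s=0.05)
        kymo, truth = make_linescan(cfg, s)
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        events = caflux.detect_sparks(dff, kymo.pixel_size_um,
                                      kymo.line_interval_ms)
        for pos, ts, amp in truth.spark_events:
            n_true += 1
            match = [e for e in events
                     if abs(e.position_um - pos) < 1.0
                     and abs(e.time_s - ts - cfg.spark_rise_ms / 1000.0) < 0.05]
            if match:
                n_det += 1
                amp_err.append(abs(match[0].amplitude_dff - amp) / amp)

    inside = 0
    rate, dur = 0.1, 15.0
    for s in _sub_seeds(seed, "freq", n_freq):
        cfg = ScanSimConfig(pacing_hz=0.0, spark_rate_per_site_per_s=rate,
                            duration_s=dur)
        kymo, truth = make_linescan(cfg, s)
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        n = len(caflux.detect_sparks(dff, kymo.pixel_size_um,
                                     kymo.line_interval_ms))
        lam = rate * len(truth.site_positions_um) * dur
        lo, hi = stats.poisson.ppf([0.025, 0.975], lam)
        inside += int(lo <= n <= hi)
    return {
        "false_positives_per_100um_s": fp / area,
        "recall": n_det / n_true if n_true else float("nan"),
        "amplitude_mean_abs_error": float(np.mean(amp_err)) if amp_err else float("nan"),
        "frequency_in_ci": inside,
        "n_freq_seeds": n_freq,
    }


# ---------------------------------------------------------------- coupling

def coupling_recovery(seed: int = 0,
                      p_values=(1.0, 0.9, 0.7)) -> dict:
    """Empirical miss fractions vs the generated Bernoulli coupling."""
    out = {}
    seeds = _sub_seeds(seed, "couple", len(p_values))
    for p, s in zip(p_values, seeds):
        cfg = ScanSimConfig(duration_s=16.0, p_couple=p)
        kymo, truth = make_linescan(cfg, s)
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        res = caflux.score_dyad_coupling(
            dff, kymo.pacing_times_s, kymo.pixel_size_um, kymo.line_interval_ms,
            site_positions_um=truth.site_positions_um)
        miss = float((~res.activation_matrix).mean())
        n_pairs = res.activation_matrix.size
        out[p] = {
            "miss_fraction": miss,
            "expected": 1.0 - p,
            "three_se": 3.0 * math.sqrt(p * (1 - p) / n_pairs),
            "missed_rate_per_100um": res.missed_rate_per_100um,
            "n_inconsistent": len(res.inconsistent_sites),
            "n_pairs": n_pairs,
        }
    return out


def sr_content_recovery(seed: int = 0, n_seeds: int = 20,
                        scales=(1.0, 0.75)) -> dict:
    """Paired caffeine-dump simulations; the estimate ratio tracks SR content."""
    ratios = []
    seeds = _sub_seeds(seed, "sr", 2 * n_seeds)
    for i in range(n_seeds):
        ests = []
        for j, scale in enumerate(scales):
            kymo, _ = make_linescan(
                ScanSimConfig(caffeine_mode=True, duration_s=12.0,
                              store_scale=scale), seeds[2 * i + j])
            ests.append(caflux.sr_content_caffeine(kymo).delta_over_f0)
        ratios.append(ests[1] / ests[0])
    return {"mean_ratio": float(np.mean(ratios)),
            "expected_ratio": scales[1] / scales[0],
            "sd": float(np.std(ratios)), "n_seeds": n_seeds}


# --------------------------------------------------- direction-of-effect

TT_REF = TTSimConfig(image_size_um=(20.0, 10.0), transverse_dropout=0.2,
                     longitudinal_density=0.1)
TT_KO = TTSimConfig(image_size_um=(20.0, 10.0), transverse_dropout=0.5,
                    longitudinal_density=0.3)
SCAN_REF = dict(p_couple=1.0, spark_rate_per_site_per_s=0.05,
                transient_amplitude_dff=2.0, store_scale=1.0)
SCAN_KO = dict(p_couple=0.8, spark_rate_per_site_per_s=0.15,
               transient_amplitude_dff=1.4, store_scale=0.75)
EM_REF = dict(ellipse_semi_axes_nm=(250.0, 200.0), jsr_arc_fraction=0.6,
              zline_mean_nm=20.0, zline_sd_nm=5.0)
EM_KO = dict(ellipse_semi_axes_nm=(300.0, 100.0), jsr_arc_fraction=0.3,
             zline_mean_nm=60.0, zline_sd_nm=20.0)


def _caflux_arm(params: dict, seeds: list[int]) -> dict:
    s1, s2, s3 = seeds
    kymo, _ = make_linescan(ScanSimConfig(
        pacing_hz=0.0, duration_s=8.0,
        spark_rate_per_site_per_s=params["spark_rate_per_site_per_s"]), s1)
    f0, _ = caflux.estimate_baseline(kymo)
    dff = caflux.normalize_dff(kymo, f0)
    events = caflux.detect_sparks(dff, kymo.pixel_size_um, kymo.line_interval_ms)
    freq = caflux.spark_frequency(events, kymo.scan_length_um, kymo.duration_s)

    kymo2, _ = make_linescan(ScanSimConfig(
        duration_s=6.0, p_couple=params["p_couple"],
        transient_amplitude_dff=params["transient_amplitude_dff"]), s2)
    f0, _ = caflux.estimate_baseline(kymo2)
    dff2 = caflux.normalize_dff(kymo2, f0)
    trans = caflux.detect_transients(dff2, kymo2.pacing_times_s,
                                     kymo2.line_interval_ms)
    coup = caflux.score_dyad_coupling(dff2, kymo2.pacing_times_s,
                                      kymo2.pixel_size_um, kymo2.line_interval_ms)

    kymo3, _ = make_linescan(ScanSimConfig(
        caffeine_mode=True, duration_s=12.0,
        store_scale=params["store_scale"]), s3)
    sr = caflux.sr_content_caffeine(kymo3).delta_over_f0
    return {
        "spark_frequency": freq,
        "transient_amplitude": float(np.mean([t.amplitude_dff for t in trans])),
        "missed_rate": coup.missed_rate_per_100um,
        "sr_content": sr,
    }


def _em_arm(params: dict, seeds: list[int], n_scenes: int = 6) -> dict:
    rng = np.random.default_rng(seeds[0])
    circ, cr, jz = [], [], []
    for i in range(n_scenes):
        zd = max(float(rng.normal(params["zline_mean_nm"], params["zline_sd_nm"])), 0.0)
        cfg = EMSimConfig(ellipse_semi_axes_nm=params["ellipse_semi_axes_nm"],
                          jsr_arc_fraction=params["jsr_arc_fraction"],
                          zline_distance_nm=zd)
        m = dyadgeom.analyze_scene(make_em_scene(cfg, seeds[1 + i]))
        circ.append(m.circularity)
        cr.append(m.coupling_ratio)
        jz.append(m.junction_z_distance_nm)
    return {"circularity": float(np.mean(circ)),
            "coupling_ratio": float(np.mean(cr)),
            "jz_mean": float(np.mean(jz)), "jz_sd": float(np.std(jz))}


def ko_direction_suite(seed: int = 0, n_seeds: int = 20) -> dict:
    """Paired reference-vs-KO contrasts across all modalities.

    Returns the number of paired seeds (out of n_seeds) in which the
    disrupted arm moves in the disease direction for each metric.
    """
    wins = {k: 0 for k in ("transverse_fraction_down", "longitudinal_fraction_up",
                           "circularity_down", "coupling_ratio_down",
                           "jz_mean_up", "jz_sd_up", "spark_frequency_up",
                           "transient_amplitude_down", "missed_rate_up",
                           "sr_content_down")}
    all_seeds = _sub_seeds(seed, "ko", n_seeds * 20)
    for i in range(n_seeds):
        chunk = all_seeds[i * 20:(i + 1) * 20]
        # the generator renders the long axis along x; supplying it isolates
        # the fraction readout from axis-estimation noise on small images
        mr = ttubule.analyze_ttubule_image(make_ttubule_image(TT_REF, chunk[0])[0],
                                           axis_deg=0.0)
        mk = ttubule.analyze_ttubule_image(make_ttubule_image(TT_KO, chunk[1])[0],
                                           axis_deg=0.0)
        wins["transverse_fraction_down"] += mk.transverse_fraction < mr.transverse_fraction
        wins["longitudinal_fraction_up"] += mk.longitudinal_fraction > mr.longitudinal_fraction

        er = _em_arm(EM_REF, chunk[2:9])
        ek = _em_arm(EM_KO, chunk[9:16])
        wins["circularity_down"] += ek["circularity"] < er["circularity"]
        wins["coupling_ratio_down"] += ek["coupling_ratio"] < er["coupling_ratio"]
        wins["jz_mean_up"] += ek["jz_mean"] > er["jz_mean"]
        wins["jz_sd_up"] += ek["jz_sd"] > er["jz_sd"]

        cr = _caflux_arm(SCAN_REF, chunk[16:19])
        ck = _caflux_arm(SCAN_KO, [chunk[19], chunk[19] + 1, chunk[19] + 2])
        wins["spark_frequency_up"] += ck["spark_frequency"] > cr["spark_frequency"]
        wins["transient_amplitude_down"] += (ck["transient_amplitude"]
                                             < cr["transient_amplitude"])
        wins["missed_rate_up"] += ck["missed_rate"] > cr["missed_rate"]
        wins["sr_content_down"] += ck["sr_content"] < cr["sr_content"]
    return {"wins": {k: int(v) for k, v in wins.items()}, "n_seeds": n_seeds}


# ------------------------------------------------------------------- bioid

def _brute_force_order(table, threshold=5.0):
    zero, finite = [], []
    for _, r in table.iterrows():
        mean = (r.sensor_A + r.sensor_B) / 2.0
        if r.control == 0:
            if mean > 0:
                zero.append((-mean, r.protein_id))
        else:
            finite.append((-mean / r.control, -mean, r.protein_id))
    order = [p for _, p in sorted(zero)] + [p for *_k, p in sorted(finite)]
    retained = {p for _, p in zero} | {p for rr, _m, p in finite if -rr > threshold}
    return order, retained


def bioid_oracle_check(seed: int = 0, n_tables: int = 100) -> dict:
    """Ranking vs a brute-force sort oracle on random tables."""
    import pandas as pd
    agree = 0
    zero_first_ok = True
    rngs = [np.random.default_rng(s) for s in _sub_seeds(seed, "bioid", n_tables)]
    for rng in rngs:
        n = 60
        rows = []
        for i in range(n):
            a, b = rng.uniform(0, 50, 2)
            c = 0.0 if rng.random() < 0.15 else float(rng.uniform(0.1, 20))
            rows.append((f"P{i:03d}", float(a), float(b), c))
        table = pd.DataFrame(rows, columns=["protein_id", "sensor_A",
                                            "sensor_B", "control"])
        ranked = rank_table(table)
        order, retained = _brute_force_order(table)
        ok = (list(ranked["protein_id"]) == order and
              set(ranked.loc[ranked["retained"], "protein_id"]) == retained)
        agree += ok
        cz = ranked["control_zero"].to_numpy()
        if cz.any() and (~cz).any():
            zero_first_ok &= cz[:int(cz.sum())].all() and not cz[int(cz.sum()):].any()
    import pandas as pd
    boundary = rank_table(pd.DataFrame(
        [("PX", 10.0, 10.0, 2.0)], columns=["protein_id", "sensor_A",
                                            "sensor_B", "control"]))
    return {"oracle_agreement": agree, "n_tables": n_tables,
            "zero_control_always_first": bool(zero_first_ok),
            "ratio_exactly_5_retained": bool(boundary.loc[0, "retained"])}


# ------------------------------------------------------------- periodicity

def periodicity_benchmark(seed: int = 0, n_null: int = 100,
                          n_images: int = 5) -> dict:
    x = np.arange(0, 40, 0.1)
    sine = striation.SpatialProfile(x, 100 + 50 * np.sin(2 * np.pi * x / 2.0))
    sine_res = striation.detect_period(sine)

    period_errs = []
    for s in _sub_seeds(seed, "perimg", n_images):
        img, _ = make_ttubule_image(TTSimConfig(), s)
        prof = striation.spatial_profile(img, (0.0, 10.0), (40.0, 10.0),
                                         width_um=2.0)
        res = striation.detect_period(prof)
        period_errs.append(abs(res.period_um - 2.0) / 2.0 if res.is_striated
                           else float("inf"))

    rng = np.random.default_rng(_sub_seeds(seed, "pernull", 1)[0])
    hits = sum(striation.detect_period(striation.SpatialProfile(
        np.arange(1000) * 0.1, rng.normal(100, 10, 1000))).is_striated
        for _ in range(n_null))
    return {"sine_period_um": sine_res.period_um,
            "image_period_max_rel_error": max(period_errs),
            "null_striated_count": int(hits), "n_null": n_null}


# ----------------------------------------------------------- determinism

def pipeline_determinism(tmp_dir, seed: int = 0) -> dict:
    """Run the same pipeline config twice; outputs must be byte-identical."""
    from pathlib import Path
    from .pipeline import RunConfig, run_pipeline
    tmp_dir = Path(tmp_dir)
    stages = [
        {"kind": "emscene", "name": "em"},
        {"kind": "bioid", "name": "bio",
         "params": {"n_background": 200, "n_enriched": 10,
                    "n_zero_control_enriched": 3}},
        {"kind": "linescan", "name": "ls", "params": {"duration_s": 5.0}},
    ]
    manifests = []
    for sub in ("a", "b"):
        cfg = RunConfig.from_dict({"seed": seed, "out_dir": str(tmp_dir / sub),
                                   "stages": stages})
        manifests.append(run_pipeline(cfg))
    m1, m2 = manifests
    identical = m1.file_digests == m2.file_digests and all(
        (tmp_dir / "a" / f).read_bytes() == (tmp_dir / "b" / f).read_bytes()
        for f in m1.file_digests)
    return {"byte_identical": bool(identical), "n_files": len(m1.file_digests)}
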