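#!/usr/bin/env python
"""Full recovery benchmark: every analysis stage against generator truth.

Thin driver over dyadkit.evaluation; prints the same quantities that
scripts/acceptance.py writes and saves them to results/benchmark.csv.
"""

import tempfile
from pathlib import Path

import pandas as pd

from dyadkit import evaluation as ev
from dyadkit.io import write_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    rows = []

    g = ev.geometry_identities(seed)
    rows += [("circularity_unit_square", g["circularity_unit_square"]),
             ("coupling_ratio_max_abs_error", g["coupling_ratio_max_abs_error"]),
             ("junction_z_max_abs_error_nm", g["junction_z_max_abs_error_nm"])]

    tt = ev.tt_fraction_recovery(seed, n_seeds=5)
    rows.append(("tt_fraction_max_mean_abs_error", tt["max_mean_abs_error"]))

    sp = ev.spark_benchmark(seed, n_null=5, n_rec=5, n_freq=10)
    rows += [("spark_recall", sp["recall"]),
             ("spark_fp_per_100um_s", sp["false_positives_per_100um_s"]),
             ("spark_amplitude_mean_abs_error", sp["amplitude_mean_abs_error"])]

    sr = ev.sr_content_recovery(seed, n_seeds=10)
    rows.append(("sr_content_ratio_store075", sr["mean_ratio"]))

    bi = ev.bioid_oracle_check(seed, n_tables=30)
    rows.append(("bioid_oracle_agreement_frac",
                 bi["oracle_agreement"] / bi["n_tables"]))

    per = ev.periodicity_benchmark(seed, n_null=50)
    rows.append(("striation_sine_period_um", per["sine_period_um"]))

    with tempfile.TemporaryDirectory() as tmp:
        det = ev.pipeline_determinism(tmp, seed)
    rows.append(("pipeline_byte_identical", float(det["byte_identical"])))

    df = pd.DataFrame(rows, columns=["quantity", "value"])
    write_csv(df, OUT / "benchmark.csv")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
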