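"""Instrument-strength QC and a priori power for the outcome panel.

Reads the heart-failure cohort's exposure GWAS (all cohorts share the
exposure design), writes the per-SNP R²/F table and the per-cohort power
to detect OR 0.90 at alpha 0.05.
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from mrpipe.instrument_qc import PowerSpec, aggregate_r2, mean_f, mr_power_binary, qc_table
from mrpipe.summary_io import read_summary_stats, select_instruments


def main() -> None:
    exposure = read_summary_stats(common.DATA / "heart_failure" / "exposure.tsv",
                                  trait_name="exposure")
    instruments = select_instruments(exposure)
    qc = qc_table(instruments)
    common.RESULTS.mkdir(exist_ok=True)
    qc.to_csv(common.RESULTS / "instrument_qc.tsv", sep="\t", index=False)
    total_r2 = aggregate_r2(instruments)
    print(f"{len(instruments)} instruments; total R2 = {total_r2:.4f}; "
          f"mean F = {mean_f(instruments):.1f}")

    rows = []
    for name, (_seed, _theta, n_out, k) in common.COHORTS.items():
        power = mr_power_binary(PowerSpec(
            n_total=n_out, case_fraction=k,
            r2_exposure=total_r2, odds_ratio=0.90))
        rows.append({"outcome": name, "n": n_out, "case_fraction": k,
                     "r2": total_r2, "or": 0.90, "power_pct": 100 * power})
    tab = pd.DataFrame(rows)
    tab.to_csv(common.RESULTS / "power.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
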