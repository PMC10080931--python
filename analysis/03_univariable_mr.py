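"""Univariable MR of the exposure against the five-outcome panel.

Each cohort pairs its own exposure/outcome files (independent GWAS draws).
Writes the full results table, the formatted report and a forest plot.
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from mrpipe.pipeline import AnalysisConfig, plot_forest, run_report, run_univariable
from mrpipe.summary_io import read_summary_stats


def main() -> None:
    config = AnalysisConfig(seed=7)
    frames = []
    for name in common.COHORTS:
        d = common.DATA / name
        exposure = read_summary_stats(d / "exposure.tsv", trait_name="exposure")
        outcome = read_summary_stats(d / "outcome.tsv", trait_name=name,
                                     trait_type="binary")
        results, log, errors = run_univariable(exposure, [outcome], config)
        if errors:
            raise SystemExit(f"{name}: {errors}")
        frames.append(results)
    results = pd.concat(frames, ignore_index=True)

    common.RESULTS.mkdir(exist_ok=True)
    results.to_csv(common.RESULTS / "mr_univariable.tsv", sep="\t", index=False)
    report = run_report(results, common.RESULTS / "mr_report.tsv")
    plot_forest(results, common.RESULTS / "forest_ivw.png")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
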