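"""Two-step mediation: decompose the total effect into direct and
mediated components and report the mediated proportion with its CI."""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from mrpipe.mediation import mediate
from mrpipe.summary_io import read_summary_stats


def main() -> None:
    d = common.DATA / "mediation"
    exposure = read_summary_stats(d / "exposure.tsv", trait_name="exposure")
    mediator = read_summary_stats(d / "mediator.tsv", trait_name="mediator")
    outcome = read_summary_stats(d / "outcome.tsv", trait_name="outcome",
                                 trait_type="binary")

    res = mediate(exposure, mediator, outcome)
    lo, hi = res.proportion_ci
    tab = pd.DataFrame([{
        "exposure": res.exposure, "mediator": res.mediator,
        "outcome": res.outcome,
        "total": res.total, "se_total": res.se_total,
        "alpha": res.alpha, "se_alpha": res.se_alpha,
        "beta_m": res.beta_m, "se_beta_m": res.se_beta_m,
        "indirect": res.indirect, "se_indirect": res.se_indirect,
        "proportion_pct": res.proportion, "ci_low_pct": lo, "ci_high_pct": hi,
        "out_of_range": res.out_of_range,
    }])
    common.RESULTS.mkdir(exist_ok=True)
    tab.to_csv(common.RESULTS / "mediation.tsv", sep="\t", index=False)
    print(f"mediated proportion: {res.proportion:.1f}% "
          f"(95% CI {lo:.1f}% to {hi:.1f}%)"
          + (" [outside 0-100%]" if res.out_of_range else ""))


if __name__ == "__main__":
    main()
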