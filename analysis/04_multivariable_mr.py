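"""Multivariable MR: exposure and mediator jointly against the outcome.

Uses the mediation-chain GWAS; the MVMR exposure coefficient is the
direct effect conditional on the mediator.
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from mrpipe.mvmr import assemble_mvmr_input, mvmr_ivw
from mrpipe.summary_io import read_summary_stats


def main() -> None:
    d = common.DATA / "mediation"
    exposure = read_summary_stats(d / "exposure.tsv", trait_name="exposure")
    mediator = read_summary_stats(d / "mediator.tsv", trait_name="mediator")
    outcome = read_summary_stats(d / "outcome.tsv", trait_name="outcome",
                                 trait_type="binary")

    mv = assemble_mvmr_input([exposure, mediator], outcome)
    results = mvmr_ivw(mv)
    tab = pd.DataFrame([{
        "method": r.method, "n_snp": r.n_snp, "beta": r.beta, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
    } for r in results])
    common.RESULTS.mkdir(exist_ok=True)
    tab.to_csv(common.RESULTS / "mvmr.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
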