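"""Generate the synthetic exposure/outcome panel and the mediation chain.

Writes one directory per cohort under results/data/ containing
exposure.tsv, outcome.tsv and the generator's truth.tsv sidecar, plus a
mediation/ directory with the exposure-mediator-outcome chain.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from mrpipe.synthetic_data import (
    SynthConfig,
    simulate_mediation_chain,
    simulate_two_sample,
    write_truth,
)


def main() -> None:
    for name in common.COHORTS:
        out_dir = common.DATA / name
        out_dir.mkdir(parents=True, exist_ok=True)
        exposure, outcome, truth = simulate_two_sample(common.cohort_config(name))
        exposure.write(out_dir / "exposure.tsv")
        outcome.write(out_dir / "outcome.tsv")
        write_truth(truth, out_dir / "truth.tsv")
        print(f"{name}: {len(exposure)} SNPs -> {out_dir}")

    med_dir = common.DATA / "mediation"
    med_dir.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome, truth = simulate_mediation_chain(
        SynthConfig(seed=common.MEDIATION_SEED))
    exposure.write(med_dir / "exposure.tsv")
    mediator.write(med_dir / "mediator.tsv")
    outcome.write(med_dir / "outcome.tsv")
    print(f"mediation chain: true proportion {truth.proportion:.1f}% -> {med_dir}")


if __name__ == "__main__":
    main()
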