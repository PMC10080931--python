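"""Shared settings for the analysis drivers.

The five outcome cohorts mirror a cardiovascular panel: each gets its own
synthetic GWAS with a fixed seed and a fixed true causal log-OR per SD of
the exposure.  These are study conditions chosen once, not tuned.
"""

from pathlib import Path

from mrpipe.synthetic_data import SynthConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

# cohort name -> (seed, true theta, outcome N, case fraction)
COHORTS = {
    "heart_failure": (101, -0.36, 500_000, 0.05),
    "coronary_artery_disease": (102, -0.36, 180_000, 0.33),
    "myocardial_infarction": (103, -0.40, 170_000, 0.26),
    "atrial_fibrillation": (104, -0.05, 500_000, 0.10),
    "stroke": (105, -0.13, 450_000, 0.09),
}

MEDIATION_SEED = 201


def cohort_config(name: str) -> SynthConfig:
    seed, theta, n_out, k = COHORTS[name]
    return SynthConfig(seed=seed, theta_true=theta, n_outcome=n_out,
                       case_fraction=k)
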