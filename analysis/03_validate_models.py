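#!/usr/bin/env python
"""Main validation run: every registered model against the synthetic cohort.

Produces the discrimination/calibration table, the threshold table, the
case-mix (mean linear predictor) table, and plot-ready calibration-bin and
decision-curve CSVs under results/main/.

The shipped model configurations carry placeholder coefficients, so the
numbers here characterize the machinery on a known cohort, not any
published model's true transportability.
"""

import warnings
from pathlib import Path

from ckdval.pipeline import RunConfig, run_validation

N_PATIENTS = 6000
SEED = 2009

OUT = Path(__file__).resolve().parents[1] / "results" / "main"


def main() -> None:
    config = RunConfig(
        synthetic={"n_patients": N_PATIENTS},
        output_dir=str(OUT),
        seed=SEED,
        bootstrap_B=500,
        threshold_sd_B=200,
        imputation={"n_imputations": 10, "n_cycles": 10},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_validation(config)
    print("flow:", results["flow"])
    table4 = results["table4"].pivot_table(index="model", columns="metric",
                                           values="estimate")
    print(table4.round(3).to_string())


if __name__ == "__main__":
    main()
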