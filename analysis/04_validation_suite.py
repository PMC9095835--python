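#!/usr/bin/env python
"""Calibration and recovery checks for every estimator in the pipeline.

Runs the validation suite (PAF recovery, inverse point-spread, CFC
calibration, cluster-permutation error rates) at its standard problem sizes
and writes the numbers to results/validation.json.  These are the same
computations the acceptance script reports.
"""

import json
from pathlib import Path

from tcdeeg import validation as V

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    out = {
        "relative_power_sum_max_abs_dev": V.relative_power_conservation(SEED),
        "band_bin_shares": V.band_bin_shares(),
        "paf_recovery": V.paf_recovery(SEED, n_subjects=50),
        "inverse_point_spread": V.inverse_point_spread(SEED),
        "cfc_calibration": V.cfc_calibration(SEED),
        "cluster_error_rates": V.cluster_error_rates(SEED),
    }
    ROOT.mkdir(exist_ok=True)
    with open(ROOT / "validation.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
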