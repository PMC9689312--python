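#!/usr/bin/env python
"""Staged identification of the CO2 model from synthetic batches 2-4.

Same protocol as the biomass fit: 5% relative noise, three temperatures,
four-stage fit (KS pinned, KS alone, law coefficients, global refit) from
1.5x-truth starts, followed by the Fisher-information uncertainty report.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402
import yaml  # noqa: E402

from brewkin import (  # noqa: E402
    default_designs,
    make_dataset,
    staged_fit_co2,
    uncertainty_report,
    write_dataset,
)
from brewkin.params import default_params  # noqa: E402

SEED, SIGMA = 20241, 0.05
RESULTS = ROOT / "results"
(RESULTS / "datasets").mkdir(parents=True, exist_ok=True)

truth = default_params("co2")
datasets = []
for i, design in enumerate(default_designs()[1:]):
    ds = make_dataset("co2", truth, design, sigma_rel=SIGMA, seed=SEED + i)
    write_dataset(ds, RESULTS / "datasets" / f"co2_batch{design.id}.csv")
    datasets.append(ds)

theta0 = {k: 1.5 * v for k, v in truth.items()}
fit = staged_fit_co2(datasets, seed=SEED, theta0=theta0)
report = uncertainty_report(fit, datasets)

table = pd.DataFrame({
    "truth": [truth[n] for n in fit.spec.free],
    "estimate": [fit.theta[n] for n in fit.spec.free],
    "cv_percent": report.cv_percent,
}, index=fit.spec.free)
print(f"stage costs J: {[f'{s.J:.4g}' for s in fit.stage_history]}")
print(table.to_string(float_format=lambda v: f"{v:.4g}"))

out = {
    "model_id": "co2",
    "seed": SEED,
    "sigma_rel": SIGMA,
    "stage_J": [float(s.J) for s in fit.stage_history],
    "theta": fit.theta,
    "truth": {k: float(v) for k, v in truth.items()},
    "cv_percent": {n: float(c) for n, c in zip(fit.spec.free, report.cv_percent)},
    "eps2": float(report.eps2),
    "bounds_hit": fit.bounds_hit,
    "warnings": fit.warnings,
}
(RESULTS / "co2_fit.yaml").write_text(yaml.safe_dump(out, sort_keys=False))
print(f"written to {RESULTS / 'co2_fit.yaml'}")
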