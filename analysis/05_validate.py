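#!/usr/bin/env python
"""Validate the identified parameters: training batches and held-out batch 1.

Direct validation re-predicts the training batches 2-4 with the fitted
parameters.  Cross-validation predicts the held-out batch 1 (19 degC, not
used for fitting) after re-estimating only its initial conditions, the
protocol for a batch whose starting point is itself uncertain.  Uses the
fit results from scripts 03/04 when present, otherwise the packaged
parameter values.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import yaml  # noqa: E402

from brewkin import default_designs, make_dataset, validation_report  # noqa: E402
from brewkin.params import default_params  # noqa: E402

SEED, SIGMA = 20242, 0.05
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

lines = []
for model_id in ("biomass", "co2"):
    fit_file = RESULTS / f"{model_id}_fit.yaml"
    if fit_file.exists():
        params = yaml.safe_load(fit_file.read_text())["theta"]
        source = f"fit from {fit_file.name}"
    else:
        params = default_params(model_id)
        source = "packaged parameter values"
    truth = default_params(model_id)
    designs = default_designs()

    train = [make_dataset(model_id, truth, d, sigma_rel=SIGMA, seed=SEED + i)
             for i, d in enumerate(designs[1:])]
    direct = validation_report(params, train, model_id, mode="direct")

    heldout = make_dataset(model_id, truth, designs[0], sigma_rel=SIGMA,
                           seed=SEED + 9)
    cross = validation_report(params, heldout, model_id, mode="cross",
                              seed=SEED)

    lines += [f"== {model_id} model ({source}) ==", str(direct), "",
              str(cross), ""]

report = "\n".join(lines)
(RESULTS / "validation.txt").write_text(report)
print(report)
print(f"written to {RESULTS / 'validation.txt'}")
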