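#!/usr/bin/env python
"""Qualitative demonstration: odorless interferents and the two feature modes.

Calibrates and selects the best raw-maximum (SMAX) and dB-mode (SDB) models
on a clean campaign, then applies both to a monitoring period dominated by a
strong methane-like interferent — a gas the MOS channels respond to but the
panel cannot smell.  Raw maxima absorb the interferent directly, while the
logarithmic peak-to-baseline feature compresses it, so the SMAX model is
expected to overestimate the true odor concentration more often.  The
outcome is reported, not asserted.

Usage::

    python scripts/interferent_demo.py [--seed 0]
"""

from __future__ import annotations

import argparse
import warnings

import numpy as np

from odorcal.features import estimate_baseline, extract_features
from odorcal.pipeline import PipelineConfig, run_pipeline
from odorcal.synthetic import (
    GeneratorConfig,
    generate_emission_profile,
    simulate_sensor_array,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    # 1) calibrate and select on a clean campaign (no interferent)
    clean = GeneratorConfig(seed=args.seed, interferent_prob=0.0)
    from odorcal.synthetic import make_study

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(make_study(clean), PipelineConfig(reject_interferents=False))

    # 2) monitoring period with a strong, frequent interferent
    monitor = clean.replace(
        seed=args.seed + 1,
        n_sessions=60,
        event_prob=0.2,
        interferent_prob=0.9,
        interferent_mu_log=np.log(40.0),
    )
    cod_true, interferent = generate_emission_profile(monitor)
    windows = simulate_sensor_array(cod_true, interferent, monitor)

    quiet = cod_true <= 3.0
    print("interferent stress test (reported, not asserted)")
    print("=" * 64)
    print(f"monitoring period: {monitor.n_sessions} windows, "
          f"{(interferent > 0).sum()} with interferent "
          f"(median level {np.median(interferent[interferent > 0]):.1f}), "
          f"{int(quiet.sum())} genuinely quiet (true C_od <= 3 ou/m3)")
    rates, quiet_rates = {}, {}
    # the monitoring pairing: principal-component regression on raw maxima
    # versus the Stevens/PC1 hybrid on dB features
    pairing = {"SMAX": "PCR", "SDB": "STEVENS_PC1"}
    for mode, family in pairing.items():
        model = result.models[(mode, family)]
        preds = []
        for w in windows:
            fv = extract_features(w, mode, s0=estimate_baseline(w))
            preds.append(float(model.predict(fv.values.to_frame().T)[0]))
        preds = np.asarray(preds)
        rates[mode] = float(np.mean(preds > 1.5 * cod_true))
        quiet_rates[mode] = float(np.mean(preds[quiet] > 20.0))
        print(
            f"{mode:>4}: {family:<15} "
            f"overestimation rate (pred > 1.5x true): {rates[mode]:.2f}   "
            f"quiet windows misread as > 20 ou/m3: {quiet_rates[mode]:.2f}"
        )
    if quiet_rates["SMAX"] > quiet_rates["SDB"]:
        print("the raw-maximum model overstates quiet periods more often, "
              "as expected of an additive interferent on raw signals")
    else:
        print("no excess raw-maximum overestimation in this draw")


if __name__ == "__main__":
    main()
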