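#!/usr/bin/env python
"""Stage 3 — pre- vs. post-bariatric-surgery simulations.

Runs the 20 mg oral dose under healthy, post-sleeve-gastrectomy and
post-one-anastomosis-gastric-bypass gut physiology, and summarizes the
changes in exposure metrics, in vivo dissolution, regional absorption and
early (0.5 h) plasma exposure.

Writes results/scenario_metrics.csv, results/scenario_deltas.csv,
results/regional_absorption.csv, per-scenario plasma profiles, and a
plasma-profile overlay figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from baripbpk import StudyConfig, early_exposure, run_study, vardenafil_fixture
from baripbpk.cli_io import write_profiles

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    drug = vardenafil_fixture().fitted()
    report = run_study(StudyConfig(drug=drug))

    print("== scenario metrics (20 mg unless noted) ==")
    print(report.metrics.round(3).to_string())
    report.metrics.to_csv(OUT / "scenario_metrics.csv")

    deltas = report.deltas_frame()
    print("\n== percent change vs pre-surgery (positive = decrease) ==")
    print(deltas.round(2).to_string(index=False))
    deltas.to_csv(OUT / "scenario_deltas.csv", index=False)

    print("\n== regional absorption (% of dose) ==")
    print(report.regional.round(2).to_string())
    report.regional.rename_axis("segment").to_csv(OUT / "regional_absorption.csv")

    print("\n== early exposure, 0.5 h post-dose (ng/mL) ==")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for scenario in ("pre_surgery", "post_sg", "post_oagb"):
        res = report.results[(scenario, 20.0)]
        prof = res.plasma_profile
        print(f"{scenario:12s}: {early_exposure(prof, 0.5):6.2f}")
        write_profiles(res, OUT / f"profiles_{scenario}_20mg")
        mask = prof.times <= 12.0
        ax.plot(prof.times[mask], prof.concentrations[mask], label=scenario)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.set_title("vardenafil 20 mg: predicted plasma profiles")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "plasma_profiles.png", dpi=150)
    print(f"\nfigure: {OUT / 'plasma_profiles.png'}")
    print("\nSleeve gastrectomy leaves exposure essentially unchanged (slightly "
          "faster peak); gastric bypass lowers and delays the peak while total "
          "absorption stays complete via the distal intestine.")


if __name__ == "__main__":
    main()
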