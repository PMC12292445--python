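#!/usr/bin/env python
"""Stage 2 — validation of the healthy-state model against clinical PK.

Simulates 10 and 20 mg oral doses in the fasted healthy state and compares
C_max, T_max and AUC(0–inf) with the observed clinical values via fold
errors (1.25-fold acceptance range) and R².  Also reports the terminal
half-life implied by the disposition micro-constants.

Writes results/validation_report.csv and results/validation_report.json.
"""

import json
from pathlib import Path

from baripbpk import (
    DispositionParams,
    StudyConfig,
    run_study,
    terminal_half_life,
    vardenafil_fixture,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    drug = vardenafil_fixture().fitted()
    t_half = terminal_half_life(DispositionParams.from_drug(drug))
    print(f"terminal half-life from micro-constants: {t_half:.2f} h")

    report = run_study(StudyConfig(drug=drug, scenarios=("pre_surgery",)))
    print("\n== healthy (pre-surgery) predictions ==")
    print(report.metrics.round(3).to_string())

    val = report.validation
    print("\n== validation vs observed clinical parameters ==")
    print(val.table.round(3).to_string(index=False))
    print(f"\nR² = {val.r_squared:.4f}; all fold errors within "
          f"[{1 / val.criterion:.2f}, {val.criterion}]: {val.all_within}")

    val.table.to_csv(OUT / "validation_report.csv", index=False)
    (OUT / "validation_report.json").write_text(json.dumps(val.to_dict(), indent=2))


if __name__ == "__main__":
    main()
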