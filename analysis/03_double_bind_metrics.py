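#!/usr/bin/env python
"""Double-bind diagnostics from the fitted parameters.

Computes, per treatment arm: the double-bind score lambda_RN - lambda_SN
(positive when NK cells preferentially kill radiation-resistant cells), the
cost of resistance r_S - r_R, and the competition-coefficient interaction
class.  Writes results/double_bind_report.json and prints the report.

Run analysis/02_fit_model.py first.
"""

import json
from pathlib import Path

from doublebind import FitSummary, analyze_summary

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary_path = OUT / "parameter_summary.json"
    if not summary_path.exists():
        raise SystemExit(f"{summary_path} missing - run analysis/02_fit_model.py")
    summary = FitSummary.from_json(summary_path)

    report = analyze_summary(summary)
    (OUT / "double_bind_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    print(report.to_text())


if __name__ == "__main__":
    main()
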