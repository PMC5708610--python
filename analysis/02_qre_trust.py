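#!/usr/bin/env python
"""Trust Game: logit QRE fits to observed trust and gratefulness.

For each session's observed average trust k* and return n*, fits the
logit precision by minimizing the Euclidean distance between the model
forecast pair (k(lam), n(lam)) and the observation, and reports the
forecasts at the fitted precision.  Writes results/table4_replica.csv.
"""

from pathlib import Path

from coopeq import run_full_analysis

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = run_full_analysis()
    OUT.mkdir(exist_ok=True)
    t4 = report.table4.round(
        {"lam": 3, "forecast_trust": 2, "forecast_grat": 2}
    )
    t4.to_csv(OUT / "table4_replica.csv", index=False)

    print("Trust Game logit fits (k* = observed trust, n* = observed return):")
    print(t4.to_string(index=False))
    print(
        f"\nMean fitted precision: {report.table4['lam'].mean():.2f} — "
        "an order of magnitude below the PD precisions of the same "
        "sessions, i.e. the QRE reads observed trust as near-chaotic play."
    )


if __name__ == "__main__":
    main()
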