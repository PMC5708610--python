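#!/usr/bin/env python
"""Pre-socialization cooperation through the QRE lens.

Inverts the symmetric logit QRE fixed point for each session's average
pre-socialization cooperation level, reproducing the published
per-session precision column, and evaluates the precision at the
series-average cooperation level.  Writes results/table2_replica.csv.
"""

from pathlib import Path

from coopeq import run_full_analysis

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = run_full_analysis()
    OUT.mkdir(exist_ok=True)
    report.table2.round({"lam": 3}).to_csv(OUT / "table2_replica.csv", index=False)

    print("Per-session QRE precision from average cooperation (before socialization):")
    print(report.table2.round({"lam": 3}).to_string(index=False))
    print(
        f"\nSeries-average cooperation {report.series['mean_cooperation']:.4f} "
        f"-> precision {report.series['lam_at_mean']:.2f}"
    )
    print(
        "All pre-socialization cooperation rates are below 0.5, so each "
        "session is rationalized by a positive logit precision: noisy "
        "best response toward defection describes the anonymous stage."
    )


if __name__ == "__main__":
    main()
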