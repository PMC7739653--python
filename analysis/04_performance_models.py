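"""Relating laboratory capacities to field skiing performance.

Per-sex Pearson correlations of each laboratory variable with biathlon-
competition skiing speed, and the two blockwise regressions (entry order
V̇O₂peak | V̇O₂@4mmol, then relative anaerobic energy contribution, then
gross efficiency) with their incremental-R² variance partitions. Writes
results/correlations.csv and results/regressions.json.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from biaperf.pipeline import run_analysis

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim-dir", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    d = args.sim_dir
    report = run_analysis(
        d / "stages.csv", d / "tt.csv", d / "athletes.csv", d / "protocol.yaml"
    )
    args.out.mkdir(parents=True, exist_ok=True)
    report.correlations.to_csv(args.out / "correlations.csv", index=False)
    regs = {
        sex: {name: dataclasses.asdict(part) for name, part in models.items()}
        for sex, models in report.regressions.items()
    }
    (args.out / "regressions.json").write_text(json.dumps(regs, indent=2))

    print("Correlations with competition skiing speed (r, p):")
    for _, r in report.correlations.iterrows():
        print(f"  {r['sex']:<7} {r['variable']:<16} r={r['r']:+.2f}  p={r['p']:.3f}")
    print("\nBlockwise regressions (incremental R² per predictor):")
    for sex, models in report.regressions.items():
        for name, part in models.items():
            inc = ", ".join(
                f"{p} {100 * dr:.0f}%"
                for p, dr in zip(part.predictors, part.delta_r2)
            )
            print(f"  {sex:<7} {name}: total R²={part.total_r2:.2f} "
                  f"(p={part.p_value:.3f}) — {inc}")
    print(f"\nwrote {args.out / 'correlations.csv'} and regressions.json")


if __name__ == "__main__":
    main()
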