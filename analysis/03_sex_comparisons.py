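"""Sex comparisons of the protocol-independent laboratory variables.

Student's t (pooled), Cohen's d with magnitude bands, and Shapiro-Wilk
normality reports. Gross efficiency, TT power and TT metabolic rates are
summarised but not tested: the two sexes skied different inclines and
distances, so those scales are not comparable. Writes
results/sex_comparison.csv and results/normality.csv.
"""

import argparse
import math
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
    report.sex_comparison.to_csv(args.out / "sex_comparison.csv", index=False)
    report.normality.to_csv(args.out / "normality.csv", index=False)

    print(f"{'variable':<16} {'F mean±SD':>14} {'M mean±SD':>14} "
          f"{'p':>7} {'ES':>6}  magnitude")
    for _, r in report.sex_comparison.iterrows():
        line = (
            f"{r['variable']:<16} "
            f"{r['female_mean']:6.1f} ± {r['female_sd']:4.1f} "
            f"{r['male_mean']:6.1f} ± {r['male_sd']:4.1f} "
        )
        if math.isfinite(r["p"]):
            line += f"{r['p']:7.3f} {r['es']:6.2f}  {r['magnitude']}"
        else:
            line += "      (protocols differ; not compared)"
        print(line)
    print(f"wrote {args.out / 'sex_comparison.csv'}")


if __name__ == "__main__":
    main()
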