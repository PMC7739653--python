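"""Simulate the study cohort: 14 female and 14 male biathletes.

Writes the three-file CSV layout (submaximal stages, time-trial series,
athlete roster with field-competition speeds) plus the per-sex treadmill
protocol constants under results/sim/.
"""

import argparse
from pathlib import Path

from biaperf.cohort import CohortConfig
from biaperf.pipeline import simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n-per-sex", type=int, default=14)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "sim")
    args = parser.parse_args()

    config = CohortConfig(n_per_sex=args.n_per_sex, seed=args.seed)
    paths = simulate(config, args.out)
    print(f"Simulated {2 * args.n_per_sex} athletes (seed {args.seed}):")
    for role, p in paths.items():
        print(f"  {role:<9} {p}")


if __name__ == "__main__":
    main()
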