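"""Generate the vertigo-like demonstration trial dataset.

112 subjects in two dose groups (50 low, 62 high), five visits at months
0, 3, 6, 9, 12, monthly attack counts from a Poisson process with
correlated subject-specific intercepts and slopes.  Writes the long-format
table to results/ and prints a short structural summary.

Usage: python analysis/01_simulate_trial_data.py [--seed 1] [--out results]
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from glmmscore import generate_vertigo_like  # noqa: E402


def main(argv=None) -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-low", type=int, default=50)
    ap.add_argument("--n-high", type=int, default=62)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args(argv)

    data = generate_vertigo_like(args.n_low, args.n_high, seed=args.seed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "vertigo_like_trial.csv"
    data.to_csv(path)

    tab = data.table
    print(f"wrote {path}: {data.n_subjects} subjects, {data.n_obs} rows")
    print(f"zero counts: {(tab['count'] == 0).mean():.1%}")
    for g, sub in tab.groupby("group"):
        m = sub.groupby("time")["count"].mean()
        arrow = " -> ".join(f"{v:.1f}" for v in m)
        print(f"group {g}: mean attacks per visit  {arrow}")
    print("Both groups start at a comparable attack rate; the high-dose "
          "group declines faster, so the treatment signal sits in the "
          "group-by-time interaction.")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
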