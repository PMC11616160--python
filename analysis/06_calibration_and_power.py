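"""Calibration and power of the Dirichlet-multinomial LRT.

Runs a null simulation (shared alpha between arms) to measure the type-I
error at p < 0.05, and planted-shift simulations to measure power at FDR <
0.05 across effect sizes.  Writes results/calibration.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from splicomp.studies import dm_null_rejection_rate, dm_power

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--null-groups", type=int, default=500)
parser.add_argument("--out", type=Path, default=Path("results/calibration.tsv"))
args = parser.parse_args()
args.out.parent.mkdir(parents=True, exist_ok=True)

rate, _ = dm_null_rejection_rate(args.seed, n_groups=args.null_groups)
rows = [("null", 0.0, rate)]
print(f"type-I error at p<0.05 over {args.null_groups} null groups: {rate:.3f}")

for delta in (0.1, 0.2, 0.3):
    power = dm_power(args.seed + 1, effect_delta_psi=delta)
    rows.append(("power", delta, power))
    print(f"power at delta-PSI {delta:.1f} (n=20+20, FDR<0.05): {power:.2f}")

pd.DataFrame(rows, columns=["study", "effect_delta_psi", "rate"]).to_csv(
    args.out, sep="\t", index=False, float_format="%.4g"
)
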