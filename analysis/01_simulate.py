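"""Simulate the study inputs: a 63-pig growth cohort, dorsal masks rendered
from the cohort's allometry, and the farm activity ledger.

Writes results/sim/{cohort.csv, weights.csv, masks/, ledger/}.
"""

import argparse
from pathlib import Path

import pandas as pd

from pigcycle.lca import EmissionFactorSet
from pigcycle.morphometrics import write_mask_png
from pigcycle.synthetic import (
    CohortSpec,
    cohort_to_frame,
    generate_cohort,
    generate_ledger,
    render_mask,
    silhouette_for_weight,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-masks", type=int, default=40)
parser.add_argument("--out", type=Path, default=Path("results/sim"))
args = parser.parse_args()

out = args.out
(out / "masks").mkdir(parents=True, exist_ok=True)

cohort = generate_cohort(CohortSpec(seed=args.seed, noise_sd_weight=3.0))
frame = cohort_to_frame(cohort)
frame.to_csv(out / "cohort.csv", index=False)

rows = frame.sample(n=args.n_masks, random_state=args.seed).reset_index(drop=True)
weights = []
for i, row in rows.iterrows():
    mask, _ = render_mask(silhouette_for_weight(row["true_weight"], seed=args.seed + i))
    write_mask_png(mask, out / "masks" / f"mask{i:04d}.png")
    weights.append({"mask_id": f"mask{i:04d}", "pig_id": row["pig_id"],
                    "day": row["day"], "observed_weight": row["observed_weight"]})
pd.DataFrame(weights).to_csv(out / "weights.csv", index=False)

generate_ledger(cohort, EmissionFactorSet(), seed=args.seed).to_csv_dir(out / "ledger")

print(f"cohort: {len(cohort)} pigs, {len(frame)} weigh-ins, "
      f"weights {frame.true_weight.min():.1f}-{frame.true_weight.max():.1f} kg")
print(f"masks:  {len(rows)} rendered to {out / 'masks'}")
print(f"ledger: feed {sum(v for v in pd.read_csv(out / 'ledger/ledger_feed.csv').tonnes):.1f} t")
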