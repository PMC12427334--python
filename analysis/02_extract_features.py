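"""Extract the five morphometric features from the simulated masks and
summarise their spread, the bridge from image to weight.

Reads results/sim/masks/; writes results/features.csv.
"""

import argparse
from pathlib import Path

from pigcycle.morphometrics import extract_directory

parser = argparse.ArgumentParser()
parser.add_argument("--masks", type=Path, default=Path("results/sim/masks"))
parser.add_argument("--out", type=Path, default=Path("results/features.csv"))
args = parser.parse_args()

table = extract_directory(args.masks)
table.to_csv(args.out, index=False)

print(f"{len(table)} masks -> {args.out}")
print(table[["RA", "CP", "BL", "BW", "E"]].describe().loc[["min", "mean", "max"]].round(3))
print("RA spans", f"{table.RA.min():.3f}-{table.RA.max():.3f}",
      "of the frame (dorsal area fraction).")
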