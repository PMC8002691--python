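"""Partition each depth's rates into fungal / bacterial / nitrification.

The chloramphenicol rate is the fungal upper limit; the remainder of the
plain ¹⁵NO₃⁻ rate is bacterial denitrification; the ¹⁵NH₄⁺ rate is
nitrification. Negative fits are floored and flagged.
"""

import argparse
from pathlib import Path

import pandas as pd

from tracern2o.io import partition_to_frame, rates_from_frame, read_profile, write_table
from tracern2o.pipeline import partition_all

parser = argparse.ArgumentParser()
parser.add_argument("--rates", type=Path, default=Path("results/rates.csv"))
parser.add_argument("--profile", type=Path, default=Path("results/sim/profile.csv"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

estimates = rates_from_frame(pd.read_csv(args.rates, float_precision="round_trip"))
profiles = partition_all(estimates, read_profile(args.profile))
frame = partition_to_frame(profiles)
write_table(frame, args.outdir / "partition.csv")

print(f"partitioned {len(frame)} depths "
      f"({int(frame['clamped'].sum())} clamped, "
      f"{int(frame['floored_inputs'].sum())} floored)")
near_interface = frame.loc[frame["o2_uM"] < 1.0]
share = 100 * near_interface["fungal_rate"] / near_interface["total_no3_rate"]
print(f"fungal share of NO3-derived N2O below the interface: "
      f"{share.min():.0f}-{share.max():.0f}%")
print(f"wrote {args.outdir}/partition.csv")
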