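"""Render the run's tables and flags into a single markdown report."""

import argparse
from pathlib import Path

import pandas as pd

from tracern2o.io import render_report

parser = argparse.ArgumentParser()
parser.add_argument("--resultsdir", type=Path, default=Path("results"))
args = parser.parse_args()

read = lambda name: (
    pd.read_csv(args.resultsdir / name, float_precision="round_trip")
    if (args.resultsdir / name).exists()
    else None
)
rates = read("rates.csv")
if rates is None:
    raise SystemExit("run 02_fit_rates.py first")
text = render_report(rates, read("partition.csv"), read("integration.csv"))
(args.resultsdir / "report.md").write_text(text)
print(f"wrote {args.resultsdir}/report.md")
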