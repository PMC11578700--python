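#!/usr/bin/env python
"""Generate the synthetic FAERS-style study dataset.

Writes the deterministic printed-count fixture (full bisphosphonate cohort,
500,000-report background universe by default) as $-delimited quarterly-style
tables plus the ground-truth ledger.  These files are the input for
02_run_pipeline.py.
"""

import argparse
from pathlib import Path

from bptox.synth import printed_counts_fixture, write_tables

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out-dir", type=Path, default=Path("scratch/data/fixture"))
parser.add_argument("--background", type=int, default=500_000)
parser.add_argument("--scaled", action="store_true", help="1/10-scale variant for quick runs")
args = parser.parse_args()

frames = printed_counts_fixture(background_n=args.background, scaled=args.scaled)
paths = write_tables(frames, args.out_dir)

ledger = frames.ledger
print(f"wrote {len(paths)} files to {args.out_dir}")
print(f"reports per drug: {ledger.groupby('drug').size().to_dict()}")
print(f"oesophageal cases per drug: {ledger.groupby('drug')['is_case'].sum().to_dict()}")
print(f"background universe: {len(frames.demo) - len(ledger)} further report rows (incl. duplicates)")
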