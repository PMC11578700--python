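#!/usr/bin/env python
"""Operating characteristics of the time-to-onset tests and the MGPS fit.

Measures the log-rank type-I error on identical lognormal onset
distributions, its power to separate three groups with the per-drug medians
and usable-record counts the pipeline reports (346/126/28 days at
n = 847/88/19), and how closely the MGPS hyperparameter fit recovers a known
generating gamma-mixture prior.
"""

import argparse
import json
from pathlib import Path

from bptox.validation import logrank_separation_power, logrank_type1_error, mgps_recovery

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/tto_mgps_checks.json"))
args = parser.parse_args()

t1 = logrank_type1_error(n_replicates=2_000, n_per_group=30, seed=args.seed)
print(f"log-rank type-I error at alpha=0.05: {100 * t1:.1f}% over 2,000 replicates")

power = logrank_separation_power(n_replicates=50, seed=args.seed)
print(f"three-group separation (medians 346/126/28, n=847/88/19): p<1e-4 in {100 * power:.0f}% of 50 replicates")

rec = mgps_recovery(n_pairs=5_000, seed=args.seed)
print(f"MGPS recovery on 5,000 simulated pairs: fitted marginal log-likelihood "
      f"{-rec.deficit:+.2f} relative to the generating prior's")

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps({
    "logrank_type1_error": t1,
    "logrank_separation_power": power,
    "mgps_loglik_true": rec.loglik_true,
    "mgps_loglik_fitted": rec.loglik_fitted,
}, indent=1) + "\n")
print(f"wrote {args.out}")
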