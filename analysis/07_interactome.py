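#!/usr/bin/env python
"""Filter AP-MS unique-peptide tables (>=2 peptides, background removal,
two-fold normalized excess in >=1 replicate) on simulated pull-downs and on
the packaged hand-checkable toy dataset."""

import argparse
import os

from chromfate.interactome import call_interactors
from chromfate.pipeline import load_toy_interactome, run_interactome_stage
from chromfate.synthetic_data import SimulationConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/interactome")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)
    res = run_interactome_stage(SimulationConfig(seed=args.seed), args.outdir)
    print(f"simulated: {res['n_candidates']} candidates "
          f"(missed {len(res['missed'])}, false {len(res['false_positives'])})")
    baits, controls, background, truth = load_toy_interactome()
    calls = call_interactors(baits, controls, background=background)
    agree = int((calls["candidate"] == truth.reindex(calls.index)).sum())
    print(f"toy fixture: {int(calls['candidate'].sum())} candidates, "
          f"{agree}/{len(truth)} agree with hand-computed truth")


if __name__ == "__main__":
    main()
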