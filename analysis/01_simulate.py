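#!/usr/bin/env python
"""Generate the full synthetic study (annotation, ChIP, peaks, ATAC,
expression, peptides) from one seed and write every summary table.

The planted truth (states, regions, fates, modules, interactors) is what
the downstream scripts score their recoveries against.
"""

import argparse

from chromfate import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/synthetic_study")
    args = ap.parse_args()
    pipeline.run_full(seed=args.seed, outdir=args.outdir)
    print(f"synthetic study written to {args.outdir}")
    print("tables: promoter states, transitions, regions, fates, ATAC, modules, interactome")


if __name__ == "__main__":
    main()
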