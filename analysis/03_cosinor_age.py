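#!/usr/bin/env python
"""Fit sex-specific Gompertz proportional-hazards models (rhythm + age, and age
only), solve the 5-year risk equality for biological age, and label
accelerated aging (AA = BA - CA > 0); writes aging.csv and models.json.

Requires the upstream artifacts in results/pipeline/ (run the earlier
numbered scripts first).
"""

import argparse

from rhythmage.pipeline import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=2000)
    ap.add_argument("--out", default="results/pipeline")
    args = ap.parse_args()
    run_pipeline(RunConfig(n_subjects=args.n, seed=args.seed,
                           outdir=args.out, stages=["cosinorage"]))
    print("stage 'cosinorage' artifacts written to", args.out)


if __name__ == "__main__":
    main()
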