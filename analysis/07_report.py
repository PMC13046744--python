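#!/usr/bin/env python
"""Summarise the cohort: median/IQR and N(%) descriptives with rank-sum/chi-
square split comparisons, plus age-acceleration stratum medians of MVPA and
IS.

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
                           outdir=args.out, stages=["report"]))
    print("stage 'report' artifacts written to", args.out)


if __name__ == "__main__":
    main()
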