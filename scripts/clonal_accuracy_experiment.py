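#!/usr/bin/env python
"""Clonal-frame recovery accuracy across recombination rates.

Full-scale harness: simulates whole genomes over a grid of within-species
recombination rates, infers trees by neighbour joining, UPGMA and (when a
``fasttree`` binary is on PATH) maximum likelihood, and scores
Robinson-Foulds branch accuracy against the true clonal frame, overall and
split into old / middle-aged / young branches (root-to-midpoint distance
thresholds 1.32 and 2.09 N_e generations).

At the published operating point -- 1 Mbp genomes, theta = 0.01, rates up
to R = 0.1 -- ML recovery of the clonal frame degrades to roughly 91 %,
with old branches hardest to recover.  The sample size behind that figure
is not on record, so it is exposed here as a knob (default 15).  A full
1 Mbp run takes hours; the defaults below are the scaled-down setting used
by the test suite, and ``--full`` switches to 1 Mbp with 10 replicates at
R = 0.1.

Usage:
    python scripts/clonal_accuracy_experiment.py --seed 1 --out results.tsv
    python scripts/clonal_accuracy_experiment.py --full --seed 1 --out results.tsv
"""

from __future__ import annotations

import argparse
import csv
import sys

import numpy as np

from bacsim.oracle import ExperimentConfig, run_clonal_recovery_experiment


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="-")
    ap.add_argument("--samples", type=int, default=15)
    ap.add_argument("--length", type=int, default=50_000)
    ap.add_argument("--reps", type=int, default=50)
    ap.add_argument("--rates", type=float, nargs="+",
                    default=[0.0, 0.01, 0.1])
    ap.add_argument("--methods", nargs="+", default=["nj", "upgma", "ml"])
    ap.add_argument("--full", action="store_true",
                    help="1 Mbp genomes, 10 replicates (long-running)")
    args = ap.parse_args()
    if args.full:
        args.length = 1_000_000
        args.reps = 10
    cfg = ExperimentConfig(r_grid=tuple(args.rates), n_reps=args.reps,
                           n=args.samples, genome_length=args.length,
                           theta=0.01, delta=500.0,
                           methods=tuple(args.methods))
    rows = run_clonal_recovery_experiment(cfg, np.random.default_rng(args.seed))
    out = sys.stdout if args.out == "-" else open(args.out, "w", newline="")
    writer = csv.DictWriter(out, fieldnames=["R", "method", "age_class",
                                             "mean_accuracy", "sd",
                                             "n_reps"], delimiter="\t")
    writer.writeheader()
    for row in rows:
        writer.writerow(row)
    if out is not sys.stdout:
        out.close()
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
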