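#!/usr/bin/env python
"""Simulate iterative REPSA-style selection and emit a late-round read
pool.

Two complementary simulations:

1. Selection dynamics at desk scale: a pool of a few thousand random
   24-bp cassettes under seven rounds of bind/cleave/amplify pressure
   with a short palindromic motif (a 16-mer has essentially no true
   sites in so small a random pool, so a 6-mer stands in to exhibit the
   dynamics), including a trace amount of enzyme-A-resistant
   contaminant that sweeps under enzyme A and is purged after the
   switch to enzyme B.

2. A late-round read pool for motif discovery: 1000 reads with the
   16-mer consensus planted in 60% of cassettes, written as FASTA for
   the downstream scripts.

Outputs: results/selection_trajectory.tsv, results/round7_reads.fasta
"""

import argparse
from pathlib import Path

import pandas as pd

from tfdissect.datasets import CONSENSUS
from tfdissect.io import write_fasta
from tfdissect.simulate import (RepsaRoundConfig, SelectionLibraryConfig,
                                planted_read_pool, simulate_selection)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    import numpy as np
    from tfdissect.pwm import PositionWeightMatrix, encode
    short = "TGTACA"
    counts = np.zeros((len(short), 4))
    counts[np.arange(len(short)), encode(short)] = 8
    motif = PositionWeightMatrix.from_counts(counts)

    cfg = RepsaRoundConfig(resistant_fraction=0.001,
                           rounds=("A", "A", "A", "A", "B", "B", "B"))
    res = simulate_selection(
        SelectionLibraryConfig(pool_size=4000, seed=args.seed), cfg, motif)
    traj = pd.DataFrame({
        "round": range(len(res.motif_bearing_fraction)),
        "enzyme": ("input",) + cfg.rounds,
        "motif_bearing_fraction": res.motif_bearing_fraction,
        "enzymeA_resistant_fraction": res.resistant_fraction,
    })
    traj.to_csv(args.out / "selection_trajectory.tsv", sep="\t",
                index=False)
    print(traj.to_string(index=False))
    print(f"\nmotif-bearing fraction rose from "
          f"{traj.motif_bearing_fraction.iloc[0]:.3f} to "
          f"{traj.motif_bearing_fraction.iloc[-1]:.3f}; the resistant "
          f"contaminant peaked at round 4 "
          f"({traj.enzymeA_resistant_fraction.iloc[4]:.3f}) and fell to "
          f"{traj.enzymeA_resistant_fraction.iloc[-1]:.4f} after the "
          f"enzyme switch.")

    reads, planted = planted_read_pool(CONSENSUS, 1000, 0.6,
                                       seed=args.seed + 1)
    write_fasta(args.out / "round7_reads.fasta",
                [(f"read{i+1}", r) for i, r in enumerate(reads)])
    print(f"\nwrote 1000 late-round reads "
          f"({planted.sum()} motif-bearing) to round7_reads.fasta")


if __name__ == "__main__":
    main()
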