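#!/usr/bin/env python
"""Two-group expression comparison on a synthetic 3-vs-3 design.

Emulates the regulator-deficient vs wild-type microarray comparison:
200 genes, one strongly induced single-unit gene planted at
logFC +2.62, a 14-gene operon block planted uniformly up (+1.3), a
4-gene block planted down (−2.5), and null background. Runs Welch
t-tests with BH correction, aggregates to operons, and partitions
affected genes by direction.

Outputs: results/dge.tsv, results/operon_summary.tsv
"""

import argparse
from pathlib import Path

from tfdissect.expression import (affected_gene_report,
                                  differential_expression,
                                  operon_summarize, to_frame)
from tfdissect.simulate import ExpressionSimSpec, simulate_expression


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    planted = {"gene0000": 2.62}
    operon_map = {"gene0000": "induced_single"}
    for i in range(1, 15):                      # 14-gene up operon
        planted[f"gene{i:04d}"] = 1.3
        operon_map[f"gene{i:04d}"] = "respiratory_block"
    for i in range(15, 19):                     # 4-gene down operon
        planted[f"gene{i:04d}"] = -2.5
        operon_map[f"gene{i:04d}"] = "transporter_block"

    matrix = simulate_expression(ExpressionSimSpec(
        n_genes=200, planted_logfc=planted, noise_sd=0.2,
        seed=args.seed))
    rows = differential_expression(matrix, operon_map=operon_map)
    to_frame(rows).to_csv(args.out / "dge.tsv", sep="\t", index=False)

    top = max(rows, key=lambda r: r.logfc)
    print(f"strongest induction: {top.gene_id} "
          f"logFC {top.logfc:+.2f} (adj p {top.adj_p:.2e}); "
          f"planted +2.62")

    summary = operon_summarize(rows)
    summary.to_csv(args.out / "operon_summary.tsv", sep="\t",
                   index=False)
    named = summary[summary["operon"] != "unmapped"]
    print(named.to_string(index=False))

    rep = affected_gene_report(rows, logfc_threshold=1.0,
                               adjp_threshold=0.05)
    print(f"\naffected genes: {rep['n_affected']} "
          f"({100*rep['fraction_up']:.0f}% up, "
          f"{100*rep['fraction_down']:.0f}% down); planted 15 up of "
          f"19 affected (79%/21%).")


if __name__ == "__main__":
    main()
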