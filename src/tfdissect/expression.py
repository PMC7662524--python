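"""Two-group differential expression with FDR control and
operon-level aggregation.

Intended for small-n microarray-style designs (e.g. 3 deficient-strain
vs 3 wild-type samples on a log2 scale): per-gene log fold-change is a
difference of group means, significance a two-sided Welch t-test, and
multiple testing is handled with Benjamini–Hochberg. Note this is a
plain (unmoderated) t-test; empirical-Bayes variance moderation as in
limma shifts p-values slightly at n=3 and is deliberately not
replicated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import benjamini_hochberg


@dataclass(frozen=True)
class DGERow:
    gene_id: str
    logfc: float            # test - control, log2 scale
    p_value: float
    adj_p: float
    operon_id: str | None = None


def _split_groups(matrix: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray]:
    groups = matrix.columns.get_level_values("group")
    test = matrix.loc[:, groups == "test"].to_numpy()
    control = matrix.loc[:, groups == "control"].to_numpy()
    if test.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    return test, control


def differential_expression(matrix: pd.DataFrame,
                            operon_map: dict | None = None
                            ) -> list[DGERow]:
    """Per-gene logFC, Welch p-value and BH-adjusted p-value.

    ``matrix`` is genes x samples with a (sample_id, group) column
    MultiIndex, group in {test, control}, values on the log2 scale.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    test, control = _split_groups(matrix)
    logfc = test.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(test, control, axis=1, equal_var=False)
    p = np.asarray(p)
    degenerate = np.isnan(p)
    # zero variance both groups: p=1 if means equal, else effectively 0
    p[degenerate & (logfc == 0)] = 1.0
    p[degenerate & (logfc != 0)] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = benjamini_hochberg(p)
    operon_map = operon_map or {}
    return [DGERow(str(g), float(l), float(pv), float(q),
                   operon_map.get(g))
            for g, l, pv, q in zip(matrix.index, logfc, p, adj)]


def to_frame(rows: list[DGERow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "operon_id": r.operon_id,
          "logfc": r.logfc, "p_value": r.p_value, "adj_p": r.adj_p}
         for r in rows])


def operon_summarize(rows: list[DGERow],
                     operon_map: dict | None = None) -> pd.DataFrame:
    """Aggregate gene-level results to operons.

    Per operon: member count, median logFC, direction (up iff median
    > 0), and the fraction of members significant at adj_p < 0.05.
    Genes missing from the map are grouped under "unmapped".
    """
    recs = []
    for r in rows:
        op = r.operon_id
        if op is None and operon_map is not None:
            op = operon_map.get(r.gene_id)
        recs.append({"operon": op if op is not None else "unmapped",
                     "logfc": r.logfc, "sig": r.adj_p < 0.05})
    df = pd.DataFrame(recs)
    out = df.groupby("operon").agg(
        n_members=("logfc", "size"),
        median_logfc=("logfc", "median"),
        fraction_significant=("sig", "mean"))
    out["direction"] = np.where(out["median_logfc"] > 0, "up", "down")
    return out.reset_index()


def affected_gene_report(rows: list[DGERow],
                         logfc_threshold: float = 1.0,
                         adjp_threshold: float = 0.05) -> dict:
    """Partition genes into up / down / unchanged.

    A gene is affected when |logFC| >= logfc_threshold and
    adj_p <= adjp_threshold; direction follows the sign of logFC.
    Reports the member lists, counts, and up/down fractions among
    affected genes.
    """
    if logfc_threshold <= 0 or adjp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    up = [r.gene_id for r in rows
          if r.logfc >= logfc_threshold and r.adj_p <= adjp_threshold]
    down = [r.gene_id for r in rows
            if r.logfc <= -logfc_threshold and r.adj_p <= adjp_threshold]
    affected = len(up) + len(down)
    unchanged = [r.gene_id for r in rows
                 if r.gene_id not in set(up) | set(down)]
    return {
        "upregulated": up,
        "downregulated": down,
        "unchanged": unchanged,
        "n_affected": affected,
        "fraction_up": len(up) / affected if affected else float("nan"),
        "fraction_down": len(down) / affected if affected else float("nan"),
    }
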