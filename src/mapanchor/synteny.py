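"""Reciprocal-best-hit homolog pairing and inter-genome collinearity.

Two all-vs-all protein similarity tables (12-column tabular alignment
format) are reduced to putative ortholog pairs: (a, b) is kept iff b is a's
highest-scoring hit and a is b's, both passing the e-value ceiling.  Paired
genes are then binned by chromosome pair, and per chromosome pair the
Spearman correlation of gene midpoints is reported as an absolute value
(relative orientation of chromosomes is arbitrary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_E_MAX = 1e-7


def _best_hits(hits: pd.DataFrame, e_max: float) -> dict[str, str]:
    """query -> best subject by (higher bitscore, lower e-value, lexicographic
    subject id)."""
    ok = hits[hits["evalue"] <= e_max]
    if ok.empty:
        return {}
    ranked = ok.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    first = ranked.drop_duplicates("query", keep="first")
    return dict(zip(first["query"], first["subject"]))


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, e_max: float = DEFAULT_E_MAX
) -> pd.DataFrame:
    """Mutual-best pairs between genomes A and B; columns gene_a, gene_b."""
    best_ab = _best_hits(hits_ab, e_max)
    best_ba = _best_hits(hits_ba, e_max)
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    pairs.sort()
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def chromosome_correspondence(
    pairs: pd.DataFrame,
    pos_a: pd.DataFrame,
    pos_b: pd.DataFrame,
) -> pd.DataFrame:
    """Per (chromA, chromB): homolog-pair count and |Spearman rho| of gene
    midpoints (NaN below 2 pairs).  Position frames need columns gene,
    chrom, midpoint."""
    pa = pos_a.set_index("gene")
    pb = pos_b.set_index("gene")
    missing = [g for g in pairs["gene_a"] if g not in pa.index]
    missing += [g for g in pairs["gene_b"] if g not in pb.index]
    if missing:
        raise KeyError(f"positions missing for genes {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    df = pairs.copy()
    df["chrom_a"] = pa.loc[df["gene_a"], "chrom"].to_numpy()
    df["mid_a"] = pa.loc[df["gene_a"], "midpoint"].to_numpy()
    df["chrom_b"] = pb.loc[df["gene_b"], "chrom"].to_numpy()
    df["mid_b"] = pb.loc[df["gene_b"], "midpoint"].to_numpy()

    rows = []
    for (ca, cb), grp in df.groupby(["chrom_a", "chrom_b"], sort=True):
        if len(grp) >= 2 and grp["mid_a"].nunique() > 1 and grp["mid_b"].nunique() > 1:
            rho = abs(float(stats.spearmanr(grp["mid_a"], grp["mid_b"]).statistic))
        else:
            rho = float("nan")
        rows.append((ca, cb, len(grp), rho))
    return pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "n_pairs", "abs_rho"])


def dominant_partners(correspondence: pd.DataFrame) -> pd.DataFrame:
    """For each chromosome of genome A, the genome-B chromosome holding the
    most homolog pairs."""
    idx = correspondence.groupby("chrom_a")["n_pairs"].idxmax()
    out = correspondence.loc[idx, ["chrom_a", "chrom_b", "n_pairs", "abs_rho"]]
    return out.reset_index(drop=True)


def dotplot_table(
    pairs: pd.DataFrame, pos_a: pd.DataFrame, pos_b: pd.DataFrame
) -> pd.DataFrame:
    """Midpoint coordinates of every pair, for external plotting."""
    pa = pos_a.set_index("gene")
    pb = pos_b.set_index("gene")
    return pd.DataFrame({
        "gene_a": pairs["gene_a"],
        "chrom_a": pa.loc[pairs["gene_a"], "chrom"].to_numpy(),
        "mid_a": pa.loc[pairs["gene_a"], "midpoint"].to_numpy(),
        "gene_b": pairs["gene_b"],
        "chrom_b": pb.loc[pairs["gene_b"], "chrom"].to_numpy(),
        "mid_b": pb.loc[pairs["gene_b"], "midpoint"].to_numpy(),
    })
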