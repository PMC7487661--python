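"""Differential expression: per-gene t-tests, BH FDR and consensus calling.

Expression tables are genes x samples on the log2 scale, with columns
named ``sample:group``.  Differential genes are called in two case-vs-
normal comparisons (primary tumour and metastasis) and the final list is
the consensus of both comparisons intersected with an external evidence
list carrying per-gene directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tfnetminer.io import expression_groups


@dataclass(frozen=True)
class EvidenceList:
    """(gene, direction) pairs from an external differential-expression source."""

    directions: dict  # gene_id -> "up" | "down"

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceList":
        dirs: dict[str, str] = {}
        for gene, direction in zip(df["gene_id"], df["direction"]):
            if direction not in ("up", "down"):
                raise ValueError(f"evidence direction {direction!r} for {gene}")
            if dirs.get(gene, direction) != direction:
                raise ValueError(f"conflicting evidence directions for {gene}")
            dirs[gene] = direction
        return cls(dirs)


def per_gene_ttest(
    expr: pd.DataFrame,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided per-gene t-test of ``group_b`` (case) vs ``group_a`` (normal).

    Welch by default (``equal_var=False``).  Genes with zero variance in
    both groups get p = 1 when the means are equal (inert) and p = 0
    otherwise.  Direction is "up" when mean_case >= mean_normal.

    Returns a frame indexed by gene with columns mean_normal, mean_case,
    t, p, direction.
    """
    groups = expression_groups(expr)
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"group label {g!r} absent from expression columns")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    a = expr[groups[group_a]].to_numpy(dtype=float)
    b = expr[groups[group_b]].to_numpy(dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.where(degenerate & (mean_a != mean_b), 0.0, p)
    t = np.where(degenerate, 0.0, t)
    return pd.DataFrame(
        {
            "mean_normal": mean_a,
            "mean_case": mean_b,
            "t": t,
            "p": p,
            "direction": np.where(mean_b >= mean_a, "up", "down"),
        },
        index=expr.index,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(expr: pd.DataFrame, normal: str = "normal",
             case_groups: tuple[str, str] = ("primary", "metastasis"),
             equal_var: bool = False) -> pd.DataFrame:
    """Both comparisons with BH columns, one row per gene."""
    frames = {}
    for case in case_groups:
        res = per_gene_ttest(expr, normal, case, equal_var=equal_var)
        res["q"] = bh_adjust(res["p"].to_numpy())
        frames[case] = res
    out = pd.DataFrame(index=expr.index)
    for case, tag in zip(case_groups, ("primary", "met")):
        out[f"p_{tag}"] = frames[case]["p"]
        out[f"q_{tag}"] = frames[case]["q"]
        out[f"direction_{tag}"] = frames[case]["direction"]
    return out


def consensus_de(
    de_primary: pd.DataFrame,
    de_metastasis: pd.DataFrame,
    evidence: EvidenceList,
    alpha: float = 0.05,
    mode: str = "both",
) -> tuple[list[str], list[str]]:
    """Consensus up/down gene lists.

    ``mode="both"`` (default, strict): a gene must satisfy q < ``alpha``
    with a consistent direction in both comparisons.  ``mode="either"``
    relaxes to one comparison.  In all modes the gene must appear in the
    evidence list with the same direction.  Both output lists are sorted
    by gene id.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    if not de_primary.index.equals(de_metastasis.index):
        raise ValueError("comparisons cover different gene universes")
    up, down = [], []
    for frame in (de_primary, de_metastasis):
        if "q" not in frame.columns:
            raise ValueError("DE frames must carry BH-adjusted q values")
    sig_p = de_primary["q"] < alpha
    sig_m = de_metastasis["q"] < alpha
    same_dir = de_primary["direction"] == de_metastasis["direction"]
    for gene in de_primary.index:
        ev_dir = evidence.directions.get(gene)
        if ev_dir is None:
            continue
        if mode == "both":
            ok = sig_p[gene] and sig_m[gene] and same_dir[gene]
            direction = de_primary.at[gene, "direction"]
        else:
            if sig_p[gene] and sig_m[gene] and not same_dir[gene]:
                continue  # significant both ways with conflicting directions
            ok = sig_p[gene] or sig_m[gene]
            direction = (
                de_primary.at[gene, "direction"] if sig_p[gene]
                else de_metastasis.at[gene, "direction"]
            )
        if ok and direction == ev_dir:
            (up if direction == "up" else down).append(gene)
    return sorted(up), sorted(down)
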