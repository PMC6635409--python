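"""Differential expression and co-expression calls per cancer.

A gene is differentially expressed (DEG) when |log2 fold change| >= 1 and
the BH-adjusted two-sided P value is <= 0.05.  Two DEGs form a co-expressed
pair when |Pearson r| over tumor samples reaches the effect-size threshold
h (default 0.5).

The per-gene test is Welch's two-sample t on the log2 values; the fold
change is mean(tumor) - mean(normal) on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger("campnets")

LOG2FC_MIN = 1.0
PADJ_MAX = 0.05
#: "large effect size" co-expression threshold on |Pearson r|
COEXPR_H = 0.5
#: minimum shared samples for a correlation
MIN_SHARED_SAMPLES = 3


@dataclass
class DEGTable:
    """Per-gene differential-expression results.

    ``table`` columns: gene, log2fc, p, p_adj, direction (up|down), is_deg.
    """

    table: pd.DataFrame

    @property
    def degs(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["is_deg"], "gene"])

    def direction(self, gene: str) -> str:
        row = self.table.loc[self.table["gene"] == gene]
        return str(row["direction"].iloc[0])


@dataclass
class CoexpressionPairSet:
    """Unordered co-expressed gene pairs with their correlations."""

    pairs: dict[frozenset[str], float]
    h: float = COEXPR_H

    def __post_init__(self) -> None:
        for pair, r in self.pairs.items():
            if len(pair) != 2:
                raise ValueError(f"self-pair or malformed pair: {set(pair)}")
            if abs(r) < self.h:
                raise ValueError(f"pair {set(pair)} with |r|={abs(r):.3f} < h={self.h}")

    def __contains__(self, pair: Iterable[str]) -> bool:
        return frozenset(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def neighbors(self) -> dict[str, frozenset[str]]:
        """Gene -> set of genes it is co-expressed with (cached)."""
        cached = getattr(self, "_neighbors", None)
        if cached is None:
            nbrs: dict[str, set[str]] = {}
            for pair in self.pairs:
                a, b = tuple(pair)
                nbrs.setdefault(a, set()).add(b)
                nbrs.setdefault(b, set()).add(a)
            cached = {g: frozenset(v) for g, v in nbrs.items()}
            object.__setattr__(self, "_neighbors", cached)
        return cached


def call_degs(expr: ExpressionMatrix,
              log2fc_min: float = LOG2FC_MIN,
              padj_max: float = PADJ_MAX) -> DEGTable:
    """Welch two-sample test per gene with BH adjustment across all genes.

    Requires at least two tumor and two normal samples.  A gene with zero
    variance in both groups gets p = 1 (its fold change is still reported).
    """
    tumor = expr.tumor().to_numpy(dtype=float)
    normal = expr.normal().to_numpy(dtype=float)
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >=2 tumor and >=2 normal samples")
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    zero_var = (tumor.var(axis=1) == 0) & (normal.var(axis=1) == 0)
    p = np.where(np.isnan(p) | zero_var, 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    is_deg = (np.abs(log2fc) >= log2fc_min) & (p_adj <= padj_max)
    table = pd.DataFrame({
        "gene": expr.genes,
        "log2fc": log2fc,
        "p": p,
        "p_adj": p_adj,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "is_deg": is_deg,
    })
    return DEGTable(table=table)


def coexpressed_pairs(expr_tumor: pd.DataFrame,
                      genes_a: Iterable[str],
                      genes_b: Iterable[str],
                      h: float = COEXPR_H) -> CoexpressionPairSet:
    """Pearson co-expression between two gene lists over tumor samples.

    Every cross pair (a, b) with a != b is tested; pairs with |r| >= h are
    retained.  Constant genes yield an undefined correlation and are
    skipped with a logged count.  Needs at least three tumor samples.
    """
    genes_a = sorted(set(genes_a))
    genes_b = sorted(set(genes_b))
    missing = (set(genes_a) | set(genes_b)) - set(expr_tumor.index)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    if expr_tumor.shape[1] < MIN_SHARED_SAMPLES:
        raise ValueError(f"need >= {MIN_SHARED_SAMPLES} tumor samples")
    values = expr_tumor.loc[sorted(set(genes_a) | set(genes_b))]
    constant = set(values.index[values.std(axis=1, ddof=0) == 0])
    if constant:
        logger.warning("coexpressed_pairs: %d constant genes skipped", len(constant))
    corr = values.T.corr(method="pearson")
    pairs: dict[frozenset[str], float] = {}
    for a in genes_a:
        if a in constant:
            continue
        for b in genes_b:
            if b == a or b in constant:
                continue
            r = float(corr.at[a, b])
            if abs(r) >= h:
                pairs[frozenset((a, b))] = r
    return CoexpressionPairSet(pairs=pairs, h=h)


def all_coexpressed_pairs(expr_tumor: pd.DataFrame,
                          genes: Iterable[str],
                          h: float = COEXPR_H) -> CoexpressionPairSet:
    """All within-list co-expressed pairs (convenience for the M universe)."""
    genes = sorted(set(genes))
    return coexpressed_pairs(expr_tumor, genes, genes, h=h)
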