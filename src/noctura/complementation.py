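"""Modified quantitative complementation test (QCT) for candidate genes.

Natural alleles from nocturnal (N*), diurnal (D*) and control (C*) isogenic
backgrounds are each crossed over a mutant allele of a candidate gene; if the
backgrounds carry functionally different alleles at that gene, the mutant
cross fails to mask them and the ND-ratio distributions of the three crosses
diverge.  The analysis compares the three mutant-allele crosses with a
Kruskal–Wallis rank test (df = 2) and all pairwise two-sample
Kolmogorov–Smirnov tests, and issues a verdict:

* ``complemented`` — the crosses order D* < C* < N* in mean ND ratio, the
  N*-vs-D* KS test is significant and the KW test is significant (the
  confirmation pattern);
* ``failed_to_complement`` — significance without that ordering pattern;
* ``inconclusive`` — everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BACKGROUNDS = ("N*", "D*", "C*")
ALLELES = ("mutant", "control")


@dataclass
class QCTTable:
    """ND ratios by (background, allele) cell for one candidate gene."""

    gene: str
    cells: dict[tuple[str, str], np.ndarray]
    min_per_cell: int = 5

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], np.ndarray] = {}
        for (bg, allele), values in self.cells.items():
            if bg not in BACKGROUNDS:
                raise ValueError(f"unknown background {bg!r}")
            if allele not in ALLELES:
                raise ValueError(f"unknown allele class {allele!r}")
            arr = np.asarray(values, dtype=float)
            if arr.size < self.min_per_cell:
                raise ValueError(
                    f"cell ({bg}, {allele}) has {arr.size} flies; "
                    f"floor is {self.min_per_cell}"
                )
            clean[(bg, allele)] = arr
        backgrounds = {bg for bg, _ in clean}
        if len(backgrounds) < 2:
            raise ValueError("need at least two backgrounds")
        self.cells = clean

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene: str | None = None,
                       min_per_cell: int = 5) -> "QCTTable":
        """Build from a long table with columns gene, background, allele, nd_ratio."""
        required = {"background", "allele", "nd_ratio"}
        if missing := required - set(df.columns):
            raise ValueError(f"missing columns: {sorted(missing)}")
        if gene is not None and "gene" in df.columns:
            df = df[df["gene"] == gene]
        name = gene or (str(df["gene"].iloc[0]) if "gene" in df.columns else "?")
        cells = {
            (bg, allele): sub["nd_ratio"].to_numpy(dtype=float)
            for (bg, allele), sub in df.groupby(["background", "allele"])
        }
        return cls(gene=name, cells=cells, min_per_cell=min_per_cell)


@dataclass
class QCTResult:
    gene: str
    kw_stat: float
    kw_df: int
    kw_p: float
    ks_D: pd.DataFrame
    ks_p: pd.DataFrame
    ks_p_adj: pd.DataFrame
    cross_means: dict[str, float]
    ordering_ok: bool
    verdict: str
    alpha: float = 0.05

    def ks_matrix(self) -> pd.DataFrame:
        """Combined matrix with p-values in the top half, D in the bottom half."""
        out = pd.DataFrame(
            np.nan, index=list(BACKGROUNDS), columns=list(BACKGROUNDS)
        )
        for i, a in enumerate(BACKGROUNDS):
            for j, b in enumerate(BACKGROUNDS):
                if i < j:
                    out.loc[a, b] = self.ks_p.loc[a, b]
                elif i > j:
                    out.loc[a, b] = self.ks_D.loc[a, b]
        return out


def _pairwise_ks(groups: Mapping[str, np.ndarray], exact_max_n: int = 25
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    names = list(groups)
    d = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = groups[a], groups[b]
            method = "exact" if max(x.size, y.size) <= exact_max_n else "asymp"
            res = stats.ks_2samp(x, y, method=method)
            d.loc[a, b] = d.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return d, p


def qct_test(table: QCTTable, alpha: float = 0.05) -> QCTResult:
    """Run the complementation analysis on the mutant-allele crosses.

    Requires mutant cells for all of N*, D* and C*.  Ties-only cells are
    handled by the KS test's tie-aware empirical CDFs (with a warning).
    """
    groups: dict[str, np.ndarray] = {}
    for bg in BACKGROUNDS:
        key = (bg, "mutant")
        if key not in table.cells:
            raise ValueError(f"missing mutant-allele cell for background {bg}")
        groups[bg] = table.cells[key]
        if np.ptp(groups[bg]) == 0:
            logger.warning("%s: cell (%s, mutant) is ties-only", table.gene, bg)
    kw_stat, kw_p = stats.kruskal(*groups.values())
    kw_df = len(groups) - 1
    ks_d, ks_p = _pairwise_ks(groups)
    flat = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            flat.append(((a, b), ks_p.loc[a, b]))
    adj = multipletests([v for _, v in flat], method="fdr_bh")[1]
    ks_p_adj = ks_p.copy()
    for ((a, b), _), q in zip(flat, adj):
        ks_p_adj.loc[a, b] = ks_p_adj.loc[b, a] = q
    means = {bg: float(v.mean()) for bg, v in groups.items()}
    ordering_ok = means["D*"] < means["C*"] < means["N*"]
    ks_nd_sig = ks_p.loc["N*", "D*"] < alpha
    kw_sig = kw_p < alpha
    if ordering_ok and ks_nd_sig and kw_sig:
        verdict = "complemented"
    elif (kw_sig or ks_nd_sig) and not ordering_ok:
        verdict = "failed_to_complement"
    else:
        verdict = "inconclusive"
    return QCTResult(
        gene=table.gene,
        kw_stat=float(kw_stat),
        kw_df=kw_df,
        kw_p=float(kw_p),
        ks_D=ks_d,
        ks_p=ks_p,
        ks_p_adj=ks_p_adj,
        cross_means=means,
        ordering_ok=bool(ordering_ok),
        verdict=verdict,
        alpha=alpha,
    )
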