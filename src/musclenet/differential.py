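"""Per-stage DE and MA statistics, cumulative DE, developmental-regulation
scores, PIF, and extreme-slice rankings.

Conventions (used everywhere downstream):

* ``d`` — differential expression, BA minus CH, log2 scale;
* ``a`` — average abundance, (BA + CH)/2, log2 scale;
* ``pif`` — phenotypic impact factor, ``a * d`` (log2^2 scale), which
  emphasizes genes that are both abundant and differential and de-emphasizes
  lowly expressed genes near the detection limit;
* cumulative DE — the sum of |d| over the stages where d is available;
* developmental-regulation score — the standard deviation of a gene's four
  stage means within one breed.

These are ranking devices, not significance tests: the study design (2-3
biological replicates per treatment) supports ordering genes, and the
analysis works on the extremes of the ranked lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BREEDS, STAGES

#: the study's MA plotting threshold; |d| must strictly exceed it
DEFAULT_MA_THRESHOLD = 0.5


@dataclass
class DiffTable:
    """Per-row, per-stage abundance ``a`` and contrast ``d`` (BA - CH).

    Both frames share an index (probe or gene) and have one column per
    stage.  A stage missing either breed's treatment mean is missing in
    both ``a`` and ``d``.
    """

    a: pd.DataFrame
    d: pd.DataFrame

    @property
    def pif(self) -> pd.DataFrame:
        """Phenotypic impact factor, abundance x contrast, per stage."""
        return self.a * self.d

    @property
    def index(self) -> pd.Index:
        return self.d.index

    def mean_d(self) -> pd.Series:
        """Contrast averaged over available stages (used as d_j in RIF)."""
        return self.d.mean(axis=1)

    def mean_pif(self) -> pd.Series:
        return self.pif.mean(axis=1)


def compute_diff(means: pd.DataFrame) -> DiffTable:
    """Derive (a, d) per stage from an 8-treatment mean table.

    ``d(g, s) = mean_BA(g, s) - mean_CH(g, s)``;
    ``a(g, s) = (mean_BA + mean_CH) / 2``.
    """
    ba, ch = means["BA"], means["CH"]
    stages = [s for s in STAGES if s in ba.columns and s in ch.columns]
    d = ba[stages] - ch[stages]
    a = (ba[stages] + ch[stages]) / 2.0
    return DiffTable(a=a, d=d)


def fold_change(log2_diff: float) -> float:
    """Linear-scale fold change equivalent of a log2 difference."""
    return float(2.0 ** log2_diff)


def ma_filter(diff: DiffTable, stage: int, threshold: float = DEFAULT_MA_THRESHOLD) -> pd.Index:
    """Rows with |d| strictly greater than ``threshold`` at ``stage``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    d = diff.d[stage]
    return d.index[d.abs() > threshold]


def cumulative_de(diff: DiffTable, min_stages: int = 3) -> pd.DataFrame:
    """Sum |d| over available stages and rank on the sum, descending.

    Rows with fewer than ``min_stages`` available stages get no cumulative
    score (the study likewise excluded genes with missing values at some
    stages from its ranked table) and sort last. Ties break stably by row
    id. Columns: ``cum_de``, ``n_stages``, ``rank``.
    """
    absd = diff.d.abs()
    n_avail = absd.notna().sum(axis=1)
    cum = absd.sum(axis=1, min_count=1)
    cum[n_avail < min_stages] = np.nan
    out = pd.DataFrame({"cum_de": cum, "n_stages": n_avail})
    # sort by id first, then stable-sort on the score: ties break by row id
    out = out.sort_index(kind="mergesort").sort_values(
        "cum_de", ascending=False, kind="mergesort", na_position="last")
    ranks = np.full(len(out), np.nan)
    scored = out["cum_de"].notna()
    ranks[: int(scored.sum())] = np.arange(1, int(scored.sum()) + 1)
    out["rank"] = ranks
    return out


def devreg_score(means: pd.DataFrame, breed: str = "BA", ddof: int = 1) -> pd.DataFrame:
    """Developmental regulation: SD of the four stage means within a breed.

    Sample SD (``ddof=1``) by default over the stages present; rows with
    fewer than 2 available stage means get no score and rank last. Columns:
    ``devreg``, ``n_stages``, ``rank``.
    """
    if breed not in BREEDS:
        raise ValueError(f"unknown breed {breed!r}")
    block = means[breed]
    n_avail = block.notna().sum(axis=1)
    sd = block.std(axis=1, ddof=ddof)
    sd[n_avail < 2] = np.nan
    out = pd.DataFrame({"devreg": sd, "n_stages": n_avail})
    out = out.sort_index(kind="mergesort").sort_values(
        "devreg", ascending=False, kind="mergesort", na_position="last")
    ranks = np.full(len(out), np.nan)
    scored = out["devreg"].notna()
    ranks[: int(scored.sum())] = np.arange(1, int(scored.sum()) + 1)
    out["rank"] = ranks
    return out


def pif_table(diff: DiffTable, stage: int) -> pd.DataFrame:
    """Per-row ``a``, ``d`` and ``pif`` at one stage, sorted by pif descending."""
    out = pd.DataFrame({"a": diff.a[stage], "d": diff.d[stage],
                        "pif": diff.pif[stage]})
    return out.sort_values("pif", ascending=False, kind="mergesort")


def extreme_slice(scores: pd.Series, fraction: float = 0.01) -> tuple[pd.Index, pd.Index]:
    """Top and bottom ``floor(N * fraction)`` row ids of a ranked score.

    N is the background size (rows with a score); e.g. the nominal 1% of a
    19,100-row background is 191 ids per tail. Ties break stably by the
    incoming row order.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    scored = scores.dropna()
    k = math.floor(len(scored) * fraction)
    ranked = scored.sort_values(ascending=False, kind="mergesort")
    top = ranked.index[:k]
    bottom = scored.sort_values(ascending=True, kind="mergesort").index[:k]
    return top, bottom
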