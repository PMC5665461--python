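"""Regulatory impact factors: differential-connectivity scores per regulator.

A regulator's network relevance can change between two conditions without
the regulator itself being differentially expressed.  The two RIF scores
quantify this by contrasting, per regulator r, its Pearson co-expression
with a set of n_DE selected genes computed separately within each breed
(across the four developmental-stage means):

    dw_rj  = r1_rj - r2_rj                      (differential wiring)
    RIF1_r = (1/n_DE) * sum_j  e_bar_j * d_j * dw_rj**2
    RIF2_r = (1/n_DE) * sum_j  (e1_j * r1_rj)**2 - (e2_j * r2_rj)**2

where r1/r2 are the BA/CH correlations, e_bar_j is gene j's mean over all
eight treatment means, d_j its BA-CH contrast averaged over stages, and
e1_j/e2_j its mean over the four BA / four CH stage means.  RIF1 weights
squared rewiring by abundance-and-contrast (a PIF-like term); RIF2
contrasts squared "predicted abundance" (expression x correlation) between
breeds.

With only four points per correlation these are noisy estimates; the scores
are a ranking device for flagging candidate rewired regulators, not an
inferential test, and no p-values are produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import DiffTable, extreme_slice

logger = logging.getLogger(__name__)

DEFAULT_SELECTION_RULE = "pif-extreme"
DEFAULT_SELECTION_FRACTION = 0.05
DEFAULT_Z_CUTOFF = 1.96


@dataclass
class DEGeneSelection:
    """The genes used as RIF targets, with their per-gene weights."""

    genes: pd.Index
    rule: str
    e_bar: pd.Series   # mean over the 8 treatment means
    d: pd.Series       # mean per-stage contrast (BA - CH)
    e1: pd.Series      # mean over the 4 BA stage means
    e2: pd.Series      # mean over the 4 CH stage means

    @property
    def n_de(self) -> int:
        return len(self.genes)


@dataclass
class CorrelationProfiles:
    """Per (regulator, selected gene) breed-wise Pearson correlations.

    ``r1``/``r2`` are regulators x genes frames of correlations over the
    four BA / CH stage means; NaN marks pairs with fewer than
    ``min_shared`` jointly observed stages.  Zero-variance profiles give
    r = 0 and are flagged in ``degenerate`` (constant profiles carry no
    wiring signal).
    """

    r1: pd.DataFrame
    r2: pd.DataFrame
    degenerate: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def select_de_genes(
    diff: DiffTable,
    rule: str = DEFAULT_SELECTION_RULE,
    fraction: float = DEFAULT_SELECTION_FRACTION,
) -> DEGeneSelection:
    """Pick RIF target genes as the union of both extremes of a ranked score.

    ``pif-extreme`` ranks on the stage-averaged PIF, ``de-extreme`` on the
    stage-averaged contrast d. ``fraction`` is per tail, of the scored
    background.
    """
    if rule == "pif-extreme":
        score = diff.mean_pif()
    elif rule == "de-extreme":
        score = diff.mean_d()
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    top, bottom = extreme_slice(score, fraction)
    genes = top.append(bottom).unique()
    if len(genes) == 0:
        raise ValueError("empty DE-gene selection (background too small for fraction)")
    e_bar = diff.a.mean(axis=1)                  # == mean of the 8 treatment means
    half = diff.d / 2.0
    e1 = (diff.a + half).mean(axis=1)
    e2 = (diff.a - half).mean(axis=1)
    genes = pd.Index(genes, name=diff.index.name)
    return DEGeneSelection(genes=genes, rule=rule,
                           e_bar=e_bar.loc[genes], d=diff.mean_d().loc[genes],
                           e1=e1.loc[genes], e2=e2.loc[genes])


def _pearson_rows(X: np.ndarray, Y: np.ndarray, min_shared: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Row-vs-row Pearson correlations with pairwise-complete handling.

    Returns (r, degenerate) of shape (len(X), len(Y)).  Zero-variance
    profiles are assigned r = 0 and flagged; pairs with fewer than
    ``min_shared`` jointly present columns are NaN.
    """
    nX, nY = len(X), len(Y)
    r = np.zeros((nX, nY))
    degen = np.zeros((nX, nY), dtype=bool)
    complete = not (np.isnan(X).any() or np.isnan(Y).any())
    if complete:
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        xn = np.sqrt((Xc ** 2).sum(axis=1))
        yn = np.sqrt((Yc ** 2).sum(axis=1))
        x_flat = xn < 1e-12
        y_flat = yn < 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ Yc.T) / np.outer(np.where(x_flat, 1.0, xn),
                                       np.where(y_flat, 1.0, yn))
        degen = x_flat[:, None] | y_flat[None, :]
        r[degen] = 0.0
        return np.clip(r, -1.0, 1.0), degen
    for i in range(nX):
        xi = X[i]
        for j in range(nY):
            yj = Y[j]
            mask = ~(np.isnan(xi) | np.isnan(yj))
            if mask.sum() < min_shared:
                r[i, j] = np.nan
                continue
            x, y = xi[mask], yj[mask]
            sx, sy = x.std(), y.std()
            if sx < 1e-12 or sy < 1e-12:
                r[i, j] = 0.0
                degen[i, j] = True
            else:
                r[i, j] = np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0)
    return r, degen


def breed_correlation_profiles(
    means: pd.DataFrame,
    regulators,
    selection: DEGeneSelection,
    min_shared: int = 3,
) -> CorrelationProfiles:
    """Pearson correlations regulator-vs-target across the 4 stage means, per breed."""
    regulators = pd.Index([str(g) for g in regulators]).unique()
    present = regulators.intersection(means.index)
    absent = regulators.difference(means.index)
    if len(absent):
        logger.info("breed_correlation_profiles: %d regulators absent from the data",
                    len(absent))
    if len(present) == 0:
        raise ValueError("no regulators present in the expression table")
    genes = selection.genes
    out = {}
    degen = {}
    for key, breed in (("r1", "BA"), ("r2", "CH")):
        X = means.loc[present, breed].to_numpy(dtype=float)
        Y = means.loc[genes, breed].to_numpy(dtype=float)
        r, dg = _pearson_rows(X, Y, min_shared=min_shared)
        out[key] = pd.DataFrame(r, index=present, columns=genes)
        degen[key] = pd.DataFrame(dg, index=present, columns=genes)
    return CorrelationProfiles(r1=out["r1"], r2=out["r2"],
                               degenerate=degen["r1"] | degen["r2"])


def breed_correlation_profiles_replicates(
    sample_matrix: pd.DataFrame,
    design: pd.DataFrame,
    regulators,
    selection: DEGeneSelection,
    min_shared: int = 3,
) -> CorrelationProfiles:
    """Replicate-level alternative to :func:`breed_correlation_profiles`.

    Correlates over each breed's individual samples (all stages pooled)
    instead of the four stage means.  With ~10 points per breed the null
    correlation distribution is far tighter than the 4-point stage-mean
    version, at the price of conflating developmental and replicate
    covariation; offered as an option, not the default.
    """
    regulators = pd.Index([str(g) for g in regulators]).unique()
    present = regulators.intersection(sample_matrix.index)
    if len(present) == 0:
        raise ValueError("no regulators present in the expression table")
    genes = selection.genes
    out, degen = {}, {}
    for key, breed in (("r1", "BA"), ("r2", "CH")):
        samples = design.index[design["breed"] == breed]
        samples = [s for s in samples if s in sample_matrix.columns]
        X = sample_matrix.loc[present, samples].to_numpy(dtype=float)
        Y = sample_matrix.loc[genes, samples].to_numpy(dtype=float)
        r, dg = _pearson_rows(X, Y, min_shared=min_shared)
        out[key] = pd.DataFrame(r, index=present, columns=genes)
        degen[key] = pd.DataFrame(dg, index=present, columns=genes)
    return CorrelationProfiles(r1=out["r1"], r2=out["r2"],
                               degenerate=degen["r1"] | degen["r2"])


def compute_rif(profiles: CorrelationProfiles, selection: DEGeneSelection) -> pd.DataFrame:
    """Raw RIF1/RIF2 per regulator; pairs with missing correlations are
    excluded and the per-regulator n_DE adjusted accordingly."""
    r1, r2 = profiles.r1, profiles.r2
    e_bar = selection.e_bar.reindex(r1.columns)
    d = selection.d.reindex(r1.columns)
    e1 = selection.e1.reindex(r1.columns)
    e2 = selection.e2.reindex(r1.columns)
    weights_ok = e_bar.notna() & d.notna() & e1.notna() & e2.notna()
    usable = r1.notna() & r2.notna()
    usable.loc[:, ~weights_ok.to_numpy()] = False
    n_used = usable.sum(axis=1)

    dw = r1 - r2
    term1 = dw.pow(2).mul(e_bar * d, axis=1)
    term2 = r1.pow(2).mul(e1 ** 2, axis=1) - r2.pow(2).mul(e2 ** 2, axis=1)
    rif1 = term1.where(usable).sum(axis=1, min_count=1) / n_used
    rif2 = term2.where(usable).sum(axis=1, min_count=1) / n_used
    empty = n_used == 0
    if empty.any():
        logger.warning("compute_rif: %d regulators had no usable pairs", int(empty.sum()))
    return pd.DataFrame({"n_de_used": n_used, "rif1_raw": rif1, "rif2_raw": rif2})


def standardize_and_rank(rif_table: pd.DataFrame, cutoff: float = DEFAULT_Z_CUTOFF) -> pd.DataFrame:
    """Z-standardize raw RIF columns over scored regulators and flag extremes.

    Adds ``rif1_z``, ``rif2_z`` (mean 0, sample sd 1 over regulators with a
    score), a quadrant label by z signs, and ``extreme_both`` marking
    |z| > ``cutoff`` in both columns.  Rows come back sorted by
    |rif1_z| + |rif2_z| descending (unscored regulators last).
    """
    scored = rif_table["rif1_raw"].notna() & rif_table["rif2_raw"].notna()
    if int(scored.sum()) < 2:
        raise ValueError("need at least 2 scored regulators to standardize")
    out = rif_table.copy()
    for raw, z in (("rif1_raw", "rif1_z"), ("rif2_raw", "rif2_z")):
        col = out.loc[scored, raw]
        out[z] = (out[raw] - col.mean()) / col.std(ddof=1)
    signs = np.sign(out[["rif1_z", "rif2_z"]])
    out["quadrant"] = [
        "" if (np.isnan(s1) or np.isnan(s2))
        else ("+" if s1 >= 0 else "-") + ("+" if s2 >= 0 else "-")
        for s1, s2 in signs.to_numpy()
    ]
    out["extreme_both"] = (out["rif1_z"].abs() > cutoff) & (out["rif2_z"].abs() > cutoff)
    order = (out["rif1_z"].abs() + out["rif2_z"].abs()).fillna(-np.inf)
    return out.loc[order.sort_values(ascending=False, kind="mergesort").index]
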