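"""Gene-set bookkeeping, the sign-skew statistic, and ranked-list export.

The central statistic asks whether the per-gene contrast signs within a
gene set (e.g. the mitoproteome) deviate from a 50:50 up/down split.  The
probability of seeing at least k of n genes on the majority side under a
fair-coin null is the exact binomial upper tail,

    P(X >= k) = sum_{i=k..n} C(n, i) p^i (1-p)^(n-i),

computed by direct summation in log space so that n in the hundreds does
not underflow (e.g. 345 of 514 at p = 0.5 gives P ~ 3e-15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .differential import DiffTable
from .io import read_gene_list, write_gene_list

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named collection of gene symbols (uppercased for matching)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g).upper(), None)
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        return cls(name or Path(path).stem, read_gene_list(path))

    def to_file(self, path: str | Path) -> None:
        write_gene_list(self.genes, path)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SkewResult:
    """Up/down split of a matched gene set's contrast signs at one stage."""

    n_up: int           # d > 0, i.e. higher in BA
    n_down: int         # d < 0, i.e. higher in CH
    n_zero: int         # d == 0, excluded from the test
    n_missing: int      # d unavailable at the stage
    p_value: float      # one-sided upper tail at the majority count
    direction: str      # breed label of the larger side ('BA', 'CH' or 'tie')
    sided: str = "one"

    @property
    def n_tested(self) -> int:
        return self.n_up + self.n_down


def _symbols_of(index: pd.Index) -> pd.Index:
    """Gene symbols of a row index that may be plain or (gene, probe)."""
    if isinstance(index, pd.MultiIndex):
        if "gene" not in (index.names or []):
            raise ValueError("MultiIndex rows need a 'gene' level for set matching")
        return pd.Index(index.get_level_values("gene").astype(str).str.upper())
    return pd.Index(index.astype(str).str.upper())


def match_set(rows, gene_set: GeneSet, collapse_duplicates: bool = False):
    """Subset rows (a DataFrame/Series/Index keyed by gene symbol) to a set.

    Matching is case-insensitive.  Multi-probe genes yield duplicate rows,
    retained by default; ``collapse_duplicates`` keeps the first row per
    gene.  Zero matches raise, naming the set.
    """
    index = rows if isinstance(rows, pd.Index) else rows.index
    symbols = _symbols_of(index)
    mask = symbols.isin(set(gene_set.genes))
    if not mask.any():
        raise ValueError(f"gene set {gene_set.name!r} matched no rows")
    if collapse_duplicates:
        mask &= ~symbols.duplicated()
    logger.info("match_set: %d rows matched set %r (%d symbols)",
                int(mask.sum()), gene_set.name, len(gene_set))
    if isinstance(rows, pd.Index):
        return rows[mask]
    return rows.loc[mask]


def sign_split(diff: DiffTable, stage: int, rows=None, sided: str = "one") -> SkewResult:
    """Count contrast signs of (a subset of) rows at one stage and test the skew.

    ``rows`` may be an index of row ids (e.g. from :func:`match_set`);
    default is every row.  Zeros are excluded from the binomial test; the
    reported p-value is the one-sided upper tail at the majority count by
    default (convention recorded in the result).
    """
    d = diff.d[stage]
    if rows is not None:
        d = d.loc[rows]
    n_missing = int(d.isna().sum())
    d = d.dropna()
    n_up = int((d > 0).sum())
    n_down = int((d < 0).sum())
    n_zero = int((d == 0).sum())
    n = n_up + n_down
    if n == 0:
        raise ValueError(f"no nonzero contrasts at stage {stage}")
    k = max(n_up, n_down)
    p = binom_tail_exact(k, n, 0.5, sided=sided)
    direction = "BA" if n_up > n_down else ("CH" if n_down > n_up else "tie")
    return SkewResult(n_up=n_up, n_down=n_down, n_zero=n_zero, n_missing=n_missing,
                      p_value=p, direction=direction, sided=sided)


def _log_pmf(n: int, p: float) -> np.ndarray:
    i = np.arange(n + 1)
    return (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
            + i * np.log(p) + (n - i) * np.log1p(-p))


def binom_tail_exact(k: int, n: int, p: float = 0.5, sided: str = "one") -> float:
    """Exact binomial tail by direct log-space summation.

    One-sided: ``P(X >= k)``.  Two-sided: twice the smaller of the upper
    tail at k and the lower tail through k, capped at 1.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    logs = _log_pmf(n, p)
    upper = float(np.exp(logsumexp(logs[k:])))
    if sided == "one":
        return min(upper, 1.0)
    lower = float(np.exp(logsumexp(logs[: k + 1])))
    return min(1.0, 2.0 * min(upper, lower))


def binom_tail_exact_lower(k: int, n: int, p: float = 0.5) -> float:
    """Exact lower tail ``P(X <= k)``; k < 0 gives 0."""
    if k < 0:
        return 0.0
    if k >= n:
        return 1.0
    logs = _log_pmf(n, p)
    return min(float(np.exp(logsumexp(logs[: k + 1]))), 1.0)


def export_ranked_list(
    ranked_ids,
    out_dir: str | Path,
    prefix: str = "ranked",
    top=None,
    bottom=None,
) -> dict[str, Path]:
    """Write enrichment-tool inputs: a ranked list, and target/background pairs.

    Writes ``{prefix}_ranked.txt`` (all ids, rank order) and, when tails
    are given, ``{prefix}_background.txt`` plus ``{prefix}_top.txt`` /
    ``{prefix}_bottom.txt`` for the two-list import mode.  An empty tail
    produces an empty file with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ranked_ids = list(ranked_ids)
    paths = {"ranked": out_dir / f"{prefix}_ranked.txt"}
    write_gene_list(ranked_ids, paths["ranked"])
    if top is not None or bottom is not None:
        paths["background"] = out_dir / f"{prefix}_background.txt"
        write_gene_list(ranked_ids, paths["background"])
        for tag, tail in (("top", top), ("bottom", bottom)):
            if tail is None:
                continue
            tail = list(tail)
            if not tail:
                logger.warning("export_ranked_list: empty %s tail for %r", tag, prefix)
            paths[tag] = out_dir / f"{prefix}_{tag}.txt"
            write_gene_list(tail, paths[tag])
    return paths
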