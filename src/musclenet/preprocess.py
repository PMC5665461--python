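"""Replicate averaging, treatment means, expression filtering, gene mapping.

This stage turns a probe-level log2 matrix plus a sample design into the
8-column (breed x stage) treatment-mean table the downstream statistics
work on, reproducing the study's replicate averaging and the
"expressed in at least 7 of the 8 treatments" quality filter.

Missing handling: the mean of a partially missing replicate or treatment
set uses the available values; a cell is missing only when every
underlying value is missing.
"""

from __future__ import annotations

import logging

import pandas as pd

from .design import TREATMENTS, treatment_label, validate_design

logger = logging.getLogger(__name__)

#: default minimal-expression floor on the log2 scale (the study does not
#: state its floor; this value is arbitrary and must be set deliberately)
DEFAULT_EXPRESSION_FLOOR = 2.0


def average_technical_replicates(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates per probe.

    Returns the collapsed matrix (one column per ``tech_group``, in first-
    appearance order) and the collapsed one-row-per-group design.  Groups of
    size one pass through unchanged; the mean of a partly missing group uses
    available values.
    """
    design = validate_design(design)
    unknown = [s for s in matrix.columns if s not in design.index]
    if unknown:
        raise ValueError(f"samples absent from design: {unknown[:5]}")
    groups = design.loc[matrix.columns, "tech_group"]
    order = groups.drop_duplicates().tolist()
    averaged = matrix.T.groupby(groups, sort=False).mean().T[order]
    collapsed = (design.loc[matrix.columns]
                 .groupby("tech_group", sort=False)
                 .first()
                 .loc[order])
    collapsed.index.name = "sample_id"
    collapsed["tech_group"] = collapsed.index
    return averaged, collapsed


def compute_treatment_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean per (breed, stage) treatment over that treatment's available samples.

    Output columns are the canonical 8-treatment MultiIndex; an empty
    treatment raises, naming the offending cell.
    """
    design = validate_design(design)
    cols = {}
    for breed, stage in TREATMENTS:
        samples = design.index[(design["breed"] == breed) & (design["stage"] == stage)]
        samples = [s for s in samples if s in matrix.columns]
        if not samples:
            raise ValueError(f"treatment {treatment_label(breed, stage)} has no samples")
        cols[(breed, stage)] = matrix[samples].mean(axis=1)
    means = pd.DataFrame(cols)
    means.columns = pd.MultiIndex.from_tuples(means.columns, names=["breed", "stage"])
    return means


def filter_expressed(
    means: pd.DataFrame,
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
    min_treatments: int = 7,
) -> pd.DataFrame:
    """Keep rows at or above the floor in >= ``min_treatments`` of the 8 treatments.

    A missing cell never counts as expressed. ``min_treatments=0`` is the
    identity filter.
    """
    if not 0 <= min_treatments <= len(TREATMENTS):
        raise ValueError("min_treatments must lie in [0, 8]")
    ok = (means.notna() & (means >= expression_floor)).sum(axis=1) >= min_treatments
    kept = means.loc[ok]
    logger.info("filter_expressed: retained %d of %d rows (floor=%g, min=%d)",
                len(kept), len(means), expression_floor, min_treatments)
    return kept


def map_to_genes(
    means: pd.DataFrame, probe_map: pd.Series, mode: str = "best-probe"
) -> pd.DataFrame:
    """Relabel probe rows by gene symbol.

    ``keep-probes`` keeps every mapped probe and returns a (gene, probe)
    MultiIndex; ``best-probe`` keeps, per gene, the probe with the highest
    mean abundance across the 8 treatments (ties broken by lexicographic
    probe id) and returns a plain gene index. Unmapped probes are dropped
    with a logged count.
    """
    if mode not in ("keep-probes", "best-probe"):
        raise ValueError(f"unknown mode {mode!r}")
    mapped = means.index.intersection(probe_map.index)
    n_dropped = len(means) - len(mapped)
    if n_dropped:
        logger.info("map_to_genes: dropped %d unmapped probes", n_dropped)
    sub = means.loc[mapped]
    genes = probe_map.loc[mapped].astype(str).str.upper()
    if mode == "keep-probes":
        out = sub.copy()
        out.index = pd.MultiIndex.from_arrays([genes.values, mapped], names=["gene", "probe_id"])
        return out
    abundance = sub.mean(axis=1)
    pick = (pd.DataFrame({"gene": genes.values, "abundance": abundance.values,
                          "probe": mapped})
            .sort_values(["gene", "abundance", "probe"],
                         ascending=[True, False, True], kind="mergesort")
            .drop_duplicates("gene"))
    out = sub.loc[pick["probe"]]
    out.index = pd.Index(pick["gene"].values, name="gene")
    return out
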