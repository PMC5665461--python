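"""Study-design constants and helpers.

The experimental layout is a two-breed (Blonde d'Aquitaine, BA; Charolais,
CH) by four-stage (110, 180, 210 and 260 days post conception) factorial
with unbalanced biological replication.  A *treatment* is one breed x stage
cell; there are eight.  Sample annotations travel as a pandas DataFrame
indexed by sample id with columns ``breed``, ``stage``, ``tech_group`` and
optionally ``sex``.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

BREEDS: tuple[str, ...] = ("BA", "CH")
STAGES: tuple[int, ...] = (110, 180, 210, 260)
#: the eight breed x stage treatments, breed-major order
TREATMENTS: tuple[tuple[str, int], ...] = tuple((b, s) for b in BREEDS for s in STAGES)


def treatment_label(breed: str, stage: int) -> str:
    """Human-readable treatment name, e.g. ``'BA_110'``."""
    return f"{breed}_{stage}"


def treatment_index() -> pd.MultiIndex:
    """The canonical (breed, stage) column index for treatment-mean tables."""
    return pd.MultiIndex.from_tuples(TREATMENTS, names=["breed", "stage"])


def make_design_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Build a validated design frame from per-sample records."""
    df = pd.DataFrame.from_records(list(records)).set_index("sample_id")
    return validate_design(df)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a design frame.

    Ensures unique sample ids, known breed and stage levels, an integer
    stage dtype and a ``tech_group`` column (defaulting to the sample id,
    i.e. no technical replication).
    """
    if design.index.has_duplicates:
        dupes = design.index[design.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in design: {dupes}")
    missing = {"breed", "stage"} - set(design.columns)
    if missing:
        raise ValueError(f"design lacks required columns: {sorted(missing)}")
    design = design.copy()
    design["stage"] = design["stage"].astype(int)
    bad_breed = set(design["breed"]) - set(BREEDS)
    if bad_breed:
        raise ValueError(f"unknown breed labels: {sorted(bad_breed)} (expected {BREEDS})")
    bad_stage = set(design["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)} (expected {STAGES})")
    if "tech_group" not in design.columns:
        design["tech_group"] = design.index
    else:
        design["tech_group"] = design["tech_group"].fillna(pd.Series(design.index, index=design.index))
    return design


def swap_breed_labels(design: pd.DataFrame) -> pd.DataFrame:
    """Relabel BA<->CH; useful for antisymmetry checks."""
    out = design.copy()
    out["breed"] = out["breed"].map({"BA": "CH", "CH": "BA"})
    return out
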