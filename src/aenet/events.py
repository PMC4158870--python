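"""Long-format event tables.

The single input container of the pipeline is a pandas DataFrame with one
row per ``(patient_id, term, term_type)`` triple and a positive integer
``count`` giving how many times the term was recorded for that patient.
``term_type`` distinguishes adverse events (``AE``), drug codes (``drug``)
and diagnosis codes (``diagnosis``).

All derived quantities used downstream come from this table:

* ``f`` — the per-record count,
* ``F`` — a patient's total count over all terms of one type,
* ``N`` — the number of distinct patients with at least one record of the
  chosen type,
* ``n`` — for a given term, the number of distinct patients carrying it.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

TERM_TYPES = ("AE", "drug", "diagnosis")
COLUMNS = ("patient_id", "term", "term_type", "count")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table and return it with canonical column order.

    Raises ``ValueError`` on missing columns, unknown term types,
    non-positive counts, or duplicated (patient_id, term, term_type) keys.
    """
    missing = [c for c in COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    events = events.loc[:, list(COLUMNS)]
    if len(events) == 0:
        raise ValueError("event table is empty")
    bad_type = set(events["term_type"].unique()) - set(TERM_TYPES)
    if bad_type:
        raise ValueError(
            f"unknown term_type values {sorted(bad_type)}; expected one of {TERM_TYPES}"
        )
    counts = pd.to_numeric(events["count"], errors="coerce")
    if counts.isna().any() or (counts < 1).any() or (counts != counts.round()).any():
        raise ValueError("count must be a positive integer in every row")
    if events.duplicated(subset=["patient_id", "term", "term_type"]).any():
        raise ValueError("duplicate (patient_id, term, term_type) rows")
    out = events.copy()
    out["count"] = counts.astype(np.int64)
    return out


def subset_by_type(events: pd.DataFrame, term_type: str) -> pd.DataFrame:
    if term_type not in TERM_TYPES:
        raise ValueError(f"unknown term_type {term_type!r}; expected one of {TERM_TYPES}")
    return events.loc[events["term_type"] == term_type]


def incidence_matrix(
    events: pd.DataFrame,
    term_type: str = "AE",
    vocabulary: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binary patient x term incidence for one term type.

    Rows are patients with at least one record of the type, sorted by id;
    columns follow ``vocabulary`` if given (terms absent from the data get
    all-zero columns), otherwise the sorted observed terms.
    """
    sub = subset_by_type(events, term_type)
    if len(sub) == 0:
        raise ValueError(f"no records of term_type {term_type!r}")
    inc = (
        sub.assign(present=1)
        .pivot_table(index="patient_id", columns="term", values="present", fill_value=0)
        .astype(np.int8)
    )
    inc = inc.sort_index()
    if vocabulary is not None:
        vocab = list(vocabulary)
        if len(set(vocab)) != len(vocab):
            raise ValueError("vocabulary contains duplicate terms")
        extra = set(inc.columns) - set(vocab)
        if extra:
            raise ValueError(f"events contain terms outside the vocabulary: {sorted(extra)[:5]}")
        inc = inc.reindex(columns=vocab, fill_value=0).astype(np.int8)
    else:
        inc = inc.sort_index(axis=1)
    return inc


def term_prevalence(events: pd.DataFrame, term_type: str = "AE") -> pd.Series:
    """Number of distinct patients carrying each term, sorted by term."""
    sub = subset_by_type(events, term_type)
    return sub.groupby("term")["patient_id"].nunique().sort_index()
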