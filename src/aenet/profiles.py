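"""tf-idf document vectors over adverse events, drugs or diagnoses.

A "document" is either a single patient's record or the merged records of
all patients in a cluster. For a term with per-document count ``f``,
document total ``F``, corpus size ``N`` (number of patients with at least
one term of the chosen type) and document frequency ``n`` (number of those
patients carrying the term),

    tfidf = (f / F) * ln(N / n)

The normalized term frequency ``f/F`` removes the bias toward patients with
longer records; the idf factor down-weights ubiquitous terms (a term present
in every patient scores ln(1) = 0 everywhere).

For heat-map style comparisons across documents, each tf-idf vector is
reduced to its *characteristic scale*: the fraction each term contributes to
the vector sum, in [0, 1] and summing to 1. The term with the largest
fraction is the document's most distinguishing term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .events import subset_by_type

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "CharacteristicProfile",
    "compute_tfidf",
    "characteristic_scale",
    "characteristic_profiles",
    "rank_distinguishing_terms",
]


@dataclass
class ProfileMatrix:
    """Dense documents x terms matrix of non-negative reals."""

    document_ids: list[str]
    vocabulary: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.document_ids), len(self.vocabulary)):
            raise ValueError("values shape does not match document_ids x vocabulary")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("profile values must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.document_ids, columns=self.vocabulary
        )

    def row(self, document_id: str) -> np.ndarray:
        return self.values[self.document_ids.index(document_id)]


@dataclass
class CharacteristicProfile:
    """Fractions each term contributes to a document's tf-idf vector sum."""

    document_id: str
    fractions: dict[str, float]


def compute_tfidf(
    events: pd.DataFrame,
    term_type: str = "AE",
    document_grouping: Mapping[str, str] | None = None,
    idf_corpus: str = "patients",
) -> ProfileMatrix:
    """Build the tf-idf ProfileMatrix for one term type.

    Parameters
    ----------
    events:
        Long-format event table.
    term_type:
        Which vocabulary to use: "AE", "drug" or "diagnosis".
    document_grouping:
        Optional patient_id -> document_id map. When given, the counts of
        all patients mapped to the same document are merged (the cluster
        vector case); patients missing from the map are dropped.
    idf_corpus:
        "patients" (default) keeps N and n defined over individual
        patients even when documents are merged clusters, so cluster
        values stay on the same scale as patient values; "documents"
        computes the idf over the documents actually present.

    Patients with no terms of the requested type simply do not appear in
    the table and are excluded; when a grouping is supplied, the number of
    its patients absent from the data is logged.
    """
    if idf_corpus not in ("patients", "documents"):
        raise ValueError("idf_corpus must be 'patients' or 'documents'")
    sub = subset_by_type(events, term_type)
    if len(sub) == 0:
        raise ValueError(f"no records of term_type {term_type!r}: empty vocabulary")

    # patient-level document frequency, before any merging
    n_by_term = sub.groupby("term")["patient_id"].nunique()
    n_patients = sub["patient_id"].nunique()

    if document_grouping is not None:
        keep = sub["patient_id"].isin(document_grouping.keys())
        missing = set(document_grouping) - set(sub["patient_id"])
        if missing:
            logger.warning(
                "%d patients in the grouping have no %s records and are dropped",
                len(missing), term_type,
            )
        sub = sub.loc[keep].copy()
        if len(sub) == 0:
            raise ValueError("no records left after applying document_grouping")
        sub["document"] = sub["patient_id"].map(dict(document_grouping)).astype(str)
    else:
        sub = sub.copy()
        sub["document"] = sub["patient_id"]

    counts = (
        sub.groupby(["document", "term"])["count"].sum().unstack(fill_value=0)
    )
    counts = counts.sort_index().sort_index(axis=1)
    f = counts.to_numpy(dtype=float)
    F = f.sum(axis=1, keepdims=True)

    if idf_corpus == "patients":
        big_n = n_patients
        n = n_by_term.reindex(counts.columns).to_numpy(dtype=float)
    else:
        big_n = counts.shape[0]
        n = (f > 0).sum(axis=0).astype(float)

    with np.errstate(divide="ignore"):
        idf = np.where(n > 0, np.log(big_n / np.maximum(n, 1)), 0.0)
    values = (f / F) * idf
    return ProfileMatrix(
        document_ids=list(counts.index),
        vocabulary=list(counts.columns),
        values=values,
    )


def characteristic_scale(
    profiles: ProfileMatrix, document_id: str
) -> CharacteristicProfile:
    """Fractions of the tf-idf vector sum for one document.

    Only terms with a positive value appear in the result; the fractions
    sum to 1. An all-zero row cannot be characterized and raises.
    """
    row = profiles.row(document_id)
    total = row.sum()
    if total <= 0:
        raise ValueError(
            f"document {document_id!r} has an all-zero profile and cannot be characterized"
        )
    fractions = {
        term: float(v / total)
        for term, v in zip(profiles.vocabulary, row)
        if v > 0
    }
    return CharacteristicProfile(document_id=document_id, fractions=fractions)


def characteristic_profiles(profiles: ProfileMatrix) -> ProfileMatrix:
    """Row-normalize a ProfileMatrix to characteristic fractions.

    Rows with an all-zero profile raise, matching ``characteristic_scale``.
    """
    totals = profiles.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if len(zero):
        raise ValueError(
            f"documents with all-zero profiles cannot be characterized: "
            f"{[profiles.document_ids[i] for i in zero[:5]]}"
        )
    return ProfileMatrix(
        document_ids=list(profiles.document_ids),
        vocabulary=list(profiles.vocabulary),
        values=profiles.values / totals[:, None],
    )


def rank_distinguishing_terms(
    profile: CharacteristicProfile, k: int
) -> list[tuple[str, float]]:
    """Top-k terms by characteristic fraction, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(profile.fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: min(k, len(ranked))]
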