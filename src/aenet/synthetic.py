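"""Seeded synthetic cohorts with the statistical structure of a text-mined
adverse-event corpus.

Real mental-health-center EMR data cannot be redistributed, so every stage
of the pipeline is exercised on generated cohorts that emulate the corpus
shape the analysis assumes: a few thousand patients, a heavy-tailed
adverse-event (AE) prevalence distribution in which roughly half of all AEs
affect a single patient, an overdispersed per-patient AE burden (mean about
5, maximum a few dozen, with roughly a fifth of patients carrying exactly
one AE), planted patient clusters each dominated by one distinguishing AE,
and planted positively correlated AE pairs.

Mechanisms (all seeded through a single ``numpy`` generator):

* Background AE popularity is a discrete power law (shifted Zipf) with
  exponent ``prevalence_tail_exponent`` and head offset
  ``prevalence_head_offset`` — the simplest mechanism that produces a large
  fraction of singleton AEs while keeping the most popular AEs at a
  plausible (non-universal) prevalence.
* The number of distinct AEs per patient is a negative binomial with mean
  ``burden_mean`` and dispersion ``burden_dispersion``, truncated to
  ``[1, burden_max]``; the untruncated mean is solved numerically so the
  truncated distribution hits ``burden_mean`` exactly in expectation.
* Cluster members draw each AE from a mixture: the cluster's distinguishing
  AE with probability ``dominant_ae_weight``, its secondary AE with
  probability ``secondary_ae_weight``, otherwise the background power law.
* Each planted pair ``(i, j, joint_boost)`` is a latent per-patient
  "syndrome" switched on with probability ``joint_boost``; when on, both
  AEs are added, giving a controllable positive dependence.
* The recorded occurrence count ``f`` of a present AE is the number of
  times the mixture drew it while filling the patient's AE set, plus
  geometric noise with mean ``event_count_mean``; a cluster member's
  distinguishing AE is therefore not only present but also carries a high
  term frequency, which is what makes the cluster recoverable from tf-idf
  profiles.
* Each cluster carries one or two characteristic drug and diagnosis codes
  sampled with a cluster-specific bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .events import validate_events

__all__ = [
    "CohortConfig",
    "CohortSummary",
    "generate_cohort",
    "planted_labels",
    "cohort_summary",
    "reference_config",
    "planted_cluster_config",
    "null_config",
]


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the corpus shape of a text-mined psychiatric EMR
    cohort: 2347 AE-bearing patients, 1190 unique AEs, mean burden 5.2
    distinct AEs per patient (max 48).
    """

    n_patients: int = 2347
    n_aes: int = 1190
    cluster_sizes: list[int] = field(
        default_factory=lambda: [60, 50, 45, 40, 35, 30, 25, 20]
    )
    dominant_ae_weight: float = 0.5
    secondary_ae_weight: float = 0.1
    prevalence_tail_exponent: float = 1.8
    prevalence_head_offset: float = 5.0
    burden_mean: float = 5.2
    burden_max: int = 48
    burden_dispersion: float = 0.65
    event_count_mean: float = 1.5
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    n_drugs: int = 50
    n_diagnoses: int = 40
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        if self.n_aes < 1:
            raise ValueError("n_aes must be a positive integer")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes entries must be >= 1")
        if sum(self.cluster_sizes) > self.n_patients:
            raise ValueError("cluster_sizes must sum to <= n_patients")
        if self.n_aes < 2 * self.n_clusters:
            raise ValueError(
                "n_aes must be >= 2 * number of clusters so every cluster has "
                "a distinct distinguishing AE and a distinct secondary AE"
            )
        if not 0.0 < self.dominant_ae_weight < 1.0:
            raise ValueError("dominant_ae_weight must lie in (0, 1)")
        if not 0.0 <= self.secondary_ae_weight < 1.0:
            raise ValueError("secondary_ae_weight must lie in [0, 1)")
        if self.dominant_ae_weight + self.secondary_ae_weight >= 1.0:
            raise ValueError(
                "dominant_ae_weight + secondary_ae_weight must be < 1 so the "
                "background mixture component has positive mass"
            )
        if self.prevalence_tail_exponent <= 0:
            raise ValueError("prevalence_tail_exponent must be positive")
        if self.prevalence_head_offset < 0:
            raise ValueError("prevalence_head_offset must be non-negative")
        if self.burden_mean <= 0:
            raise ValueError("burden_mean must be positive")
        if self.burden_max < 1:
            raise ValueError("burden_max must be a positive integer")
        if self.burden_mean > self.burden_max:
            raise ValueError("burden_mean must not exceed burden_max")
        if self.burden_dispersion <= 0:
            raise ValueError("burden_dispersion must be positive")
        if self.event_count_mean < 1:
            raise ValueError("event_count_mean must be >= 1 (counts are >= 1)")
        for i, j, boost in self.planted_pairs:
            if not (0 <= i < self.n_aes and 0 <= j < self.n_aes):
                raise ValueError("planted_pairs indices must be valid AE indices")
            if i == j:
                raise ValueError("planted_pairs must pair two distinct AEs (i != j)")
            if not 0.0 <= boost <= 1.0:
                raise ValueError("planted_pairs joint_boost must lie in [0, 1]")
        if self.n_drugs < 0 or self.n_diagnoses < 0:
            raise ValueError("n_drugs and n_diagnoses must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def reference_config(seed: int = 0) -> CohortConfig:
    """Default cohort matching the corpus-shape marginals (see module doc)."""
    return CohortConfig(seed=seed)


def planted_cluster_config(seed: int = 0) -> CohortConfig:
    """Small cohort with three well-separated planted clusters.

    Used to demonstrate and test stratification recovery: three clusters of
    sizes 30/20/15 plus background patients that mostly end up as noise
    singletons after size filtering.
    """
    return CohortConfig(
        n_patients=100,
        n_aes=80,
        cluster_sizes=[30, 20, 15],
        dominant_ae_weight=0.8,
        secondary_ae_weight=0.1,
        burden_mean=5.2,
        burden_max=20,
        n_drugs=12,
        n_diagnoses=10,
        seed=seed,
    )


def null_config(seed: int = 0, n_patients: int = 200, n_aes: int = 50) -> CohortConfig:
    """Cohort with independent AEs: no planted clusters, no planted pairs.

    The AE popularity tail is kept mild so most of the 50 AEs are observed;
    used for false-positive-rate checks of the co-occurrence tests.
    """
    return CohortConfig(
        n_patients=n_patients,
        n_aes=n_aes,
        cluster_sizes=[],
        prevalence_tail_exponent=0.8,
        burden_mean=5.2,
        burden_max=20,
        n_drugs=0,
        n_diagnoses=0,
        seed=seed,
    )


def _truncated_nbinom_raw_mean(target_mean: float, r: float, upper: int) -> float:
    """Untruncated NB mean whose [1, upper]-truncation has the target mean."""
    ks = np.arange(1, upper + 1)

    def trunc_mean(mu: float) -> float:
        p = r / (r + mu)
        pmf = stats.nbinom.pmf(ks, r, p)
        total = pmf.sum()
        if total <= 0:
            return 0.0
        return float((ks * pmf).sum() / total)

    lo, hi = 1e-6, float(upper) * 4
    if trunc_mean(hi) < target_mean:
        return hi
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi))


def _sample_burdens(
    rng: np.random.Generator, size: int, mean: float, r: float, upper: int
) -> np.ndarray:
    """Negative binomial burdens truncated to [1, upper] by rejection."""
    mu = _truncated_nbinom_raw_mean(mean, r, upper)
    p = r / (r + mu)
    out = np.zeros(size, dtype=np.int64)
    pending = np.arange(size)
    while len(pending):
        draw = rng.negative_binomial(r, p, size=len(pending))
        ok = (draw >= 1) & (draw <= upper)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def planted_labels(config: CohortConfig) -> dict[str, int]:
    """Ground-truth cluster label per patient id; 0 means background.

    Patients are laid out deterministically: the first ``cluster_sizes[0]``
    ids belong to cluster 1, the next block to cluster 2, and so on;
    remaining patients are background (label 0).
    """
    config.validate()
    labels: dict[str, int] = {}
    idx = 0
    for c, size in enumerate(config.cluster_sizes, start=1):
        for _ in range(size):
            labels[f"P{idx:05d}"] = c
            idx += 1
    for i in range(idx, config.n_patients):
        labels[f"P{i:05d}"] = 0
    return labels


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a seeded synthetic event table.

    Deterministic for a fixed config (including its seed). Every patient
    gets at least one AE record; drug and diagnosis records are attached
    when ``n_drugs`` / ``n_diagnoses`` are positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_aes = config.n_aes
    ae_terms = [f"AE{i:04d}" for i in range(n_aes)]
    # distinct dominant and secondary AEs per cluster; dominant AEs sit at
    # the head of the popularity ranking, mirroring corpora where cluster
    # signatures are also the globally prevalent events
    dominant = list(range(config.n_clusters))
    secondary = list(range(config.n_clusters, 2 * config.n_clusters))

    ranks = np.arange(1, n_aes + 1, dtype=float) + config.prevalence_head_offset
    w = ranks ** -config.prevalence_tail_exponent
    w /= w.sum()
    cdf = np.cumsum(w)

    labels = planted_labels(config)
    patients = list(labels)
    burdens = _sample_burdens(
        rng, config.n_patients, config.burden_mean,
        config.burden_dispersion, config.burden_max,
    )

    dw, sw = config.dominant_ae_weight, config.secondary_ae_weight
    geom_p = 1.0 / config.event_count_mean
    # per patient: draw mixture events until the burden's worth of distinct
    # AEs is reached; the draw multiplicity becomes the term count f, so a
    # cluster's distinguishing AE also dominates its members' term frequency
    ae_counts: list[dict[int, int]] = []
    for i, pid in enumerate(patients):
        c = labels[pid]
        b = int(burdens[i])
        drawn: dict[int, int] = {}
        attempts = 0
        while len(drawn) < b and attempts < 50 * b + 100:
            attempts += 1
            if c > 0:
                u = rng.random()
                if u < dw:
                    ae = dominant[c - 1]
                elif u < dw + sw:
                    ae = secondary[c - 1]
                else:
                    ae = int(np.searchsorted(cdf, rng.random()))
            else:
                ae = int(np.searchsorted(cdf, rng.random()))
            drawn[ae] = drawn.get(ae, 0) + 1
        ae_counts.append(drawn)

    for i_ae, j_ae, boost in config.planted_pairs:
        hits = rng.random(config.n_patients) < boost
        for idx in np.flatnonzero(hits):
            ae_counts[idx].setdefault(i_ae, 1)
            ae_counts[idx].setdefault(j_ae, 1)

    records: list[tuple[str, str, str, int]] = []
    for i, pid in enumerate(patients):
        for ae in sorted(ae_counts[i]):
            f = ae_counts[i][ae] + int(rng.geometric(geom_p)) - 1
            records.append((pid, ae_terms[ae], "AE", f))
        c = labels[pid]
        for kind, n_codes, prefix in (
            ("drug", config.n_drugs, "DRG"),
            ("diagnosis", config.n_diagnoses, "DX"),
        ):
            if n_codes == 0:
                continue
            cluster_codes = (
                [(2 * (c - 1)) % n_codes, (2 * (c - 1) + 1) % n_codes] if c > 0 else []
            )
            n_rec = min(1 + int(rng.poisson(1.0)), n_codes)
            codes: set[int] = set()
            attempts = 0
            while len(codes) < n_rec and attempts < 50 * n_rec + 100:
                attempts += 1
                if cluster_codes and rng.random() < 0.7:
                    codes.add(cluster_codes[int(rng.integers(len(cluster_codes)))])
                else:
                    codes.add(int(rng.integers(n_codes)))
            for code in sorted(codes):
                f = int(rng.geometric(geom_p))
                records.append((pid, f"{prefix}{code:03d}", kind, f))

    events = pd.DataFrame.from_records(
        records, columns=["patient_id", "term", "term_type", "count"]
    )
    return validate_events(events)


@dataclass
class CohortSummary:
    n_patients: int
    n_aes: int
    mean_aes_per_patient: float
    max_aes_per_patient: int
    frac_single_ae_patients: float
    frac_single_patient_aes: float
    mean_patients_per_ae: float

    def to_dict(self) -> dict:
        return asdict(self)


def cohort_summary(events: pd.DataFrame) -> CohortSummary:
    """Exact counting summary of the AE portion of an event table.

    "AEs per patient" counts distinct AE terms; single-AE patients are
    those with exactly one distinct AE; single-patient AEs are AE terms
    observed in exactly one patient.
    """
    aes = events.loc[events["term_type"] == "AE"]
    if len(aes) == 0:
        raise ValueError("event table has no AE records")
    per_patient = aes.groupby("patient_id")["term"].nunique()
    per_ae = aes.groupby("term")["patient_id"].nunique()
    return CohortSummary(
        n_patients=int(per_patient.size),
        n_aes=int(per_ae.size),
        mean_aes_per_patient=float(per_patient.mean()),
        max_aes_per_patient=int(per_patient.max()),
        frac_single_ae_patients=float((per_patient == 1).mean()),
        frac_single_patient_aes=float((per_ae == 1).mean()),
        mean_patients_per_ae=float(per_ae.mean()),
    )
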