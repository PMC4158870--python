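"""Adverse-event co-occurrence statistics and networks.

Two independent methods identify AE pairs that affect the same patients
more often than chance, both computed from the binary patient x AE
incidence (a patient either has an AE or not):

Method 1 — co-occurrence score with Fisher filtering. For a pair (A, B)
with n_A and n_B affected patients, n_AB co-affected patients, and n_tot
patients in total, the observed count is compared with the expected count
under independence, Expt = n_A * n_B / n_tot, through a pseudocounted
log-ratio

    score = log2((n_AB + 1) / (n_A * n_B / n_tot + 1))

so pairs of very rare AEs are favored less. Significance comes from
Fisher's exact test on the 2x2 partition (A and B, A not B, B not A,
neither), with Benjamini-Hochberg control of the false discovery rate
across all pairs; edges are pairs with adjusted p below the significance
level.

Method 2 — weighted edges with the multiscale backbone (disparity filter).
Each patient p with n_p AEs contributes 1 / (n_p - 1) to every AE pair it
carries, so patients with very many AEs do not dominate:

    WE_ij = sum_p delta_i^p * delta_j^p / (n_p - 1)   (i != j; WE_ii = 0)

The backbone keeps an edge when its share p_ij = WE_ij / sum_j WE_ij of a
node's total strength is improbable under a uniform random split of that
strength over the node's k edges:

    alpha_ij = 1 - (k - 1) * integral_0^{p_ij} (1 - x)^(k-2) dx
             = (1 - p_ij)^(k-1)

An edge is retained when alpha is below the significance level from at
least one of its two endpoints (the "either" rule; a stricter "both" rule
is available). Nodes with a single edge (k = 1) get alpha = 1 and can never
be significant from their own side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .events import incidence_matrix, subset_by_type

__all__ = [
    "pair_counts",
    "cooccurrence_score",
    "fisher_pair_test",
    "bh_adjust",
    "pair_stats",
    "score_network",
    "WeightMatrix",
    "weighted_edges",
    "disparity_alpha",
    "extract_backbone",
    "NetworkOverlap",
    "compare_networks",
]

PAIR_COLUMNS = (
    "ae_i", "ae_j", "n_A", "n_B", "n_AB", "n_tot",
    "score", "fisher_p", "bh_p", "significant",
)


def pair_counts(
    events: pd.DataFrame,
    vocabulary: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exhaustive per-pair patient counts from the binary AE incidence.

    One row per unordered pair (ae_i < ae_j under the term ordering), so a
    vocabulary of V terms yields V(V-1)/2 rows. Passing ``vocabulary``
    includes terms with no observations (their counts are 0).
    """
    inc = incidence_matrix(events, term_type="AE", vocabulary=vocabulary)
    terms = list(inc.columns)
    b = inc.to_numpy(dtype=np.int64)
    n_tot = b.shape[0]
    co = b.T @ b
    n = np.diag(co)
    iu, ju = np.triu_indices(len(terms), k=1)
    return pd.DataFrame(
        {
            "ae_i": np.asarray(terms, dtype=object)[iu],
            "ae_j": np.asarray(terms, dtype=object)[ju],
            "n_A": n[iu],
            "n_B": n[ju],
            "n_AB": co[iu, ju],
            "n_tot": n_tot,
        }
    )


def _check_counts(n_AB, n_A, n_B, n_tot) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(a, dtype=np.int64) for a in (n_AB, n_A, n_B, n_tot)]
    n_ab, n_a, n_b, nt = np.broadcast_arrays(*arrs)
    if (nt <= 0).any():
        raise ValueError("n_tot must be positive")
    if (n_ab < 0).any() or (n_a < 0).any() or (n_b < 0).any():
        raise ValueError("counts must be non-negative")
    if (n_ab > np.minimum(n_a, n_b)).any():
        raise ValueError("n_AB cannot exceed min(n_A, n_B)")
    if (n_a > nt).any() or (n_b > nt).any():
        raise ValueError("n_A and n_B cannot exceed n_tot")
    if (nt - n_a - n_b + n_ab < 0).any():
        raise ValueError("inconsistent counts: negative 'neither' cell")
    return n_ab, n_a, n_b, nt


def cooccurrence_score(n_AB, n_A, n_B, n_tot):
    """Pseudocounted log2 observed/expected co-affection ratio.

    log2((n_AB + 1) / (n_A * n_B / n_tot + 1)); 0 under exact independence.
    Accepts scalars or arrays (vectorized).
    """
    n_ab, n_a, n_b, nt = _check_counts(n_AB, n_A, n_B, n_tot)
    expt = n_a.astype(float) * n_b.astype(float) / nt
    out = np.log2((n_ab + 1.0) / (expt + 1.0))
    return float(out) if out.ndim == 0 else out


def fisher_pair_test(n_AB, n_A, n_B, n_tot, alternative: str = "greater"):
    """Fisher's exact test on the 2x2 partition of patients by two AEs.

    The table cells are (n_AB, n_A - n_AB, n_B - n_AB, n_tot - n_A - n_B +
    n_AB). The default one-sided "greater" alternative asks for more
    co-affected patients than independence predicts; it equals the
    hypergeometric tail P(X >= n_AB) and is fully vectorized. "two-sided"
    sums hypergeometric outcomes no more probable than the observed one.
    """
    n_ab, n_a, n_b, nt = _check_counts(n_AB, n_A, n_B, n_tot)
    if alternative == "greater":
        p = stats.hypergeom.sf(n_ab - 1, nt, n_a, n_b)
        p = np.clip(p, 0.0, 1.0)
        return float(p) if p.ndim == 0 else p
    if alternative == "two-sided":
        flat = np.stack(
            [a.ravel() for a in np.broadcast_arrays(n_ab, n_a, n_b, nt)], axis=1
        )
        out = np.empty(len(flat))
        for r, (ab, a, b, t) in enumerate(flat):
            table = [[ab, a - ab], [b - ab, t - a - b + ab]]
            out[r] = stats.fisher_exact(table, alternative="two-sided")[1]
        out = out.reshape(np.shape(n_ab))
        return float(out) if out.ndim == 0 else out
    raise ValueError("alternative must be 'greater' or 'two-sided'")


def bh_adjust(pvalues, n_tests: int | None = None, monotone: bool = True):
    """Benjamini-Hochberg adjusted p-values, returned in input order.

    Each p-value is multiplied by the number of tests and divided by its
    rank in the ascending ordering. With ``monotone=True`` (the step-up
    procedure) adjusted values are additionally made non-decreasing in rank
    by a cumulative minimum from the largest rank down, and capped at 1;
    ``monotone=False`` returns the raw rank-scaled values. ``n_tests``
    defaults to the length of the input and may be larger when untested
    pairs count toward the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if len(p) == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if n_tests is None else int(n_tests)
    if m < len(p):
        raise ValueError("n_tests must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1, dtype=float)
    adjusted_sorted = p[order] * m / ranks
    if monotone:
        adjusted_sorted = np.minimum.accumulate(adjusted_sorted[::-1])[::-1]
        adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty_like(adjusted_sorted)
    out[order] = adjusted_sorted
    return out


def pair_stats(
    events: pd.DataFrame,
    alpha: float = 0.01,
    vocabulary: Sequence[str] | None = None,
    m_mode: str = "all_pairs",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Full per-pair statistics table (method 1).

    ``m_mode`` selects the Benjamini-Hochberg denominator: "all_pairs"
    corrects over every V(V-1)/2 pair including those never co-observed;
    "observed_pairs" corrects only over pairs with n_AB > 0 (the table is
    restricted accordingly).
    """
    if m_mode not in ("all_pairs", "observed_pairs"):
        raise ValueError("m_mode must be 'all_pairs' or 'observed_pairs'")
    table = pair_counts(events, vocabulary=vocabulary)
    if m_mode == "observed_pairs":
        table = table.loc[table["n_AB"] > 0].reset_index(drop=True)
    table["score"] = cooccurrence_score(
        table["n_AB"], table["n_A"], table["n_B"], table["n_tot"]
    )
    table["fisher_p"] = fisher_pair_test(
        table["n_AB"], table["n_A"], table["n_B"], table["n_tot"],
        alternative=alternative,
    )
    table["bh_p"] = bh_adjust(table["fisher_p"].to_numpy(), n_tests=len(table))
    table["significant"] = table["bh_p"] < alpha
    return table


def _annotate_nodes(
    g: nx.Graph,
    prevalence: Mapping[str, int],
    n_patients: int,
    annotations: Mapping[str, str] | None,
) -> None:
    for node in g.nodes:
        g.nodes[node]["prevalence"] = float(prevalence.get(node, 0)) / n_patients
        if annotations is not None:
            g.nodes[node]["anatomical_class"] = annotations.get(node, "unclassified")


def score_network(
    events: pd.DataFrame,
    alpha: float = 0.01,
    vocabulary: Sequence[str] | None = None,
    m_mode: str = "all_pairs",
    alternative: str = "greater",
    annotations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """AE network of significantly co-occurring pairs (method 1).

    Edges are pairs whose BH-adjusted Fisher p-value is below ``alpha``;
    only AEs incident to at least one edge appear as nodes. Node attributes
    carry the fraction of patients affected (and the anatomical class when
    an annotation map is supplied); edge attributes carry the score and the
    raw and adjusted p-values. The full statistics table is attached as
    ``g.graph["pair_stats"]``.
    """
    table = pair_stats(
        events, alpha=alpha, vocabulary=vocabulary,
        m_mode=m_mode, alternative=alternative,
    )
    aes = subset_by_type(events, "AE")
    n_patients = aes["patient_id"].nunique()
    prevalence = aes.groupby("term")["patient_id"].nunique().to_dict()

    g = nx.Graph(method="cooccurrence_score", alpha=alpha, m_mode=m_mode,
                 alternative=alternative)
    for row in table.loc[table["significant"]].itertuples(index=False):
        g.add_edge(
            row.ae_i, row.ae_j,
            score=float(row.score),
            fisher_p=float(row.fisher_p),
            bh_p=float(row.bh_p),
        )
    _annotate_nodes(g, prevalence, n_patients, annotations)
    g.graph["pair_stats"] = table
    return g


@dataclass
class WeightMatrix:
    """Symmetric AE x AE weighted-edge matrix with a zero diagonal."""

    terms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = len(self.terms)
        if self.values.shape != (v, v):
            raise ValueError("weight matrix must be square over terms")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("weight matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.terms, columns=self.terms)


def weighted_edges(
    events: pd.DataFrame, vocabulary: Sequence[str] | None = None
) -> WeightMatrix:
    """Patient-normalized co-occurrence weights (method 2).

    WE_ij sums 1 / (n_p - 1) over patients carrying both AEs, where n_p is
    the patient's number of distinct AEs; a patient's total contribution
    over all its pairs is therefore exactly n_p. Patients with a single AE
    contribute nothing.
    """
    inc = incidence_matrix(events, term_type="AE", vocabulary=vocabulary)
    b = inc.to_numpy(dtype=float)
    n_p = b.sum(axis=1)
    coef = np.zeros_like(n_p)
    multi = n_p > 1
    coef[multi] = 1.0 / (n_p[multi] - 1.0)
    w = (b * coef[:, None]).T @ b
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(terms=list(inc.columns), values=w)


def disparity_alpha(weights_from_node):
    """Disparity-filter significance of each edge seen from one node.

    Given the positive weights of a node's k edges, returns alpha_ij =
    (1 - p_ij)^(k-1) with p_ij = w_ij / sum(w), the closed form of
    1 - (k-1) * integral_0^{p_ij} (1-x)^(k-2) dx. A node with a single edge
    (k = 1) yields alpha = 1: its full strength on one edge carries no
    evidence of heterogeneity.
    """
    w = np.asarray(weights_from_node, dtype=float)
    if w.ndim != 1 or len(w) == 0:
        raise ValueError("weights_from_node must be a non-empty 1-d array")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    k = len(w)
    if k == 1:
        return np.ones(1)
    p = w / w.sum()
    return (1.0 - p) ** (k - 1)


def _alpha_matrix(w: np.ndarray) -> np.ndarray:
    """Directed alpha_ij for every positive edge; 1 elsewhere."""
    v = w.shape[0]
    alpha = np.ones_like(w)
    strength = w.sum(axis=1)
    degree = (w > 0).sum(axis=1)
    for i in range(v):
        if degree[i] < 2:
            continue
        js = np.flatnonzero(w[i] > 0)
        p = w[i, js] / strength[i]
        alpha[i, js] = (1.0 - p) ** (degree[i] - 1)
    return alpha


def extract_backbone(
    weights: WeightMatrix,
    alpha: float = 0.01,
    drop_top_prevalent: int = 10,
    prevalence: Mapping[str, int] | None = None,
    n_patients: int | None = None,
    rule: str = "either",
    annotations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Multiscale backbone of the weighted-edge network (method 2).

    The ``drop_top_prevalent`` most prevalent AEs (ties broken by term
    order) are removed from the weight matrix first; disparity alphas are
    then computed on the remaining matrix. An edge is retained when it is
    significant from at least one endpoint (``rule="either"``) or from both
    (``rule="both"``); nodes are the AEs incident to a retained edge.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    if drop_top_prevalent > 0 and prevalence is None:
        raise ValueError("prevalence is required when drop_top_prevalent > 0")

    terms = list(weights.terms)
    w = weights.values.copy()
    if drop_top_prevalent > 0:
        ranked = sorted(terms, key=lambda t: (-prevalence.get(t, 0), t))
        dropped = set(ranked[:drop_top_prevalent])
        keep = [i for i, t in enumerate(terms) if t not in dropped]
        terms = [terms[i] for i in keep]
        w = w[np.ix_(keep, keep)]

    a = _alpha_matrix(w)
    if rule == "either":
        keep_edge = np.minimum(a, a.T) < alpha
    else:
        keep_edge = np.maximum(a, a.T) < alpha
    keep_edge &= w > 0

    g = nx.Graph(method="weighted_backbone", alpha=alpha,
                 drop_top_prevalent=drop_top_prevalent, rule=rule)
    iu, ju = np.nonzero(np.triu(keep_edge, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        g.add_edge(
            terms[i], terms[j],
            weight=float(w[i, j]),
            alpha=float(min(a[i, j], a[j, i])),
        )
    if prevalence is not None and n_patients:
        _annotate_nodes(g, prevalence, n_patients, annotations)
    elif annotations is not None:
        for node in g.nodes:
            g.nodes[node]["anatomical_class"] = annotations.get(node, "unclassified")
    return g


@dataclass
class NetworkOverlap:
    """Node/edge overlap between two AE networks."""

    n_nodes_a: int
    n_edges_a: int
    n_nodes_b: int
    n_edges_b: int
    shared_nodes: int
    shared_edges: int
    frac_nodes_a: float
    frac_nodes_b: float
    frac_edges_a: float
    frac_edges_b: float
    edges_per_node_a: float
    edges_per_node_b: float

    def summary(self) -> dict:
        """Report-ready dict with ratios rounded to two decimals."""
        out = {
            "n_nodes_a": self.n_nodes_a, "n_edges_a": self.n_edges_a,
            "n_nodes_b": self.n_nodes_b, "n_edges_b": self.n_edges_b,
            "shared_nodes": self.shared_nodes, "shared_edges": self.shared_edges,
        }
        for name in ("frac_nodes_a", "frac_nodes_b", "frac_edges_a",
                     "frac_edges_b", "edges_per_node_a", "edges_per_node_b"):
            out[name] = round(getattr(self, name), 2)
        return out


def compare_networks(a: nx.Graph, b: nx.Graph) -> NetworkOverlap:
    """Node and unordered-edge overlap between two AE networks.

    Fractions are relative to each network's own node and edge counts;
    edges are compared as unordered term pairs.
    """
    nodes_a, nodes_b = set(a.nodes), set(b.nodes)
    edges_a = {frozenset(e) for e in a.edges}
    edges_b = {frozenset(e) for e in b.edges}
    shared_nodes = len(nodes_a & nodes_b)
    shared_edges = len(edges_a & edges_b)

    def frac(x: int, denom: int) -> float:
        return x / denom if denom else 0.0

    return NetworkOverlap(
        n_nodes_a=len(nodes_a), n_edges_a=len(edges_a),
        n_nodes_b=len(nodes_b), n_edges_b=len(edges_b),
        shared_nodes=shared_nodes, shared_edges=shared_edges,
        frac_nodes_a=frac(shared_nodes, len(nodes_a)),
        frac_nodes_b=frac(shared_nodes, len(nodes_b)),
        frac_edges_a=frac(shared_edges, len(edges_a)),
        frac_edges_b=frac(shared_edges, len(edges_b)),
        edges_per_node_a=frac(len(edges_a), len(nodes_a)),
        edges_per_node_b=frac(len(edges_b), len(nodes_b)),
    )
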