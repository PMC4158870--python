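# Methods

## Scope and data model

All computations start from a long-format event table with one row per
(patient, term, term type) and a positive occurrence count, where the term
type is `AE`, `drug` or `diagnosis`. Terms are opaque, case-sensitive
strings: synonym merging, negation handling and drug–AE causality
assignment are upstream text-mining concerns and are deliberately out of
scope. All pairwise AE statistics use the *binary* patient × AE incidence;
the occurrence counts matter only for tf-idf term frequencies.

## Stratification model

Patient vectors use tfidf = (f/F)·ln(N/n) with the natural logarithm and no
smoothing inside the idf; pseudocounts appear only in the co-occurrence
score. Patients with no terms of the requested type are absent from the
profile matrix (a count of dropped patients is logged when a grouping is
supplied). Distances are cosine dissimilarity, which is invariant to record
length; values are clipped to [0, 1] against floating-point noise.

Clustering is unweighted average linkage (UPGMA — arithmetic mean over all
inter-cluster pairs, not the weighted WPGMA variant). The dendrogram cut is
*strict*: merges at height < cutoff are applied, merges at exactly the
cutoff are not, matching the "dissimilarity less than the threshold" edge
convention of the patient network. Because UPGMA heights are monotone, the
applied merges form a prefix of the linkage sequence. Cluster ids are
assigned by descending size (ties by smallest member id), so after
filtering at a minimum size the retained clusters are exactly ids 1..k.
An O(n³) naive agglomeration oracle in the test suite certifies the
partition semantics on random instances.

Cluster-level vectors merge the counts of the cluster's patients; the idf
stays at the patient level by default (`idf_corpus="patients"`), because
document frequency is a corpus property of terms and keeping it fixed makes
cluster values comparable to patient values. An idf over cluster documents
is available as a switch. Cluster characteristic fractions (value / vector
sum) feed the heat-map exports; the secondary clustering of clusters uses
Euclidean distance on those fraction vectors, and only its dendrogram leaf
order is consumed (column arrangement).

Patients filtered out of the retained clusters remain in the co-occurrence
analyses, which always use every AE-bearing patient.

## Co-occurrence statistics

*Score method.* score = log₂((n_AB+1)/(n_A n_B/n_tot + 1)); the +1
pseudocounts temper pairs of very rare AEs. Significance is a Fisher exact
test on the 2×2 partition. The test is **one-sided (enrichment)** by
default: the analysis looks for co-occurrence, not avoidance; the one-sided
p equals the hypergeometric tail P(X ≥ n_AB), which is computed vectorized
over all pairs, and a two-sided variant sits behind a flag. The
Benjamini–Hochberg correction multiplies each p by the number of tests and
divides by its rank; on top of the plain rank-scaling we enforce the
standard step-up cumulative-minimum and cap at 1, which leaves the
rejection set at any fixed α unchanged while making the adjusted values
interpretable (the raw rank-scaled values are available with
`monotone=False`). The default correction denominator is all V(V−1)/2
pairs including never-co-observed ones; `m_mode="observed_pairs"` restricts
both the table and the denominator.

*Weighted-edge method.* WE_ij = Σ_p δᵢᵖδⱼᵖ/(n_p−1): each patient
distributes exactly n_p units of weight over its pairs, so heavily affected
patients do not dominate (the suite verifies this conservation identity
numerically). The disparity filter evaluates α_ij = (1−p_ij)^(k−1), the
closed form of 1 − (k−1)∫₀^{p_ij}(1−x)^{k−2}dx (checked against numerical
quadrature to 1e-10). Nodes with a single edge get α = 1 — a k = 1 node's
entire strength on one edge carries no evidence of heterogeneity. An edge
is kept when significant from **at least one** endpoint (the backbone
literature's usual convention); a stricter both-endpoint rule is a flag.
The removal of the most prevalent AEs (default 10) is applied to the weight
matrix *before* backbone extraction, after weights have been computed on the
full data; it exists to keep the displayed network readable and is switched
off (`drop_top_prevalent=0`) in planted-pair recovery experiments, where a
strongly boosted pair would otherwise be removed for being prevalent.

Both networks include as nodes only AEs incident to a significant edge,
annotated with the fraction of patients affected and, when an annotation
table is supplied, a free-form anatomical class.

## Synthetic cohorts

The generator emulates the corpus shape of a text-mined psychiatric EMR
cohort; its defaults are the package's reference conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 2347 | AE-bearing patients |
| n_aes | 1190 | AE vocabulary size |
| burden_mean | 5.2 | mean distinct AEs per patient |
| burden_max | 48 | hard cap on per-patient AEs |
| burden_dispersion | 0.65 | negative-binomial size parameter |
| prevalence_tail_exponent | 1.8 | Zipf exponent of background AE popularity |
| prevalence_head_offset | 5.0 | Zipf head shift (caps top-AE prevalence) |
| dominant_ae_weight | 0.5 (0.8 in the cluster demo) | P(event draw = cluster's distinguishing AE) |
| secondary_ae_weight | 0.1 | P(event draw = cluster's secondary AE) |
| event_count_mean | 1.5 | geometric noise added to term counts |

Mechanisms: per-patient burden is a zero/upper-truncated negative binomial
whose untruncated mean is solved numerically so the truncated mean equals
`burden_mean` exactly; the dispersion 0.65 puts ≈22% of patients at exactly
one AE. Background AE identity is a shifted Zipf draw; with exponent 1.8
and offset 5 about 44% of observed AEs affect a single patient and the most
popular AE affects ≈44% of patients. Under these settings roughly 600 of
the 1190 vocabulary AEs are observed in a cohort — the generator
prioritizes the burden and prevalence-shape marginals over the observed
vocabulary count, which would require a flatter, less realistic tail.
Cluster members draw each AE event from a dominant/secondary/background
mixture, and the *draw multiplicity* becomes the term count, so a cluster's
distinguishing AE carries both high prevalence and high term frequency
within the cluster — this is what makes planted clusters recoverable from
tf-idf profiles. In the three-cluster demo configuration a dominant weight
of 0.8 produces clusters whose distinguishing AE makes up 35–50% of the
cluster vector sum, the regime where recovery (mean adjusted Rand index
≥ 0.8 over seeds) is reliable. Planted AE pairs are latent per-patient
"syndromes": with probability `joint_boost` both AEs are added, giving a
joint probability in excess of independence of about the boost. Each
cluster also carries two characteristic drug and diagnosis codes sampled
with 0.7 bias, giving the drug/diagnosis heat maps block structure without
modelling causality.

What the generator does **not** emulate: demographics (unused by the
analysis), prescription timing and dosage, narrative text, correlated
background AEs beyond the planted ones, and diagnosis–AE leakage. Passing
tests on these cohorts therefore certify the statistical machinery under
the stated marginals, not performance on real EMR data.

## Numerical and procedural choices

- Randomness: a single `numpy.random.default_rng(seed)` per generated
  cohort; fixed iteration order makes outputs byte-identical across runs.
- Distinct-AE selection is rejection sampling capped at 50·burden + 100
  attempts; in degenerate configurations a patient may end with fewer
  distinct AEs than its drawn burden (never fewer than one).
- Ranking ties: distinguishing-term ranking breaks fraction ties
  lexicographically; prevalence ties in the top-prevalent removal break by
  term order; UPGMA merge ties follow the linkage implementation (random
  real-valued distances make ties measure-zero).
- `bh_adjust` rejects p-values outside [0, 1]; significance uses strict
  `adjusted p < α`.
- Problem sizes in the test and acceptance runs (200–500 patients, 50–80
  AEs, 10–200 replicates) were chosen as the smallest cohorts at which the
  statistical effects are stable; the exhaustive pair-space check runs on
  the full 1190-term vocabulary.

## Known limitations

- The dendrogram cut reproduces the intended partition semantics, but with
  tied distances the UPGMA tree itself is not unique; partitions are only
  guaranteed stable for generic (tie-free) inputs.
- The two-sided Fisher variant loops per pair and is slow for exhaustive
  vocabularies; the default one-sided path is fully vectorized.
- The observed-vocabulary shortfall of the default cohort (above).
- Heat-map exports are tables; rendering is left to the user's plotting
  stack.
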