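# Methods

## Corpus model

The unit of analysis is a paper record: an opaque id, a calendar year
(validity window 1900–2100 by default), and four sets — institutional
affiliations, author ids, referenced paper ids, normalized topic tags.
Set semantics are enforced at parse time: duplicate affiliations within
a record collapse, an author with multiple affiliations contributes all
of them to the paper's institution set, and a record referencing itself
is rejected. Records with an empty institution set are retained (they
count in paper-level statistics and time series) but contribute no
network edges; their count is logged, since dropping them silently would
bias publication counts on real affiliation data, which is never
complete. References pointing outside the corpus are tracked as
`dangling_refs` rather than erased.

Tag matching is exact equality on a normalized form (lowercase, trimmed,
internal whitespace collapsed). This models selection by a curated alias
list (e.g. a gene symbol and its synonyms), not free-text search;
substring matching is deliberately not offered.

A topic's **analysis set** is the tagged core plus the papers citing it.
Both networks in the pipeline are built over that set: the collaboration
projection needs the citing papers' affiliations too, as the worked
example below makes explicit.

## Network projections

**Collaboration.** Every unordered pair of distinct institutions on a
paper increments that pair's weight by exactly one — one case per paper,
regardless of how many author pairs span the two institutions. Weights
are therefore integers and the projection obeys an exact conservation
law: Σ_{i<j} w_ij = Σ_p C(|I_p|, 2). Self-loops are not defined here;
within-institution collaboration is a property of paper-level author
sets, not an edge of an institution graph.

**Knowledge flow.** For each citation pair, each cited-paper institution
sends one unit to each citing-paper institution, giving the conservation
law Σ flow = Σ_pairs |I_cited| · |I_citing|. Direction is cited →
citing: a citation is knowledge reaching the citing institution.
Self-loops are kept — within-institution flow is one of the quantities
the indices report. A citation whose citing paper has no resolved
affiliations adds nothing to the flow network but still counts in the
annual citation series; time series and networks answer different
questions.

**Annual series.** Publications are dated by the core paper's year,
citations by the *citing* paper's year (the year the citation accrues).
Self-citation exclusion supports two definitions, since the term has no
single accepted one: shared author or shared institution between citing
and cited paper. The default is shared institution, consistent with an
institution-level analysis; neither is asserted as canonical, and the
exclusion is provably dominated (excluded counts never exceed included
ones — a property test, not an assumption).

## Indices

All indices operate on the whole weighted network, isolated nodes
included.

* **Industrial participation** = Σ_{i or j ∈ corporate} w_ij / Σ w_ij.
  The numerator counts each qualifying edge once, also when both
  endpoints are corporate — an inclusive-or over edges — so the
  fraction cannot exceed 1. Undefined (error, exported as an empty
  cell) on edgeless graphs.
* **Average clustering** uses the geometric-average-of-edge-weights
  triangle statistic: with ŵ = w / max(w) over the graph under
  analysis, C_i = (1/(k_i(k_i−1))) Σ_{j,k} (ŵ_ij ŵ_ik ŵ_jk)^{1/3} over
  ordered neighbor pairs; nodes of degree < 2 contribute 0 and are
  included in the unweighted mean. The statistic is invariant under
  uniform weight scaling (the normalization cancels). Implementation:
  cube-rooted normalized adjacency matrix, triangle sums from the
  diagonal of its cube — O(n³) dense, which is the right trade-off for
  the ≤ few-thousand-node graphs this package targets.
* **Assortativity** is the Pearson correlation of weighted degree
  (s_i = Σ_j w_ij) across edge endpoints, each edge entering the pair
  list once in both orientations and *not* weighted by its own weight:
  the text definition names weighted degree as the correlated quantity,
  not edge-weight sampling. When endpoint degrees have zero variance
  (regular graphs) the correlation is undefined and reported as
  not-applicable — never coerced to 0, which would fake neutrality.
* **Top-share fraction** ranks institutions by weighted degree
  (descending, ties broken lexicographically by id for determinism) and
  returns m/N, where m is the smallest prefix whose cumulative degree
  reaches the share threshold (default 0.9) of the total and N counts
  all nodes, isolated ones included. The threshold comparison runs in
  exact rational arithmetic (`Fraction(share) × total` against integer
  cumulative sums): degrees are integers, and a prefix landing exactly
  on the boundary must count, which float rounding of 0.9 · total would
  spuriously deny.
* **Flow fractions**: overall internal flow is self-loop flow over
  total flow; per-institution internal dissemination divides an
  institution's self-loop by its *out*-flow — the share of the
  citations its papers receive that it generates itself. Institutions
  with zero out-flow are omitted rather than given an arbitrary value.
  The overall fraction equals the out-flow-weighted mean of the
  per-institution ones (tested, not assumed).
* **Inter-institutional fraction** is paper-level: the share of
  selected papers with ≥ 2 institutions. Papers with no affiliations
  stay in the denominator. An author-pair-level variant would need
  author–affiliation links the record model does not carry.

The summary row also reports author counts. Whether "authors of a topic"
means authors of the core papers or of core plus citing papers is a
modeling choice; `compile_index_report` counts the set it is handed (the
pipeline passes the full analysis set) and `author_count` is exposed
separately so either convention can be computed.

## Synthetic corpus generator

The generator emulates the statistical regularities the analysis
assumes, with one pseudo-random stream per corpus seeded explicitly (no
global state):

* **Institutional activity**: institution k is drawn with probability ∝
  (k+1)^(−α), α = `institution_activity_exponent` (default 1.0, a
  Zipf-like law). Larger α concentrates collaboration weight in fewer
  institutions, reproducing the small-elite pattern of real corpora.
* **Papers**: years uniform over `year_range` (default 2000–2017, an
  era of multi-institution team science); institutions per paper from a
  bounded skewed integer law (default 1–5, skew 1.0 — most papers few,
  a tail many); authors nested within the paper's institutions, drawn
  from per-institution pools of 50.
* **Citations**: references target strictly earlier *years* only,
  keeping annual citation series causally ordered, and are drawn
  without replacement with probability ∝ (1 + in-citations)^β, β =
  `citation_attachment_exponent` (default 1.0, linear preferential
  attachment). Sampling uses the Gumbel-top-k trick on the log
  attachment weights — exact, vectorized, O(candidates) per paper. At
  β = 0 this reduces to uniform sampling over earlier papers
  (chi-square-tested). Requests for references before any paper exists
  are truncated and logged, never raised.
* **Sectors**: each institution is corporate with probability
  `industrial_share` (default 0.2), drawn from a substream that depends
  only on seed, institution count and share — so the corpus itself is
  identical across share settings at a fixed seed.
* **Tags**: the focal tag is planted on `tag_fraction` of papers
  (default 0.35, so that a tagged core and a citing periphery both have
  mass).

The generator's only claims are qualitative and tested: planted
concentration and industrial share are recovered monotonically from the
built networks (median top-share fraction strictly decreasing in α over
{0.0, 0.8, 1.6}; median industrial participation strictly increasing in
share over {0.1, 0.3, 0.5}; 10 seeds at 500 institutions × 5,000
papers). It does not model real author-name structure, topic mixtures,
journal effects, or calibrated citation-count distributions — passing
tests show the *pipeline* is correct and the parameters identifiable,
not that any real literature looks like these corpora.

## Pipeline determinism and exports

The analysis pipeline contains no randomness. Edge lists are sorted by
weight descending then pair id; corpora serialize with sorted keys and
sorted set fields; the run manifest records input SHA-256 hashes, stage
counts and warnings but no timestamps — so re-running on identical
inputs is byte-identical, and manifest counts can be audited against the
written artifacts. On stage failure the manifest still gets written with
the failing stage recorded, and the CLI exits non-zero.

## Problem sizes in the test suite

Property and conservation suites run on 50–200-paper corpora with 20–40
institutions; oracle-equivalence suites compare against brute-force
reference implementations on 100+ random graphs of ≤ 12 nodes at 1e-12;
the parameter-recovery suite runs the generator at its identifiability
scale, 500 institutions × 5,000 papers × 10 seeds per setting, reusing
the share-invariant corpora across industrial-share settings. These
sizes were chosen as the smallest at which the respective claims are
sharp: conservation laws are exact at any size, while monotone recovery
of planted exponents needs the larger corpora to separate medians.

## Known limitations

* Dense-matrix clustering is quadratic in memory; beyond ~2×10⁴
  institutions a sparse triangle enumeration would be needed.
* Institution identity is taken as given; affiliation-string
  disambiguation, author disambiguation and sector labeling are inputs,
  not outputs.
* The inter-institutional fraction and author counts depend on which
  paper set they are computed over (core vs. analysis set); both are
  computable, and the pipeline documents which it writes.
* Flow fractions are conditioned on the supplied corpus: citations from
  papers outside it are invisible, so internal-flow fractions are
  relative to observed flow, not to a topic's true citation universe.
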