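# Methods

## Problem and scope

meshmine quantifies a research landscape from bibliographic metadata alone.
Each PubMed/MEDLINE record is indexed with MeSH descriptors (controlled main
headings, optionally refined by `/qualifier` subheadings). The pipeline
annotates those descriptors against curated term lists — digital-health
approaches, diseases, MeSH age bands — counts how many publications are
associated with each term (overall and per publication year), counts
record-level co-occurrences of term pairs, and assembles a typed term network
whose nodes are terms (sized by occurrence count) and whose edges are
co-occurrences (weighted by pair count). Sub-networks around terms of interest
are extracted as first-degree-neighbour induced subgraphs. The outputs
(tidy TSV tables, GraphML, SIF) are meant for downstream viewers such as
Cytoscape; no layout, styling, community detection, or centrality statistics
are computed here.

## Matching model

Annotation is **exact matching at the whole-descriptor level** after
normalization: lowercase, whitespace collapsed, typographic dashes mapped to
ASCII hyphens, a leading major-topic asterisk and any `/qualifier` suffix
removed. There is no substring matching, stemming, entry-term expansion, or
MeSH-tree traversal — tree expansion would change every count, and the
descriptor level is where indexing is most consistent. Aliases
(`alias,canonical` rows in a vocabulary file) let users fold spelling variants
onto one canonical term.

Counts are **per record, binary**: a term counts once per record regardless of
how many qualifier variants repeat it, and an unordered term pair counts once
per record in which both terms are matched. This matches the natural reading
of "publications associated with term X". Within-vocabulary pairs
(disease–disease, approach–approach) and cross-vocabulary pairs run through
the same engine; network construction decides which classes to keep (default:
all).

Abstract-frequency counting is deliberately *not* implemented: the word-cloud
frequency table is derived from descriptor-level record counts, even though a
word cloud is sometimes described as counting mentions across abstracts. The
descriptor-level count is the well-defined, reproducible quantity here.

## Year handling

Year extraction precedence: the structured publication-date year; else the
first 4-consecutive-digit substring of a free-text date (MEDLINE dates like
`"2012 Jan-Feb"` are heterogeneous); else the year is absent. Records without
a year stay in the corpus and count toward totals, but contribute to no
per-year cell; per-year tables serialize densely (explicit zeros) over a
configurable window, default 2011–2021. `filter_corpus` drops records without
a year when a date window is applied, since their membership cannot be
decided.

Affiliation filtering is a case-insensitive substring test over raw
affiliation strings with default markers `{"United Kingdom", "UK"}`; no
geocoding is attempted. The same restriction can alternatively be embedded in
the generated PubMed query string (`build_query`); both paths exist because
either is a legitimate workflow.

## Network semantics

Node identity is the normalized term; the display label preserves the
vocabulary's original casing. Node type is the term's vocabulary category,
first-registered category winning (with a logged warning) if a term appears in
two vocabularies. Edges keep the raw pair count as weight — no aggregation or
rescaling — and are thresholded by a minimum count (default 1); isolated
matched terms are included only on request. First-degree sub-networks are
**induced** subgraphs on seeds plus neighbours, so neighbour–neighbour edges
are retained — the same behaviour as selecting first neighbours and creating a
network from the selection in Cytoscape. Seeds are re-typed `"selected"` in
the output so viewers can colour them.

Exports are deterministic (nodes sorted by id, edges by canonical
lexicographic pair), so identical inputs give byte-identical files. SIF output
is tab-delimited with relation `cooccurs_with`; isolated nodes are written as
single-column lines.

## Synthetic generative model

The generator emulates a *filtered search result*: `n_records` records, each
with a year drawn from `year_weights`, an abstract flag
(Bernoulli `p_abstract`), a UK-marked affiliation (Bernoulli
`uk_affiliation_p`), vocabulary-term descriptors, and `noise_terms` filler
descriptors from an alphabet disjoint from every vocabulary term (real records
carry many unrelated headings; disjointness keeps expectations exact).

Term dependence is modelled by **pair co-injection**: each term t enters
independently with probability `marginal_p[t]`; independently, each boosted
pair {a, b} fires with probability q and forces both terms in; a record's
inclusion is the union. This was chosen over a log-linear dependence model
because the closed forms stay exact while still producing genuine positive
association for network tests:

- inclusion: pi(t) = 1 − (1 − p_t) · ∏_{q in boosts touching t} (1 − q)
- occurrence: E = n·pi(t), Var = n·pi(t)(1 − pi(t))
- boosted pair {a,b}: P(both) = q + (1 − q)·pi~(a)·pi~(b), where pi~ is the
  inclusion probability excluding the shared boost (boost events are
  independent across pairs, so this is exact even when a term carries several
  boosts)
- unboosted pair: P(both) = pi(a)·pi(b)

Recovery tests assert observed counts within 4 standard deviations of these
expectations (per-term false-failure probability < 1e-4 under the model).
What passing proves: the counting pipeline is unbiased w.r.t. the generative
model at realistic scale. What it does not prove: robustness to real-data
features the generator omits — indexing lag, descriptor vocabulary drift over
years, correlated affiliation/abstract structure, or free-text noise.

## The demo scenario

`realistic_scenario()` ships marginal probabilities proportional to term
occurrence counts observed in a real ~9,200-record corpus of UK-affiliated
digital-health publications (telemedicine 1367 … software 341; rarest:
telerehabilitation 13, digital divide 8; ten diseases led by cerebrovascular
disease 119). Only the top five and bottom two digital-health counts were
itemised in that reference; the remaining 19 terms get interpolated counts
(60–310) strictly inside that range, so the reported ordering (top-1 and
bottom-2) is preserved by construction while the middle ranks are merely
plausible. Year weights rise over 2011–2021 with a slight final-year dip;
`p_abstract` and `uk_affiliation_p` are 1.0 because the emulated corpus is an
already-filtered search result. Nine pair boosts (1e-3 to 6e-3) echo the
strong telemedicine–cardiovascular/diabetes/hypertension and
smartphone/mobile-applications–obesity linkages such corpora show. Default
size is 2,300 records (the reference scale reduced ~4×) with fixed seed
20211227 — large enough that the top-1/bottom-2 ordering is stable across
seeds, small enough that an end-to-end demo runs in about a second.

## Numerical and design choices

- Ranking ties break by ascending lexicographic term (determinism; no
  external tie-break rule exists).
- Pair tables store only observed pairs under canonical lexicographic order;
  symmetric lookups are reconstructed on access.
- Duplicate PMIDs across merged sources keep the first record, with a logged
  warning, so overlapping searches cannot double-count.
- The TSV corpus cache escapes `\\`, `|`, tab and newline inside values and
  includes a `title` column so the round trip is lossless over all record
  fields.
- `aggregate_groups` recomputes group membership from the corpus (union
  semantics) rather than summing member counts, so a record matching several
  members counts once; it therefore takes the corpus and vocabulary, not a
  precomputed table.
- Empty corpora, empty networks, and all-zero tables are valid inputs and
  produce valid (header-only / element-free) outputs.
- The nbib parser delegates tagged-flat-file mechanics (continuation folding,
  field repetition) to Biopython's MEDLINE parser; the XML parser is lxml
  over the `PubmedArticleSet` dialect. Graph storage and GraphML writing sit
  on networkx.

## Test problem sizes

Oracle-equivalence sweeps use 200 random corpora of ≤ 50 records against
naive double-loop re-implementations that share no code with the library
path. Parameter recovery uses one 20,000-record corpus with 30 terms and 10
boosted pairs. Sub-network extraction is cross-checked against brute-force
induced-subgraph computation on random graphs of ≤ 30 nodes. These sizes give
tight statistical checks while the whole suite runs in a few seconds.

## Known limitations

- Gender is supported as a vocabulary category but no builtin gender list
  ships.
- The builtin disease list is a 10-term sample; real analyses should load a
  curated disease vocabulary.
- Live E-utilities harvesting is out of scope; `build_query` constructs the
  query string, but fetching and rate limiting are left to the user's tooling.
- No statistical testing of trend slopes or co-occurrence enrichment: the
  pipeline reports raw counts.
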