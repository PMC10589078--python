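# Methods

This note documents the models, conventions and parameter choices behind
`pollenniche`, stage by stage, including the places where the design was
genuinely open and what was decided.

## Taxonomy

Lineages are fixed seven-rank tuples (kingdom, phylum, class, order, family,
genus, species). Unknown ranks are explicit (`None` in memory, empty TSV
cells), and the representation enforces downward truncation: once a rank is
unknown, everything deeper is unknown. Taxon-name comparison is exact and
case-sensitive after whitespace trimming, so near-homonyms never merge
silently. The lowest common ancestor of a lineage set keeps the ranks on
which all inputs agree and truncates at the first disagreement; it is
associative, commutative and idempotent, which the property tests verify.
The seven-rank convention is an assumption — reference exports in this domain
rarely carry more structure, and genus (the unit of assignment) and family
(the host-plant unit) are what the analysis consumes.

## Semi-global alignment

The aligner is an in-house dynamic program (numba-compiled) with free
terminal gaps on both sequences: first DP row and column are zero and the
optimum is taken over the last row and column. Default scoring is match +2,
mismatch −4, internal gap −4; terminal gaps cost nothing. Scores never decide
acceptance — identity and coverage thresholds do — so the scoring scheme only
orders ties, and it is configurable.

Conventions, all of which matter for reproducibility:

* **identity** = matching columns / alignment-path columns, excluding
  terminal-gap columns and counting each internal-gap column as a non-match;
* **query coverage** = aligned (non-terminal-gap) query positions / query
  length;
* **canonical path** among co-optimal alignments: the end cell maximises
  (score, query index, target index); traceback prefers diagonal over
  query-gap over target-gap steps. Identity and coverage are reported for
  that one path, making results independent of implementation details;
* **N matches nothing**, including another N;
* coordinates are 0-based, half-open.

A caution that shaped two design points below: under free end gaps, *any* two
sequences admit a tiny terminal alignment of a few matching columns with
identity 1.0. Raw identity therefore cannot rank or select alignments by
itself; it is only meaningful alongside a coverage requirement.

## Read classification

Each merged read is searched exhaustively against the per-locus reference
set. The original search tool's "minimum of 50 accepted matches" is a
search-effort heuristic that exhaustive search subsumes; only the maximum
(100 accepted hits, configurable) is exposed. Accepted hits need identity
≥ 0.95 and query coverage ≥ 0.80 and are ordered by identity (descending),
score (descending), reference id (ascending) — deterministic and
order-independent.

Because merged amplicon orientation is not guaranteed, both the read and its
reverse complement are tried by default (`both_strands`). The thresholds are
applied **per orientation**, and the better *accepted* orientation is kept
(forward wins ties): selecting the orientation before filtering would let a
degenerate identity-1.0 corner alignment on the wrong strand mask a genuine
hit on the right one.

Assignment is top-hit based (not a consensus of all accepted hits): all hits
tied with the best on (identity, score) vote; a single genus wins outright,
otherwise the read is assigned the tied references' LCA — the genus if the
LCA reaches genus rank, else "matched, unassigned". Per locus, genus counts
plus matched-unassigned plus unmatched always partition the reads.

Reads are classified as-is: no quality trimming, primer removal or pair
merging (inputs are merged reads), no chimera detection or denoising.

## Reference cleaning

Exact matching ("100% identity, 100% query coverage") is implemented as
substring containment of the barcode in the contrast sequence; equal-length
equality is the special case, and a barcode containing N can have no exact
hit. The cascade:

1. any exact non-plant hit ⇒ mislabeled (`nonplant_exact_hit`);
2. exact plant hits: same-genus hit ⇒ correctly labeled
   (`plant_genus_match`) — and same-genus concordance wins even when
   different-genus exact hits coexist (logged with evidence), a conservative
   retention choice; different genera only ⇒ mislabeled
   (`plant_genus_mismatch`);
3. no exact plant hit: the relaxed top plant hit decides
   (`no_plant_hit_tophit_same_genus` / `..._other`). The relaxed search uses
   the read-search machinery — identity floor `relaxed_min_identity`
   (default 0, i.e. best hit regardless) *plus the 0.80 coverage
   requirement*, ordered identity/score/id. Ranking by identity alone is
   degenerate (see the alignment caution above). Hits tied on
   (identity, score) are resolved by their LCA genus. If nothing passes at
   all, the barcode is flagged mislabeled with empty evidence and a warning —
   the conservative reading of an undefined case;
4. evaluated last and overriding 2–3: any exact hit whose lineage class is
   known and differs from Magnoliopsida ⇒ mislabeled
   (`non_magnoliopsida_hit`). Only exact matches are considered here, as the
   procedure is written.

Decisions are per-barcode and independent, so cleaning is deterministic and
order-independent. The report counts decisions per rule and per locus and the
removed fraction per locus. Published removal fractions depend on external
database versions and are not reproduction targets.

## Genus profiles

Implausible genera are excluded **before** proportions are computed
(default exclusion list: *Clusia*, *Hirtella*, *Parinari*), keeping
proportions interpretable as shares of plausible pollen. Then
m(g) = max(ITS1, ITS2) count, p(g) = m(g)/Σ m(g); pre-threshold proportions
sum to 1. Sample QC requires matched reads (genus-assigned plus
matched-unassigned) to reach 5% of processed reads with both loci pooled; the
threshold is inclusive (exactly 5% passes). The 1% retention threshold is
likewise inclusive. Retained proportions are reported un-renormalized by
default — the printed procedure never renormalizes — with renormalization
over the retained set available as an option; both paths are also exposed for
the host-plant proportion, since it is not documented which the original
summaries used. Host-plant proportion sums retained proportions whose family
is in the host set (Rosaceae, Fabaceae by default); a retained genus with
unknown family contributes zero and is logged.

## Nutrition and rearing

P:L ratios are computed per sample and then summarised (never as a ratio of
means); SE = sample SD (n−1 denominator)/√n, undefined at n = 1. Diet
formulation uses the dilution-ignored convention — concentrations per mg of
*base pollen* — because published formulation tables keep the base protein
concentration unchanged when only lipid is added; a mass-balance
(dilution-aware) mode divides by total diet mass instead, leaving the ratio
identical. Exactly one additive is used per target; additive purities default
to 1.0 (pure casein / pure oil) and are overridable. The formulate→ratio
round trip returns the target to ~1e−9. Control diets of homogenized
bee-collected provisions carry a presumed 3:1 label, treated as a label
rather than a measurement.

Survival summaries use these denominators: cocoon completion over all
individuals; pupation and adult survival over cocoon completers (adult
outcomes are only defined for bees that survived the larval stage — the
published models state this convention only for the adult stage, and it is
adopted for pupation too). Development-time medians ignore unknown timings.
Inferential statistics (ANOVA, GLMs, Kruskal–Wallis) are deliberately out of
scope; the summaries are tidy tables any standard routine can consume.

## Synthetic data

All generators are pure functions of (config, seed). One global seed expands
into fixed per-stream substreams (database / reads / nutrition / rearing,
with reads further keyed by a CRC of the sample id), so adding one generator
call never perturbs another stream, and identical configs give byte-identical
output files.

**Reference databases.** A random root sequence per locus is evolved into
genus founders (default substitution fraction 0.15 per base, i.e. ≈26%
pairwise divergence between genera — far outside the 95% identity acceptance
radius) and founders into species (default 0.01 — congeneric references stay
within the acceptance radius of each other's reads, as real congeneric ITS
variation does at genus scale). Identical congeneric sequences are tolerated;
a sequence shared across genera triggers regeneration (bounded retries).
Plant contrast records embed each true sequence in random 20-bp flanks, so
exact matching genuinely exercises substring containment; non-plant
contaminants are random sequences under fungal lineages. Mislabels are
planted by replacing round(rate·N) barcodes' sequences with exact copies from
another genus or the contaminant pool, label unchanged, truth recorded — on
this truth the cleaner's precision and recall are exactly 1, which is a test
of the cascade's logic, not of real-database performance.

**Reads.** Per locus, the genus composition is reweighted by that locus's
amplification bias, counts are multinomial, and each read copies a uniformly
chosen conspecific *true* sequence (never a planted mislabel) with
substitution errors at the configured rate (default 0.01; no indel or
chimera error model). The default "paper-like" preset uses five genera at
0.40/0.30/0.15/0.10/0.05 — the two host-family genera dominant — with 2000
reads per locus and a 2-fold bias favouring each genus at exactly one locus
(alternating), which makes the dual-locus maximum rule consequential: per
genus, the better-amplified locus supplies the count.

**Nutrition.** Protein and lipid are independent zero-truncated normals;
moments are interpreted pre-truncation (truncation bias is negligible at
these CVs). Defaults: protein 151.42 ± 47.78, lipid 53.94 ± 20.66 µg/mg —
means from field provision surveys, SDs reconstructed from the printed
standard errors at the 59-sample scale the summaries use. One mathematical
consequence is documented rather than hidden: a zero-truncated normal has
positive density at zero, so the exact expectation of the P:L ratio diverges
(logarithmically) and rare near-zero lipid draws produce extreme ratios. The
oracle used in tests, `implied_ratio_mean(config, n)`, is therefore a
*finite-sample predictive* mean with the lipid integral cut at the 1/n tail
quantile — the region a sample of size n explores — computed by log-spaced
quadrature. Real provision data show no near-zero lipid values; the normal
left tail is a model artefact to keep in mind when interpreting synthetic
ratio summaries.

**Rearing.** Stage-conditional Bernoulli draws — P(cocoon), P(pupate|cocoon),
P(adult|pupate) per diet — so the stage ordering holds by construction;
development times are shifted Poisson (10 + Pois(4) days to cocoon,
30 + Pois(10) to pupation) and unknown for unreached stages. Default per-diet
probabilities qualitatively mirror the published outcome pattern (controls
and *Acer rubrum* do well; *Salix nigra* and *Dactylis glomerata* groups
produce no pupae).

What the generators do **not** emulate: ITS secondary structure and
copy-number variation, indel/chimera/PCR-duplicate error, real amplification
biases (free parameters here), the skew of real nutrition distributions, and
any correlation between protein and lipid. Passing tests therefore
demonstrate that the *procedures* are implemented correctly and recover known
truth under their stated assumptions — not that the published field values
would be reproduced from raw data.

## Problem sizes and numerical conventions

The test and acceptance workloads run at desk scale by choice: reference sets
of 30–100 barcodes, 2000 reads per locus per sample, alignment oracles on
≤ 40-bp pairs, 10⁴-draw moment checks. Tabular outputs are tab-separated
UTF-8 with one header row, stable column order and floats at 6 significant
digits; all thresholds that shaped a pipeline run are echoed in
`run_summary.json`. Every dropped barcode, read, genus or sample is logged
with the rule that dropped it, because the filters *are* the analysis.

## Known limitations

* Genus-level assignment only; no species resolution, no marker copy-number
  abundance correction.
* The cleaner assumes contrast databases are themselves trustworthy; it
  detects label/sequence disagreement, not shared contamination.
* Bulk P:L summaries ignore micronutrients, amino-acid and fatty-acid
  composition, and co-extracted non-polar compounds that inflate lipid
  estimates — the ratio is a coarse niche proxy by design.
* The CLI is a thin convenience layer; the importable API is the primary
  interface.
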