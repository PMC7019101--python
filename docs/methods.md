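# Methods

## Variant records and dialects

A variant record carries an rsID, a protein change (`R672G` style, 1-based
residue index), a consequence category, a variant class, allele
frequency/count fields, optional per-population (`pop_<label>`) and per-sex
carrier counts, and six predictor scores. Score ranges are enforced at load
time (PolyPhen-2 and SIFT and PhastCons in [0,1], Grantham in [5,215], GERP
in [−12.3, 6.17]; PROVEAN unbounded); out-of-range cells fail the load with
the row and column named, since silently clamping predictor scores corrupts
downstream thresholding. Consequence vocabulary folds Sequence-Ontology
synonyms into four categories: stop-gained / splice-donor / frameshift →
`lof`; missense; synonymous; everything else (UTR, splice-region, intronic,
unknown) → `other`. Unknown terms warn rather than fail because source
vocabularies drift between database releases.

Coding-table filtering removes, in order: indel and start/stop-loss
records, records without an rsID, and duplicate rsIDs. Duplicates keep the
first occurrence by row order — the sources state only that duplicates were
removed, and first-occurrence keeps the filter order-stable and idempotent.
rsID is the sole join key for cross-database intersection; protein-change
string matching as a fallback identity is deliberately not implemented
(ambiguous across transcripts).

## Consensus prioritization

Per-metric deleterious flags: PolyPhen-2 passes when the class is
probably-damaging **and** the score meets `polyphen2_score_min`; Grantham,
PhastCons and GERP pass at or above their cutoffs (125, 0.95, 2.0);
PROVEAN and SIFT pass strictly below theirs (−2.5, 0.05). A missing score
is flagged `missing` and never passes. The Grantham boundary is inclusive
(≥ 125) because published annotation practice stars 125 itself; PROVEAN
and SIFT boundaries are strict per their standard definitions. PhastCons
and GERP have no canonical published cutoffs; 0.95 and 2.0 are defaults
chosen so that strongly conserved sites pass, and both are configuration
fields excluded from the `class_only` rule.

Three consensus modes are shipped because the strict reading ("all metrics
beyond threshold") conflicts with the observable outcome on the reference
24-variant table, where most rows fail at least one of Grantham / PROVEAN /
SIFT. The reproduction default is `class_only` with
`polyphen2_score_min = 0.97`, the rule consistent with all 24 reference
variants (their PolyPhen-2 scores span 0.971–1.0); `all_metrics` (which
keeps exactly R672G, G754R, D429V on that table) and `k_of_n` serve the
stricter readings.

MAF benchmarking is a strict `<` comparison against reference pathogenic
allele frequencies (defaults: the two SCN5A benchmarks 6.5×10⁻⁴ and
1.9×10⁻³). Variants without a recorded frequency are dropped by the filter:
absence of evidence of rarity is not rarity.

Ranking uses descending lexicographic order on (number of passing metrics,
PolyPhen-2 score, −SIFT, −PROVEAN), ties broken by rsID. No canonical
ranking exists for this kind of consensus profile; this key orders by
breadth of predictor agreement first and then by the most quantitative
scores, and it uniquely places R672G first on the reference table.

## Hotspot detection

Given m variant residue positions on a protein of length L, candidates are
all intervals whose endpoints are observed (distinct) position values — d
distinct values give d(d+1)/2 candidates, so no cluster size or width is
pre-specified. Duplicate positions add multiplicity to member counts but do
not duplicate candidates.

The null redraws m positions i.i.d. uniformly (with replacement) over
1..L, B times. For each replicate the tightest window containing c
positions (c = 1..m) is the minimum over sliding windows of c order
statistics: min_j (p[j+c−1] − p[j] + 1). A candidate with n members and
span s is scored

    p = (1 + #{replicates: min_width(n) ≤ s}) / (B + 1),

i.e. the bootstrap probability that uniform placement packs n variants at
least as tightly anywhere in the protein, with the +1 pseudocount avoiding
zero p-values under a finite null. Benjamini–Hochberg step-up correction
(q_(i) = min_{j≥i} p_(j)·n/j, significant at q ≤ α, α = 0.05) is applied
across all candidates, and the per-residue track counts covering
significant clusters.

Defaults: L = 1,391 (NUP155; its largest annotated variant position is
residue 1389), B = 1,000, α = 0.05. B = 1,000 bounds the attainable
p-value at 1/1001 ≈ 0.001; with ~300 candidates this is the smallest B at
which a genuinely tight cluster can clear the BH threshold comfortably.
Determinism: all resampling flows from one integer seed through
`numpy.random.default_rng`.

Behaviour on the real 24-variant NUP155 positions: this statistic finds no
individually significant cluster (the positions are concentrated in the
mid-protein but not tightly enough for the minimal-window test at m = 24).
The published per-residue heatmap was produced by a different, unpublished
rendering of the cluster statistic and is not a reproduction target; what
this module guarantees instead is calibration (uniform-null false-discovery
proportion ≈ 0 at B = 200) and power (a 100-residue window holding 12 of
24 positions is recovered in well over 90% of runs at B = 1,000), both
exercised in the test suite.

## Domain enrichment

Subdomains are named, non-overlapping, 1-based inclusive residue intervals
supplied as a 3-column TSV (protein coordinates, not genomic BED).
Enrichment of m positions in a domain of span w is the exact one-sided
binomial tail P(X ≥ obs), X ~ Binomial(m, w/L). The boundaries shipped in
`analysis/04_domain_enrichment.py` (β-propeller 1–510, crescent α-helical
511–870, C-terminal stack 871–1391) are **illustrative**: published
structural descriptions of NUP155 do not pin residue-exact subdomain
limits, so the intervals are configuration, not assertion.

## Network topology

Graphs are undirected and simple (duplicate/reversed edges collapse,
self-loops drop with a warning); SIF interaction types are kept as edge
annotations but ignored by metrics. Conventions follow Cytoscape's Network
Analyzer: betweenness normalized by (n−1)(n−2)/2, closeness in the
Wasserman–Faust form (fraction-reachable scaling, well-defined on
disconnected graphs), neighborhood connectivity as mean neighbor degree
(undefined for isolates). Assortative mixing is classified from the sign
(tolerance 10⁻⁹) of the least-squares slope of log mean neighborhood
connectivity against log degree over degree classes k ≥ 1; only the sign is
contractual — the magnitude depends on binning and is not comparable across
tools. Hub ranking is descending on the chosen centrality, ties broken by
the other centrality and then label.

## Synthetic data

The variant generator draws residue positions from a mixture of weighted
hotspot intervals (weights are mixture probabilities summing to ≤ 1) over a
uniform background, class labels (damaging/benign) as Bernoulli(class_mix),
and per-class scores from beta distributions oriented toward each metric's
deleterious or tolerated extreme, shaped so default thresholds separate the
classes imperfectly (~10% overlap) as real predictors do. Allele
frequencies are log-uniform over 10⁻⁵·⁴–10⁻³·¹⁵, matching the observed
range of the reference table (4×10⁻⁶–7×10⁻⁴). Scores can be pinned per
class for construction-style tests. What the generator does **not**
emulate: linkage between predictors (real scores are correlated through
conservation), transcript-level annotation ambiguity, population structure
behind the frequencies, and genotype-level data — so passing tests
demonstrate the pipeline's statistical behaviour under its stated model,
not performance on raw database exports.

The graph generator grows preferential-attachment networks (new nodes
attach to `attachment = 2` existing nodes with probability ∝ degree), with
planted hub labels receiving an attachment-weight boost (×8) so hub
recovery has ground truth. Generated graphs are disassortative by the
neighborhood-connectivity criterion in ≈100% of seeds at n = 175.

The coding-table generator mixes clean unique missense SNVs with exact
counts of indel/start-stop-loss rows, duplicate-rsID rows and rsID-less
rows, shuffled deterministically — used to exercise the 724 → 645 filter
arithmetic.

## Pipeline and reproducibility

`run_pipeline` composes prioritize → MAF → rank → hotspot → domains →
network with individually skippable stages; executed stages are unaffected
by skipped ones. The JSON manifest records package version, seed, SHA-256
digests of file inputs and per-stage counts — no timestamps — so a fixed
config yields bit-identical runs. The `reproduce-nup155` CLI command
bundles the packaged fixture with the reproduction thresholds to regenerate
the 24 / 23 / R672G-first results.

## Problem sizes

Test and analysis runs use B = 200–1,000 bootstrap replicates, 50-seed
simulation batches for calibration/power properties, 20-seed batches for
graph properties, and exhaustive enumeration oracles at m ≤ 3, L ≤ 10
(≤ 1,000 outcomes) and all 208 simple graphs on ≤ 6 nodes. These sizes give
standard errors comfortably inside the asserted margins.

## Known limitations

- The hotspot statistic is one concrete empirical rendering of
  minimal-window cluster testing; other renderings (e.g. analytic
  order-statistic p-values) would give different per-cluster p-values,
  though the calibration and power guarantees are the same in kind.
- Candidate p-values are strongly dependent (nested intervals); BH is
  applied as-is, which the null-calibration test shows is conservative
  here.
- Domain boundaries and the PhastCons/GERP cutoffs are documented defaults,
  not published constants.
- `class_only` reproduces the reference prioritization; whether the
  original 72 → 24 reduction also used conservation cutoffs is not
  determinable from public materials, so both readings ship.
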