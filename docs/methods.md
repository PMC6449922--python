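# Methods

This note documents the models, numerical conventions and design choices
behind `m2f`, in the order data flows through the pipeline.

## The synthetic pan-genome model

`m2f.simulate.PanGenomeModel` describes a star of independent genome pairs:
each pair descends from its own ancestor, and each lineage evolves for a
divergence time `t` under two decoupled rates.

**Marker substitution.** Every marker site (16S copies; the five MLSA
genes) substitutes with probability `q = marker_sub_rate * t` per lineage,
uniformly to one of the other three bases, with no indels. The expected
per-site disagreement between the two lineages is then

    d = 2q(1-q) + (2/3)q^2

(the q^2 term covers both lineages mutating to different bases), and the
stored `expected_marker_identity` is `100*(1-d)`. Keeping markers
indel-free keeps this arithmetic exact and makes identity comparisons
against the alignment kernel trivially checkable.

The 39 nt of the embedded 515f/926r priming sites are held invariant under
16S mutation. These sites are strongly conserved in nature — that is what
makes the primers "universal" — and without the exemption uniform mutation
destroys most amplicons at deep divergence, the opposite of real V4
datasets where the large majority of genomes amplify. One consequence:
realized 16S identity sits marginally above the analytic expectation (39 of
1550 sites cannot diverge); the V4 region itself lies strictly between the
primer sites and is unaffected.

**Gene turnover.** The proteome is `n_core` core families (never lost)
plus the five MLSA genes plus a pool of `n_accessory_pool` accessory
families, each present in the ancestor with probability `p_accessory`.
Per lineage, each present accessory family is lost with probability
`gene_turnover_rate * t` and each absent pool family is gained with the
same probability (gains draw the pool sequence unchanged, mimicking recent
horizontal acquisition). Because `gene_turnover_rate >> marker_sub_rate`
by default, shared gene content drops quickly while markers still read
99–100 % identical — the fast, phylogeny-independent component — and then
continues to decay towards the core fraction as divergence grows. The
rates are free model knobs, not calibrated to any published corpus.

**Truth.** `true_shared_fraction = 2|A∩B| / (|A|+|B|)` is computed from
the realized family presence lists, never from sequence, and is re-derivable
from the emitted GFF files (each feature carries a `family=` attribute).

**Within-family divergence.** By default gene sequences are identical
across a family (`gene_sub_rate = 0`), which makes downstream recovery
checks exact. A nonzero `gene_sub_rate` applies codon-safe per-site
substitution to every CDS (mutated codons that would become stops are
repaired or reverted); `gene_sub_rate = 0.02` over the default strata gives
roughly 10 % amino-acid divergence between lineages at the deepest stratum.

**Defaults and why.** `n_core=50`, `n_accessory_pool=100`,
`p_accessory=0.4` give ~95-gene proteomes — two orders of magnitude below
real genomes but with the same core/accessory structure; gene lengths are
uniform over 300–1500 nt (mean ~900 nt, the typical bacterial CDS length),
16S is fixed at 1550 nt with the V4 region spanning 373 nt between the
primer sites; rRNA copy number is uniform on 1–4 with extra copies diverged
at 0.5 % per site (real copies are mostly >99 % identical); divergence
strata (0.02, 0.1, 0.25, 0.5, 1.0) with `marker_sub_rate=0.05` span
expected marker identities from ~99.8 % down to ~90 %. N-stretch artifacts
(a ≥10 nt run of `N` replacing an internal window of a 16S copy) are
injected with probability `n_artifact_prob` per copy.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic nucleotide composition and codon usage,
operon structure, indels, paralogy and many-to-many orthology, rate
variation across genes and sites, phylogenies deeper than independent
pairs, and annotation noise. The generator validates the *machinery*
(extraction, clustering, matching, statistics), not biological effect
sizes.

## Marker extraction

GFF3 coordinates are treated as 1-based inclusive and converted to 0-based
half-open indices only at the slicing boundary; minus-strand features are
reverse-complemented so every record reads 5'→3'. 16S records shorter than
1000 nt are dropped and reported. A copy is flagged as an assembly artifact
when it contains ≥10 consecutive `N` or when its global alignment against
the genome's most-common-length sibling copy has >20 % gap columns; both
thresholds are module constants, overridable in the run config, and flagged
copies are excluded from copy statistics and downstream datasets.

V4 in-silico PCR matches the forward primer under IUPAC degeneracy (an `N`
in the subject matches nothing), then the reverse complement of the reverse
primer strictly downstream; the leftmost valid site pair wins and the
returned amplicon *excludes* both primers (common amplicon convention; an
`include_primers` flag provides the inclusive reading). Zero mismatches
beyond degeneracy is the default, configurable per run.

MLSA concatenation requires all five housekeeping genes (S12, S15, GTPase
Der, ATP synthase delta, CTP synthase), matched by a curated
product-synonym table, present exactly once; genomes failing that are
excluded and listed in the extraction report, in canonical concatenation
order S12–S15–Der–delta–CTP.

## Identity kernel and clustering

Percent identity is computed from a global affine-gap alignment (match +1,
mismatch −2, gap open −4, gap extend −1) as matches over alignment columns
excluding terminal-gap runs; `N` never counts as a match. Because
co-optimal alignments can differ in match count, the pair is always aligned
in a canonical argument order, making the function exactly symmetric. An
edit-distance bound (edlib) lets clustering skip pairs that provably cannot
reach the threshold minus a one-point safety margin; the bound is
conservative, and a `prefilter=False` switch forces full dynamic
programming (tests assert both paths agree).

Greedy centroid clustering processes records in (length descending, id
ascending) order; each record joins the **best**-scoring centroid at or
above the threshold (not the first, so scan order cannot matter), ties to
the earlier-founded centroid, else founds a new group. Identities are
rounded to 4 decimals before threshold comparison to avoid floating-point
boundary flapping. Genus concordance is the fraction of genomes — among
those sharing a group with at least one other genome — whose every
group-mate has the same genus.

## Orthology and percent shared genes

Proteins are compared by local Smith–Waterman under BLOSUM62 (gap open −11,
extend −1); letters outside the standard 20 map to `X`. A hit requires raw
score ≥50 and query coverage ≥50 %; best hits per direction that agree form
the matched set (greedy one-to-one by score; best-hit maps are already
injective, the sort only pins tie behaviour). This single-linkage RBH is a
deliberate simplification of orthogroup clustering, which admits
many-to-many groups; with the generator's one-gene-per-family structure the
two coincide.

The all-vs-all search takes two shortcuts that do not change results on
this data: identical sequences short-circuit to their self-score (an upper
bound on any local alignment score, hence always a best hit), and pairs of
proteins ≥40 aa sharing fewer than four 6-mers are skipped — unless they
have equal length and ≥50 % positional identity, a rescue that covers
short, highly diverged homologs (equal length is guaranteed within a family
because markers and genes never gain indels). Both shortcuts are
disable-able (`prefilter=False`) and the test suite asserts agreement with
the exhaustive path.

Percent shared genes counts a matched pair once per genome:
`100 * 2M/(nA+nB)` ("dual" formula, the default); a union-of-families
reading `100 * M/(nA+nB−M)` is available as `formula="union"`.

Unmatched proteins can be validated by local alignment against all
stop-free segments (≥20 aa) of the partner genome's six-frame translation
(bacterial code, table 11); a find requires identity >70 %, query coverage
>70 % and the raw-score floor. No e-value is computed: an e-value needs a
database-size model that is meaningless at this corpus scale, so the raw
score floor stands in while the 70/70 thresholds are kept as stated.

## Binning and statistics

A genome pair belongs to the highest threshold at which any of its marker
copies share a cluster group (the any-copy rule — the most permissive
reading for multi-copy genomes, consistent with cluster-driven pair
selection); pairs never co-clustering at the lowest threshold are excluded.
Boxplot tables use linear-interpolation (type 7) quartiles and 1.5×IQR
whiskers — conventions pinned here because figure tools differ.

The lineage analysis labels each comparison with the shared taxonomy class,
pooling cross-class pairs as "Other", runs a Kruskal–Wallis omnibus, then a
Dunn z-test of each lineage against the pooled remainder with tie-corrected
rank variance and Bonferroni correction over the number of lineages. The
each-vs-rest contrast matches the question "is this lineage different from
the complete dataset?"; all-pairs contrasts are available behind a flag.
Direction (higher/lower) is reported only for adjusted p below alpha.
Monte-Carlo checks put the null rejection rate well under the nominal level
and power ≥95 % for a +15-point lineage at n=50 per group.

## GO enrichment

Annotations are closed under `is_a` ancestry (true-path rule, set
semantics; cycles are an error) before counting. Counting is
comparison-level: a protein occurring in k comparisons contributes k times,
and both members of a matched pair contribute. Each term is tested with a
two-sided Fisher exact test within its namespace against the totals of
annotated shared/unshared occurrences; namespace roots are never tested;
significance is raw p < 0.01 with optional Benjamini–Hochberg adjustment
behind a flag. No DAG-decorrelation heuristic is applied — ancestor terms
of an enriched term will often be enriched too, which is the classic
Fisher behaviour and should be kept in mind when reading the tables.

The bundled ontology (`m2f.simulate.toy_ontology`) is synthetic: a small
backbone of real GO identifiers (so tables read naturally) plus generic
filler terms, with a couple of diamonds for closure testing. It carries no
curated semantics.

## Problem sizes

The validation experiments use 40 genome pairs per divergence stratum (200
pairs per corpus) with the default ~95-gene proteomes, 100 replicates for
the statistical calibrations, and 200 random tables for the Fisher check —
sizes chosen so the full validation runs comfortably on a laptop core while
keeping Monte-Carlo error far from the asserted bounds.

## Known limitations

* RBH orthology ignores paralogy; real proteomes would need orthogroup
  clustering and the shared-gene statistic would depend on how
  many-to-many groups are counted.
* The identity kernel's scoring scheme is fixed; published clustering
  tools use internal, partly undocumented identity definitions, so group
  boundaries near a threshold may differ from theirs.
* Comparison-level GO counting inflates counts for proteins recurring
  across many comparisons of the same genomes; with the star-shaped
  synthetic corpora comparisons are disjoint, but on real overlapping
  cluster groups the Fisher p-values would be anti-conservative.
* The generator's gain model re-introduces pool families at the turnover
  rate, so beyond `gene_turnover_rate * t ≈ 0.5` shared content stops
  being monotone in time; the default strata stay well inside that range.
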