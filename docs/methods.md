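# Methods

This note documents the models, conventions and numerical choices behind
`barcodegap`, and what the synthetic benchmarks do and do not establish
about real data.

## Distances

Pairwise distances follow the Kimura 2-parameter model. For a pair of
gap-free, equal-length sequences, `P` is the proportion of compared sites
differing by a transition (A↔G or C↔T), `Q` the proportion differing by a
transversion, and

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q).

The estimator is undefined when 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 (saturation).
Undefined pairs are never silently converted to NaN: the distance matrix
carries an explicit mask, summaries exclude flagged pairs and report their
count, and tree builders refuse matrices containing them (the caller must
drop or impute the affected accessions). This mirrors how distance software
surfaces inapplicable pairs rather than corrupting means.

**Complete deletion** is applied alignment-wide, not pairwise: every column
containing a gap *or an ambiguity code* in any sequence is removed before
any pair is compared, so all pairs see an identical site set. Ambiguity
codes (N, R, Y, …) are treated as missing throughout — for deletion, for
variable/parsimony-informative site counts, and for diagnostic characters —
the conservative convention that avoids inflating apparent variation.
Mean sequence length averages ungapped lengths (biological amplicon
lengths, not alignment width).

## Barcode-gap and discrimination criteria

Per species, the package reports the maximum intraspecific distance, the
minimum interspecific distance *over pairs involving that species*, and the
ratio of the species' mean inter- to mean intraspecific distance. A species
is **discriminated** when min-inter is strictly greater than max-intra;
ties fail. Species without intraspecific pairs (single accessions) are
flagged not-evaluable rather than counted either way. The **barcode-gap
test** is a paired two-sided t-test of min-inter against max-intra across
evaluable species; a significantly positive difference indicates a gap.
Locus comparisons use one-way ANOVA with all pairwise two-sample t-tests
Bonferroni-adjusted as p×m capped at 1 (the simplest multiple-comparison
correction consistent with that name); an optional log(x + 1e-6) transform
stabilises variances of near-zero distance sets.

## Trees and species recovery

Neighbor joining (Saitou–Nei) and UPGMA are implemented directly rather
than delegated, because reproducibility of the evaluation requires a
*deterministic tie-break*: whenever the Q-matrix (NJ) or the minimum
average linkage (UPGMA) has tied argmins, the pair whose cluster
representatives (smallest leaf label per cluster) sort lexicographically
first is merged. Negative NJ branch-length estimates are clamped to zero
with the deficit moved to the sibling edge (Kuhner–Felsenstein); this
changes lengths only, never topology. Library implementations (scikit-bio
`nj`, scipy average linkage, dendropy bipartition counting) serve as
independent cross-checks in the test suite.

Bootstrap resamples complete-deleted alignment columns with replacement
(same length) per replicate; replicates whose resampled matrix contains
undefined distances are skipped and counted. Consensus trees (strict and
>50 % majority rule) are built by bipartition counting; supports are
bipartition frequencies × 100.

**Monophyly** is evaluated in the unrooted sense: a species is recovered
iff some bipartition separates exactly its accessions from all others.
Single-accession species count as recovered (this matches the denominators
of published recovery tables; the convention is explicit in the API and
trivially adjustable by filtering the report). Recovery percentages are
scored on the point-estimate tree built from the full data, with bootstrap
supports reported separately, and are rounded to one decimal.

## Diagnostic characters

Positions are reported in reference coordinates: the user supplies a
reference sequence aligned with the data and the 1-based offset within the
ungapped reference that becomes position 1 (start of ITS1, first base of a
start codon, first spacer position, …). Columns where the reference has a
gap carry no coordinate and are skipped.

A *simple* character requires every member accession (at least
`min_accessions`, default 3) to share one unambiguous state that no
non-member shows at that position. Gaps/ambiguities within the species
disqualify the site (fixation cannot be claimed); missing data in
non-members does not block a character but is counted and reported.
*Compound* characters are minimal combinations (k = 2..3 by default) of
individually non-diagnostic fixed positions whose joint pattern occurs in
no non-member; minimality means no proper subset is itself diagnostic, so
positions carrying a simple character never appear in compounds.
Disjunctive characters (alternative states at a position) are verified via
`verify_character` when supplied but not enumerated — there is no
well-defined generative rule for them. The combinatorial search is capped
(default 200 000 combinations per species) and returns partial results with
a warning when exceeded.

## AFLP analysis

A band is polymorphic iff neither present in nor absent from all
accessions; species-unique bands must be present in at least one accession
of exactly one species. Jaccard similarity a11/(a11+a10+a01) ignores joint
absences (a dominant marker's joint absence is uninformative); bands from
all primer pairs are concatenated into one profile, and 1 − S is the
distance clustered by UPGMA and ordinated by PCoA.

PCoA is classical scaling: B = −½·J·D²·J with J the centering matrix,
eigendecomposition of the symmetrised B, coordinates =
eigenvectors·sqrt(λ) for positive λ. Jaccard distances need not be
Euclidean, so negative eigenvalues can occur; they are reported uncorrected
(no Cailliez/Lingoes adjustment) and the per-axis variance fraction is
computed over positive eigenvalues only. Both conventions are recorded in
the result object.

The Mantel test is one-sided for positive association, permuting rows and
columns of the second matrix jointly; p = (#{r_perm ≥ r_obs} + 1)/(B + 1)
with B = 999 by default and an explicit seed. Geographic distances are
geodesics on the WGS84 ellipsoid via the iterative Vincenty inverse
(convergence 1e-12 rad, ≈ sub-millimetre), with a spherical haversine
fallback for the nearly antipodal pairs where the iteration cannot
converge; agreement with an independent geodesic implementation is ~1 m on
continental-scale pairs. Accessions lacking GPS records are excluded with a
warning.

## Synthetic data generator

The generator emulates a single-genus barcoding survey: `n_species` = 16
species in 4 geographic regions, 5 accessions per species, and four loci
whose lengths and depths are calibrated to the magnitudes typical of plant
barcodes — a variable nuclear spacer (602 bp, interspecific depth 0.0070,
intraspecific 0.0015 substitutions/site), two slow plastid coding loci
(488 bp at 0.0031/0.0005 and 479 bp at 0.0007/0.00005) and a moderately
variable plastid spacer (410 bp at 0.0056/0.00045). With tree height h and
star-shaped accession clusters, conspecific pairs diverge by exactly
2×intra-depth in expectation, and heterospecific pairs by
2·(1 − split)·h + 2·intra, giving interspecific means in the 0.001–0.01
band and heavy intra/inter overlap at the nuclear locus — the regime in
which barcode loci fail.

The species tree is a Yule (pure-birth) tree simulated forward (k lineages
wait Exp(k)) and rescaled to unit height. Raw Yule split depths can fall
arbitrarily close to the tips, which would create pairs of "species" with
essentially zero divergence; since grafting accession clusters onto species
tips presumes the species are distinct lineages, split depths are
compressed into [0, 1 − stem] with `species_stem_fraction` = 0.1, i.e.
every species keeps a terminal branch of at least 10 % of the tree height.

Sequences evolve site-independently under the K80 process with
transition/transversion rate ratio κ (default 2): the rate matrix is scaled
to one expected substitution per unit branch length and per-branch
transition matrices are obtained by matrix exponential, so simulation is
exact at any depth. Gene flow is modelled as whole-haplotype reassignment:
with probability `gene_flow` an accession's lineage re-attaches to a random
co-regional heterospecific species tip before sequences evolve (a minimal
stand-in for hybridization/introgression; no recombination, so each
accession is entirely native or entirely introgressed). All exchanges are
recorded in the truth record.

AFLP band presence is Bernoulli with probability
logistic(base + s·z_sb + g·z_rb), standard-normal z per (species, band) and
(region, band); defaults (base −0.6, species effect 0.6, region effect 1.2)
put the regional signal above the species signal, reproducing the
geography-over-species clustering regime, with ten primer pairs whose band
counts follow a published survey's layout (85…46, 784 bands total) plus 8
planted species-private bands. GPS coordinates are drawn around fixed
regional centroids (σ = 0.3°).

**What passing tests show — and don't.** The generator produces gap-free,
perfectly aligned, complete data: no indels, no alignment error, no
missing loci, no ITS paralogy, no AFLP scoring noise or size homoplasy.
Pipeline results on synthetic data therefore validate the *statistical
machinery* (estimator correctness, criterion logic, qualitative behaviour
under gene flow), not robustness to the data-quality problems of real
surveys.

## Problem sizes and numerical choices

Default analyses run a 16-species × 5-accession design (80 sequences per
locus, 3 160 pairs) and a 13-species AFLP survey (52 accessions, ~790
bands); the test suite uses these sizes or smaller, with bootstrap counts
of 10–50 in tests (500 is the analysis default) and 199–999 Mantel
permutations. Tolerances: tie detection in tree merges at 1e-12 absolute;
PCoA positive-eigenvalue threshold 1e-10 relative to the leading
eigenvalue; Vincenty convergence 1e-12 rad with 200 iteration cap.
Degenerate inputs (single-sequence alignments, all-gap columns, all-zero
band profiles, species without intraspecific pairs) raise errors or are
flagged not-evaluable as documented per function rather than being guessed
at.

## Known limitations

- Only the K2P model is implemented (no JC/TN93/GTR, no gamma rates), as
  the evaluation criteria are defined on K2P distances.
- Maximum parsimony is not implemented; tree-based recovery covers NJ and
  UPGMA.
- The compound-character search enumerates conjunctions only; disjunctive
  characters are verified, not discovered.
- Consensus trees carry topology and support but no branch lengths.
- The Mantel test assumes complete distance matrices; accessions with
  undefined Jaccard entries or missing GPS must be dropped first.
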