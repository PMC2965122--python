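# barcodegap

Evaluation of candidate DNA barcode loci and AFLP fingerprints for species
discrimination in taxonomically difficult plant groups.

DNA barcoding assigns specimens to species from short standardized loci
(nuclear ITS; plastid *matK*, *rbcL*, *trnH-psbA*). Whether a locus works
for a given genus hinges on the **barcoding gap** — the separation between
the largest intraspecific and the smallest interspecific genetic distance —
and on whether species come out **monophyletic** in trees built from the
locus. In groups with hybridization or recent divergence both criteria can
fail, and genome-wide fingerprints (AFLP) may cluster specimens by
geography rather than by species. `barcodegap` implements this entire
evaluation pipeline, together with a synthetic-data generator so that every
stage can be validated against known ground truth.

## What it computes

**Distance-based criteria.** Pairwise distances use the Kimura 2-parameter
model, which corrects the observed proportions of transition-differing
sites *P* (A↔G, C↔T) and transversion-differing sites *Q* for multiple
hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

computed after *complete deletion* (every alignment column containing a gap
or ambiguity in any sequence is removed first). On top of the matrix the
package partitions divergence into intra- and interspecific components,
applies the per-species discrimination criterion (minimum interspecific
distance strictly greater than maximum intraspecific distance), tests for a
barcoding gap with a paired t-test across species, and compares loci by
one-way ANOVA with Bonferroni-corrected contrasts.

**Tree-based criteria.** Neighbor-joining and UPGMA trees from the K2P
matrix, column-resampling bootstrap, strict and >50 % majority-rule
consensus, and the percentage of species recovered as exclusive clades
(unrooted bipartitions; singletons count as recovered), for single loci and
for the concatenation of accessions sequenced at every locus.

**Character-based identification.** Simple diagnostic characters (a
nucleotide state at a single position fixed in a species and absent
elsewhere) and minimal compound characters (joint state combinations at
2–3 positions), numbered in the coordinates of a reference sequence aligned
with the data. A 5.8S motif check (`GAATTGCAGAATCC` vs the fungal
`GAATTGCAGAATTC` variant) screens ITS sequences for fungal contamination.

**AFLP diversity.** Polymorphism and species-unique band accounting per
primer pair, Jaccard similarities (joint absences ignored), a UPGMA
phenogram with its cophenetic correlation, principal coordinates analysis
(Gower double-centering, positive-eigenvalue variance fractions), and a
seeded one-sided Mantel permutation test of Jaccard distance against WGS84
geodesic distances from GPS records.

**Synthetic data.** A Yule species tree scaled to a per-locus
interspecific depth carries star-shaped accession clusters at an
intraspecific depth; sequences evolve under the K80 process (matrix
exponential per branch). Optional gene flow re-attaches accessions to
co-regional heterospecific lineages, emulating introgression. AFLP matrices
are drawn with logistic species- and region-structured band frequencies and
planted species-private bands. All outputs are byte-reproducible from a
seed.

## Worked example

```python
from barcodegap import (SimConfig, simulate_species_dataset,
                        pairwise_matrix, partition_divergence,
                        species_gap_stats, barcode_gap_test,
                        nj_tree, species_recovery)

cfg = SimConfig(seed=1)          # 16 species x 5 accessions, 4 loci
alns, species, truth = simulate_species_dataset(cfg)
dm = pairwise_matrix(alns["ITS"])
div = partition_divergence(dm, species)
print(f"mean inter {div.mean_inter:.4f}  mean intra {div.mean_intra:.4f}")
gaps = species_gap_stats(dm, species)
disc = sum(1 for g in gaps if g.discriminated)
t, p, n = barcode_gap_test(gaps)
print(f"{disc}/{n} species discriminated, gap t-test p = {p:.3g}")
rec = species_recovery(nj_tree(dm), species, "nj")
print(f"NJ recovery {rec.pct_recovered}%")
```

prints

```
mean inter 0.0084  mean intra 0.0034
0/16 species discriminated, gap t-test p = 4.91e-08
NJ recovery 50.0%
```

Interspecific divergence (0.0084 substitutions/site) overlaps the
intraspecific range (0.0034), so no species passes the strict
discrimination criterion — the paired t-test is in fact significantly
*negative* (per-species minimum interspecific distances fall below the
maximum intraspecific ones) — and only half the species come out
monophyletic. This is the signature of a barcode locus failing in a
recently diverged or hybridizing group; raising the interspecific depth
(e.g. `LocusConfig("L", 1000, inter_depth=0.05, intra_depth=0.001)`)
produces a clean gap and 100 % recovery instead.

The same analyses are available from the shell:

```sh
barcodegap simulate --seed 1 --out data/
barcodegap report --config run.yaml      # full barcode + AFLP report bundle
barcodegap recover --fasta data/ITS.fasta --species-map data/species_map.csv \
    --method nj --out recovery.csv
```

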