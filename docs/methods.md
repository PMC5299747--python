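# Methods

This note documents the models, estimators and numerical choices behind
`caniglobin`, what the synthetic-data generators do and do not emulate, and
the problem sizes used by the reference studies.

## Synthetic genotype panels

Breed structure follows the Balding–Nichols model. Each marker draws a
baseline (ancestral) B-allele frequency `p ~ Beta(a, b)`, clipped to
[0.05, 0.95]; each breed then draws its own frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, where `F = drift_fst` is the single
differentiation knob: the expected Hudson F_ST between any two breeds
equals `F` under this model, which is what makes parameter-recovery tests
possible (the ratio-of-sums estimator at 10,000 SNPs recovers `F = 0.1`
within ±0.02). Genotypes are two independent Bernoulli(p_breed) chromosome
copies per dog — Hardy–Weinberg within breed by construction — and the
phased copies are kept on the panel object so sweep injection at partial
fixation is exact rather than approximated from dosages.

Defaults: 10 breeds × 25 dogs, 5,000 markers on one chromosome with
exponential inter-marker spacing of mean 5 kb (~25 Mb, i.e. ~126
non-overlapping 200-kb windows), `drift_fst = 0.1`,
`baseline_af_dist = (2, 2)`, i.e. Beta(2,2). The Beta(2,2) baseline weights
intermediate frequencies, emulating the ascertainment of genotyping arrays
toward common variants. It also matters for truth identifiability in sweep
studies: with a flat Beta(1,1) baseline, roughly one marker in five is
already ≥95% major-allele within a 25-dog breed by drift alone, so the
*true* maximal near-fixed run frequently extends past a planted tract and
"boundary recovery" is ill-posed; under Beta(2,2) that probability drops
to ~8% per marker and the planted tract is the maximal run in almost all
realisations. No recombination map or linkage decay is modelled — markers
are independent given breed frequencies, and the only haplotype structure
is the injected tract. Panels therefore lack the background LD of real
array data; passing sweep-recovery tests shows the statistics respond to
breed-specific fixation, not that they are calibrated against realistic
LD.

A sweep (`SweepSpec`) replaces a fraction `fixation` of the target breed's
chromosome copies (chosen uniformly at random) with a fixed 0/1 haplotype
over a contiguous marker tract, then collapses back to dosages; genotypes
outside the tract or in other breeds are never touched, and missing
genotypes stay missing.

## Differentiation scan

Per-SNP F_ST uses the Bhatia–Hudson estimator with observed allele counts
(missing genotypes drop a dog's two alleles from that SNP's denominator);
markers where both breeds are monomorphic for the same allele are
undefined and excluded. Windows combine markers as a ratio of sums, the
form that is consistent for unequal sample sizes; windows with no usable
SNP are dropped. Negative window values are retained — clamping at zero
would bias the genome-wide moments and hence the z-scores.

`d_i(w)` sums, over all other breeds *j*, the z-score of window *w* in the
(i, j) series, standardised by that pair's genome-wide mean and population
standard deviation over retained windows. Pairs with zero genome-wide sd
(e.g. saturated panels) are excluded with a warning. Empirical p-values
use the add-one rank form `p(w) = (1 + #{w′: d(w′) ≥ d(w)}) / (1 + N)`
(the count includes *w* itself, so a unique maximum gets `2/(N+1)` and no
p is ever 0), and q-values are Benjamini–Hochberg within breed. With
fewer than ~100 windows the p resolution is coarse and a warning is
issued. The default window is 200 kb, non-overlapping; the scan signal of
interest spans single windows at that scale.

## Direct phasing

The 0.95 threshold is interpreted as the major-allele frequency among the
anchor-homozygous class's observed chromosomes (two per genotyped dog) at
each flanking marker — near-fixation within the class, computed over
chromosomes rather than dogs (identical when all dogs are genotyped).
Extension is strictly contiguous and halts at the first failing marker per
direction; a `skip_tolerance` flag allows stepping over isolated failures
for sensitivity analyses but defaults to off. A marker where the class has
no observed alleles halts extension (near-fixation cannot be certified).
Chromosome ends halt silently. Block size is reported in bp between the
outermost passing markers, matching how haplotype spans are quoted in kb.
`min_hom = 4` applies per allele class per breed; both classes are
extended when eligible and the larger block represents the breed, since
the swept class is not known in advance. The cross-breed summary reports
the top breed, the runner-up span, and the median span over all eligible
breeds except the top one.

## TN93 distances, neighbor joining, bootstrap

The Tamura–Nei (1993) distance is evaluated from the observed A↔G, C↔T
and transversion mismatch proportions with empirical base frequencies
pooled over the pair. Degenerate compositions drop the corresponding
(necessarily count-free) term; any non-positive logarithm argument means
saturation and the distance is undefined (NaN), with the offending pair
named when a full matrix is required. The sequence simulator uses the
same TN93 parameterisation (normalised rate matrix, branch lengths in
expected substitutions/site), so closed-form divergence expectations exist
for testing the round trip.

Neighbor joining is the Saitou–Nei algorithm with two determinism rules:
Q-criterion ties join the lowest-index pair, and negative branch lengths
are clamped to zero with the deficit moved to the sibling edge (the path
length through the join is preserved). On additive matrices the generating
topology and branch lengths are recovered exactly (tested on randomized
4–8-taxon trees). Bipartitions are normalised to the side away from the
lexicographically smallest taxon; zero-length internal edges are treated
as collapsed, so an alignment of identical sequences yields a star tree
with no supported splits. Bootstrap support resamples alignment columns
with replacement (default B = 500, seeded), rebuilds the NJ tree, and
reports the percentage of replicates containing each original split;
replicates whose distances saturate are dropped from the denominator. The
conventional display floor for support values is 60.

## Chimera classification

Within each annotated segment (complete gap deletion, never pairwise), the
query is assigned the clade of its minimum-distance exemplar. The margin
is `(second-best clade's minimum − best) / best`; margins below the
threshold (default 0.05) give `ambiguous`, as do segments with no columns
left after gap deletion or with all distances saturated. The margin is
reported rather than adjudicated further because paralog segments can be
monophyletic within species, which genuinely obscures donor identity; the
tool's contract is nearest-clade assignment with an honest ambiguity
band. Shared identical tracts are maximal column runs equal across the
listed sequences (gaps compare as characters), with helper overhang
computation against a segment (e.g. intron bases abutting a converted
exon). Multiple alignment itself is out of scope — the module consumes
pre-aligned FASTA.

The reference gene-family study uses two three-taxon clades (dog/cat/
ferret HBB and HBD) plus an outgroup: within-clade terminal branches of
0.03 substitutions/site and clade stems of 0.05, giving ≥ 5% between-clade
divergence over seven gene-structure segments totalling 1,550 sites, with
a single 390-site conversion of the promoter + exon 1 region — large
enough that nearest-clade classification should be essentially error-free,
which is what the study measures.

## Promoter analysis

Scanning is forward-strand only (promoters are supplied on the coding
strand), exact IUPAC matching with no PWM scoring; an N in the query
matches only a fully degenerate consensus position. The catalog ships as
an editable table because published figures annotate motifs graphically:
defaults are CACCC (EKLF box), CCAAT, the β-globin-family CATAAA TATA
element, and a `bDRE` entry whose consensus is an explicit placeholder —
the element's exact sequence must come from the user's reference
annotation, and conclusions about sites near it depend on that input.
Anchored scanning maps exemplar motif occurrences through a supplied
pairwise alignment and reports the query's resident substring as
non-consensus with a mismatch count when it departs from the consensus.
Promoter calls use percent identity over the query's non-gap columns with
a 2-percentage-point margin; the per-column nearest-exemplar track, with
a split-point maximiser, localises conversion breakpoints to within ~10
columns at 10% noise. Conserved-but-divergent sites require the modal
base of the non-query sequences at frequency ≥ `conservation_min`
(default 1.0, strict conservation) and a differing non-gap query base.

## Residue profiling

Curation applies duplicates → incomplete (gap/ambiguity fraction above
threshold) → private-indel outliers (longest run where a sequence
disagrees with the column-majority gap state, above `max_indel_len`) →
named near-species pair collapse, in that order, deterministically, with
every removal logged; the composition is idempotent. Profiles count gaps
and non-standard letters in a 21st category excluded from modal
determination (logos display residue frequencies); modal ties resolve
alphabetically and are flagged. Rare-substitution flags report dual
coordinates — 1-based alignment column and 1-based ungapped residue number
in the query — because published position numbering may or may not count
the initiator methionine; the census likewise reports the initiator column
separately. Partitioning a mixed set into adult-like and embryonic-like
clades, when needed, reuses the NJ + bootstrap machinery on protein
p-distances.

The ortholog-set generator draws a uniform consensus residue per column
and substitutes each cell with a small probability (default 0.05);
sequences receiving a planted residue are kept noise-free elsewhere, and
the generator enforces that no unplanted sequence carries a planted
residue at its column (and rejects plants equal to the column consensus),
so the planted rarity count is exact by construction. This emulates
rarity against a conserved background, not real phylogenetic correlation
between sequences.

## Reference study sizes

The studies in `caniglobin.studies` (run by the test suite and
`scripts/acceptance.py`) use: 20 panels of 10 breeds × 25 dogs × 5,000
markers with a fully fixed one-window (200 kb) sweep for phasing/scan
recovery; 3 no-sweep panels (~3,800 window p-values) for null calibration;
one 2-breed × 50-dog × 10,000-SNP panel for drift recovery; 20 gene
families as above for chimera recovery; 100 random alignments for the
tract-scanner oracle; 50 planted-CACCC sequences for the motif-scan
oracle; and 10 43-sequence protein sets for rare-flag recovery. The whole
battery completes in well under a minute on one CPU, and all randomness
derives from a single seed.

## Known limitations

- No linkage disequilibrium, recombination or coalescent ancestry in the
  panel generator; no haplotype-based selection statistics (iHS, XP-EHH).
- No statistical phasing of heterozygotes or imputation — direct phasing
  only.
- No maximum-likelihood or parsimony tree search; topology comparison
  rests on NJ over TN93 distances.
- No permutation-based gene-conversion test (GENECONV-style); chimera
  calls are nearest-clade assignments with margins.
- PED round-trips code markers where only one allele was observed as
  A-monomorphic (allele identity is unrecoverable from such a file).
- The βDRE catalog entry is a placeholder pending a user-supplied
  consensus.
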