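# caniglobin

Population-genetic and molecular-evolution analyses of the canine
β-globin locus, packaged as a tested, reusable pipeline.

Dog breeds are closed populations, so strong recent selection leaves two
conspicuous signatures in SNP genotype panels: a window where one breed is
unusually differentiated from all the others, and a long haplotype fixed
within that breed. At the sequence level, the adult β-globin paralogs
*HBB* and *HBD* have repeatedly exchanged tracts by gene conversion,
producing chimeric genes whose promoter and 3′ end have different
ancestries — in carnivores this rewired which paralog carries the
EKLF-bound CACC box and is the dominant adult subunit. `caniglobin`
implements the statistics behind each of these observations, together with
synthetic-data generators so every analysis can be exercised against known
truth.

## What it computes

**Breed-differentiation scan (`caniglobin.fst`).** Per-SNP Hudson F_ST
between breeds *i*, *j* with the Bhatia sampling correction,

    N = (p_i − p_j)² − p_i(1−p_i)/(n_i−1) − p_j(1−p_j)/(n_j−1)
    D = p_i(1−p_j) + p_j(1−p_i),

combined over fixed-width windows as ΣN/ΣD, and the per-breed scan
statistic

    d_i(w) = Σ_{j≠i} [F_ST^{ij}(w) − E(F_ST^{ij})] / sd(F_ST^{ij}),

with add-one empirical p-values and Benjamini–Hochberg FDR per breed.

**Direct haplotype phasing (`caniglobin.phasing`).** Starting from the SNP
nearest a locus of interest, dogs homozygous at that anchor are split by
allele class (heterozygotes are excluded — their phase is ambiguous), and
each class's block is grown marker-by-marker while the within-class
major-allele frequency stays ≥ 0.95, halting at the first failing marker.
Breeds need ≥ 4 homozygous dogs per class to count. Block spans in bp are
ranked across breeds.

**Chimera detection (`caniglobin.chimera`).** An aligned gene family is cut
into gene-structure segments (5′UTR, exons, introns, 3′UTR), each segment's
columns with any gap are deleted completely, and the query is assigned per
segment to the reference clade (HBB-like / HBD-like) of its nearest
exemplar under the Tamura–Nei 1993 distance, with a relative-margin
ambiguity call and optional neighbor-joining bootstrap support (default
500 replicates). Exact shared tracts (e.g. an identical exon 2 plus a few
abutting intron bases) are located by a maximal identical-run scan.

**Promoter analysis (`caniglobin.promoter`).** IUPAC consensus scanning of
proximal promoters against an editable catalog (CACC/EKLF box, CCAAT box,
TATA box, βDRE), reporting broken elements at alignment-anchored expected
positions as non-consensus; HBB-like vs HBD-like promoter classification
by percent identity with a per-column track that localises conversion
breakpoints; and detection of columns conserved across orthologs but
divergent in the query.

**Residue profiling (`caniglobin.proteins`).** Curation of ortholog protein
sets (duplicates, incomplete entries, private-indel outliers, near-species
collapse), per-column amino-acid frequency profiles (sequence-logo data),
modal-residue census, and flagging of lineage-rare residues — columns where
a query's residue is carried by at most *k* sequences in the whole set.

**Synthetic data (`caniglobin.simulate`, `caniglobin.seqsim`).**
Balding–Nichols breed-structured panels with a single F_ST drift knob and
phased haplotypes, sweep injection at configurable fixation, TN93
sequence evolution along a guide tree with literal gene-conversion copy
events, and ortholog protein sets with planted rare residues.

## Worked example

```python
import caniglobin as cg
from caniglobin.phasing import PhasingParams, breed_summary

# simulate the standard panel (10 breeds x 25 dogs x 5,000 markers)
# and plant a fully fixed 41-marker sweep in one breed
panel, truth = cg.simulate_panel(cg.PanelConfig(seed=1))
spec = cg.SweepSpec("breed00", first_marker=2480, last_marker=2520,
                    haplotype=(1,) * 41)
swept = cg.inject_sweep(panel, spec, seed=1)

# breed-differentiation scan
result = cg.empirical_p_and_fdr(cg.di_scan(swept, window_bp=200_000))
top = result.top_window("breed00")
print(f"top window for breed00: {top.chrom}:{top.start}-{top.end}  "
      f"d_i={top.di:.1f}  p={top.p:.4f}  q={top.q:.3f}  rank={top['rank']}")

# direct phasing anchored at the tract midpoint
anchor_bp = int(swept.markers.at[2500, "pos"])
summary = breed_summary(swept, "chr1", anchor_bp, PhasingParams())
print(f"largest block: {summary.top_breed} "
      f"({summary.table.at[0,'span_bp']:,} bp), "
      f"runner-up {summary.runner_up_bp:,} bp, "
      f"median of others {summary.median_other_bp:,.0f} bp")
```

prints

```
top window for breed00: chr1:12200000-12400000  d_i=81.0  p=0.0160  q=1.000  rank=1
largest block: breed00 (200,007 bp), runner-up 3,139 bp, median of others 0 bp
```

The swept breed's d_i peaks genome-wide exactly at the window holding the
planted tract (rank 1; p is the add-one empirical minimum for a 126-window
scan), and direct phasing recovers the tract span to the marker (the true
planted span is 200,007 bp), while every other breed's block at the same
anchor stays three orders of magnitude smaller — the qualitative picture
of a single breed carrying a large fixed haplotype over the β-globin
cluster.

The same analyses are available as shell commands: `caniglobin simulate
panel|genes|proteins`, `caniglobin di-scan`, `caniglobin phase`,
`caniglobin chimera`, `caniglobin promoter`, `caniglobin profile` (see
`--help` on each).

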