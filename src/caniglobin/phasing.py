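"""Direct haplotype phasing around an anchor SNP.

Direct phasing avoids statistical phasing entirely: only dogs homozygous at
the anchor marker are used, because their haplotypes at the anchor are
unambiguous. Within each anchor-homozygous class the block is grown marker
by marker in both directions, keeping a marker while the class's
major-allele frequency there is at least ``af_min`` (default 0.95, i.e. the
class is effectively still on one shared haplotype), and halting at the
first failing marker. Breeds contribute only when an allele class holds at
least ``min_hom`` dogs (default 4).

A fixed, very large block in a single breed — orders of magnitude above the
other breeds' spans — is the hallmark of a selective sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class PhasingParams:
    """Thresholds of the direct-phasing walk.

    ``af_min``: within-class major-allele frequency a marker must reach to
    stay in the block. ``min_hom``: minimum anchor-homozygous dogs for an
    allele class to be eligible. ``skip_tolerance`` optionally lets the walk
    step over that many consecutive failing markers (sensitivity analyses
    only; default 0 = strict halt).
    """

    af_min: float = 0.95
    min_hom: int = 4
    skip_tolerance: int = 0

    def __post_init__(self):
        if not 0.5 < self.af_min <= 1.0:
            raise ValueError("af_min must lie in (0.5, 1]")
        if self.min_hom < 1:
            raise ValueError("min_hom must be >= 1")
        if self.skip_tolerance < 0:
            raise ValueError("skip_tolerance must be >= 0")


@dataclass
class PhasedBlock:
    """A contiguous near-fixed haplotype around an anchor in one allele class."""

    breed: str
    anchor: int  # marker index
    allele_class: str  # "A" or "B" (anchor-homozygous genotype)
    left_idx: int
    right_idx: int
    span_bp: int
    consensus: str  # major allele per marker, "A"/"B" string
    n_hom: int

    @property
    def n_markers(self) -> int:
        return self.right_idx - self.left_idx + 1


def select_anchor(panel: GenotypePanel, chrom: str, bp: int) -> int:
    """Index of the marker closest to chrom:bp; ties go to the lower position."""
    on_chrom = np.flatnonzero((panel.markers["chrom"] == chrom).to_numpy())
    if on_chrom.size == 0:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    pos = panel.markers["pos"].to_numpy()[on_chrom]
    dist = np.abs(pos - bp)
    # stable argmin prefers the earlier (lower-position) marker on ties
    return int(on_chrom[int(np.argmin(dist))])


def split_homozygotes(
    panel: GenotypePanel,
    anchor: int,
    breed: str,
    params: PhasingParams = PhasingParams(),
) -> dict[str, np.ndarray]:
    """Split a breed's dogs by anchor genotype into homozygous classes.

    Returns {"A": indices with dosage 0, "B": indices with dosage 2};
    heterozygous and missing dogs are excluded. Eligibility (>= min_hom) is
    checked by the caller via the class sizes.
    """
    cols = panel.sample_indices(breed)
    dosage = panel.genotypes[anchor, cols]
    return {
        "A": cols[dosage == 0],
        "B": cols[dosage == 2],
    }


def _marker_passes(
    genotypes: np.ndarray, marker: int, dogs: np.ndarray, af_min: float
) -> bool:
    g = genotypes[marker, dogs]
    g = g[g != MISSING]
    if g.size == 0:
        return False  # no observed alleles: cannot certify near-fixation
    n_b = int(g.sum())
    n = 2 * g.size
    return max(n_b, n - n_b) / n >= af_min - 1e-12


def _major_allele(genotypes: np.ndarray, marker: int, dogs: np.ndarray) -> str:
    g = genotypes[marker, dogs]
    g = g[g != MISSING]
    if g.size == 0:
        return "N"
    return "B" if 2 * int(g.sum()) >= 2 * g.size else "A"


def extend_block(
    panel: GenotypePanel,
    anchor: int,
    dogs: np.ndarray,
    params: PhasingParams = PhasingParams(),
    *,
    breed: str = "",
    allele_class: str = "",
) -> PhasedBlock:
    """Grow the phased block outward from the anchor within one allele class.

    The class frequency at each flanking marker is computed over the class's
    observed alleles (two per genotyped dog). Extension in each direction
    halts at the first marker below ``af_min`` (optionally skipping up to
    ``skip_tolerance`` consecutive failures); chromosome ends halt silently.
    """
    dogs = np.asarray(dogs)
    if dogs.size < params.min_hom:
        raise ValueError(
            f"class has {dogs.size} dogs; needs min_hom={params.min_hom}"
        )
    chrom = panel.markers.at[anchor, "chrom"]
    chrom_idx = np.flatnonzero((panel.markers["chrom"] == chrom).to_numpy())
    lo, hi = int(chrom_idx[0]), int(chrom_idx[-1])
    assert _marker_passes(panel.genotypes, anchor, dogs, params.af_min), (
        "anchor must pass af_min within an anchor-homozygous class"
    )

    def walk(step: int) -> int:
        last_pass = anchor
        m = anchor + step
        skipped = 0
        while lo <= m <= hi:
            if _marker_passes(panel.genotypes, m, dogs, params.af_min):
                last_pass = m
                skipped = 0
            else:
                skipped += 1
                if skipped > params.skip_tolerance:
                    break
            m += step
        return last_pass

    left, right = walk(-1), walk(+1)
    pos = panel.markers["pos"]
    consensus = "".join(
        _major_allele(panel.genotypes, m, dogs) for m in range(left, right + 1)
    )
    return PhasedBlock(
        breed=breed,
        anchor=anchor,
        allele_class=allele_class,
        left_idx=left,
        right_idx=right,
        span_bp=int(pos[right] - pos[left]),
        consensus=consensus,
        n_hom=int(dogs.size),
    )


@dataclass
class BreedBlockSummary:
    """Largest phased block per breed around one locus, with cross-breed ranking.

    ``table`` columns: breed, allele_class, n_hom, left_idx, right_idx,
    span_bp, sorted by span descending. ``median_other_bp`` is the median
    span over eligible breeds other than the top one (None when fewer than
    two breeds are eligible).
    """

    table: pd.DataFrame
    top_breed: str | None
    runner_up_bp: int | None
    median_other_bp: float | None
    ineligible: list[str]


def breed_summary(
    panel: GenotypePanel,
    chrom: str,
    bp: int,
    params: PhasingParams = PhasingParams(),
) -> BreedBlockSummary:
    """Phase every breed at a locus and rank the largest block spans.

    For each breed both anchor-homozygous classes are extended (when
    eligible) and the larger block is reported, since the swept class is not
    known in advance.
    """
    anchor = select_anchor(panel, chrom, bp)
    rows, ineligible = [], []
    for breed in panel.breeds:
        classes = split_homozygotes(panel, anchor, breed, params)
        best = None
        for cls, dogs in classes.items():
            if dogs.size < params.min_hom:
                continue
            block = extend_block(
                panel, anchor, dogs, params, breed=breed, allele_class=cls
            )
            if best is None or block.span_bp > best.span_bp:
                best = block
        if best is None:
            ineligible.append(breed)
        else:
            rows.append(
                (
                    breed,
                    best.allele_class,
                    best.n_hom,
                    best.left_idx,
                    best.right_idx,
                    best.span_bp,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["breed", "allele_class", "n_hom", "left_idx", "right_idx", "span_bp"],
    ).sort_values("span_bp", ascending=False, kind="stable").reset_index(drop=True)
    if table.empty:
        return BreedBlockSummary(table, None, None, None, ineligible)
    top = table.at[0, "breed"]
    runner_up = int(table.at[1, "span_bp"]) if len(table) > 1 else None
    median_other = (
        float(table["span_bp"].iloc[1:].median()) if len(table) > 1 else None
    )
    return BreedBlockSummary(table, top, runner_up, median_other, ineligible)


def blocks_to_bed(blocks: list[PhasedBlock], panel: GenotypePanel, path) -> None:
    """Write blocks as BED: chrom, start, end, breed/class, score = n_hom."""
    pos = panel.markers["pos"]
    chrom = panel.markers["chrom"]
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{chrom[b.anchor]}\t{pos[b.left_idx]}\t{pos[b.right_idx] + 1}\t"
                f"{b.breed}/{b.allele_class}\t{b.n_hom}\n"
            )
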