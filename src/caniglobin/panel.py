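"""Breed-labelled diploid SNP genotype panels.

The central container is :class:`GenotypePanel`: a marker map (chromosome,
bp position, id, A/B alleles), a sample table with breed labels, and a
genotype matrix of B-allele dosage in {0, 1, 2} with -1 for missing.
Panels round-trip through PLINK-style PED/MAP pairs or a single TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypePanel:
    """Diploid SNP genotypes on a physical map, with breed labels.

    Parameters
    ----------
    markers
        DataFrame with columns ``chrom``, ``pos``, ``id``, ``allele_a``,
        ``allele_b``; positions strictly increasing within each chromosome.
    samples
        DataFrame with columns ``id``, ``breed``.
    genotypes
        ``(n_markers, n_samples)`` int8 array of B-allele dosage
        (0/1/2, -1 = missing).
    haplotypes
        Optional ``(n_markers, n_samples, 2)`` uint8 array of phased B-allele
        indicators; carried by simulated panels so that haplotype-level edits
        (sweep injection at partial fixation) are well defined.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype dosages must be 0, 1, 2 or -1 (missing)")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
        if self.samples["breed"].isna().any():
            raise ValueError("every sample needs a breed label")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
            expect = (len(self.markers), len(self.samples), 2)
            if self.haplotypes.shape != expect:
                raise ValueError(f"haplotypes shape must be {expect}")

    # -- accessors ----------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def breeds(self) -> list[str]:
        return list(dict.fromkeys(self.samples["breed"]))

    def sample_indices(self, breed: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["breed"] == breed).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown breed: {breed!r}")
        return idx

    def allele_stats(self, breed: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-marker (B-allele count, observed allele count) within a breed.

        Missing genotypes drop a dog's two alleles from the denominator.
        """
        g = self.genotypes[:, self.sample_indices(breed)]
        observed = g != MISSING
        b_count = np.where(observed, g, 0).sum(axis=1)
        n_alleles = 2 * observed.sum(axis=1)
        return b_count.astype(np.int64), n_alleles.astype(np.int64)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.markers.copy(),
            self.samples.copy(),
            self.genotypes.copy(),
            None if self.haplotypes is None else self.haplotypes.copy(),
        )

    # -- TSV dialect --------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Markers x samples TSV; sample columns are named ``breed/sample``."""
        geno = self.genotypes.astype(object)
        geno[self.genotypes == MISSING] = "NA"
        cols = [
            f"{breed}/{sid}"
            for sid, breed in zip(self.samples["id"], self.samples["breed"])
        ]
        df = pd.concat(
            [self.markers, pd.DataFrame(geno, columns=cols)], axis=1
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["chrom", "pos", "id", "allele_a", "allele_b"]
        sample_cols = [c for c in df.columns if c not in meta_cols]
        breeds, sids = zip(*(c.split("/", 1) for c in sample_cols))
        geno = df[list(sample_cols)].to_numpy(dtype=object)
        out = np.full(geno.shape, MISSING, dtype=np.int8)
        mask = ~pd.isna(geno) & (geno != "NA")
        out[mask] = geno[mask].astype(np.int8)
        return cls(
            df[meta_cols],
            pd.DataFrame({"id": sids, "breed": breeds}),
            out,
        )

    # -- PED/MAP dialect ----------------------------------------------------
    def to_ped_map(self, prefix) -> None:
        """Write PLINK text PED/MAP; family id carries the breed label."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, m in self.markers.iterrows():
                fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\n")
        a = self.markers["allele_a"].to_numpy()
        b = self.markers["allele_b"].to_numpy()
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for j, (sid, breed) in enumerate(
                zip(self.samples["id"], self.samples["breed"])
            ):
                g = self.genotypes[:, j]
                first = np.where(g >= 1, b, a)
                second = np.where(g == 2, b, a)
                first = np.where(g == MISSING, "0", first)
                second = np.where(g == MISSING, "0", second)
                alleles = "\t".join(f"{x}\t{y}" for x, y in zip(first, second))
                fh.write(f"{breed}\t{sid}\t0\t0\t0\t-9\t{alleles}\n")

    @classmethod
    def from_ped_map(cls, prefix) -> "GenotypePanel":
        prefix = Path(prefix)
        markers = pd.read_csv(
            prefix.with_suffix(".map"),
            sep="\t",
            names=["chrom", "id", "cm", "pos"],
            dtype={"chrom": str},
        )
        sids, breeds, rows = [], [], []
        with open(prefix.with_suffix(".ped")) as fh:
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                breeds.append(fields[0])
                sids.append(fields[1])
                alleles = fields[6:]
                if len(alleles) != 2 * len(markers):
                    raise ValueError("PED row length does not match MAP")
                rows.append((alleles[0::2], alleles[1::2]))
        n_markers, n_samples = len(markers), len(sids)
        # infer A/B alleles per marker from the observed letters
        first = np.array([r[0] for r in rows], dtype="U4").T  # markers x samples
        second = np.array([r[1] for r in rows], dtype="U4").T
        allele_a = np.full(n_markers, "A", dtype="U4")
        allele_b = np.full(n_markers, "B", dtype="U4")
        geno = np.full((n_markers, n_samples), MISSING, dtype=np.int8)
        for i in range(n_markers):
            seen = sorted(
                {x for x in np.concatenate([first[i], second[i]]) if x != "0"}
            )
            if len(seen) > 2:
                raise ValueError(f"marker {markers.at[i, 'id']} has >2 alleles")
            if seen:
                allele_a[i] = seen[0]
                allele_b[i] = seen[-1]
                obs = (first[i] != "0") & (second[i] != "0")
                dosage = (first[i] == allele_b[i]).astype(np.int8) + (
                    second[i] == allele_b[i]
                ).astype(np.int8)
                if len(seen) == 1:
                    dosage[:] = 0  # monomorphic: observed allele coded A
                geno[i, obs] = dosage[obs]
        mk = pd.DataFrame(
            {
                "chrom": markers["chrom"],
                "pos": markers["pos"],
                "id": markers["id"],
                "allele_a": allele_a,
                "allele_b": allele_b,
            }
        )
        return cls(mk, pd.DataFrame({"id": sids, "breed": breeds}), geno)


def read_panel(path, *, dialect: str | None = None) -> GenotypePanel:
    """Read a panel, auto-detecting TSV vs PED/MAP by extension."""
    path = Path(path)
    if dialect is None:
        dialect = "ped" if path.suffix in {".ped", ".map"} else "tsv"
    if dialect == "ped":
        return GenotypePanel.from_ped_map(path.with_suffix(""))
    if dialect == "tsv":
        return GenotypePanel.from_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")
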