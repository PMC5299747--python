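"""Windowed Hudson F_ST between breeds and the d_i differentiation scan.

The scan statistic is, for breed i and genomic window w,

    d_i(w) = sum over j != i of  [F_ST^ij(w) - E(F_ST^ij)] / sd(F_ST^ij),

i.e. the sum over all other breeds of the genome-standardised window F_ST.
Large d_i marks windows where breed i is unusually differentiated from many
other breeds at once — the signature of breed-specific selection.

Per-SNP F_ST uses the Bhatia–Hudson estimator,

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)

with n the observed allele counts, combined over a window as a ratio of sums
(sum N / sum D). Windows are non-overlapping, fixed-width in bp. Empirical
p-values use the add-one rank form and are FDR-corrected per breed with
Benjamini–Hochberg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .panel import MISSING, GenotypePanel

DEFAULT_WINDOW_BP = 200_000


def hudson_fst(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Bhatia–Hudson per-SNP F_ST components (numerator N, denominator D).

    ``p`` are B-allele frequencies, ``n`` observed allele counts (>= 2).
    Markers with D == 0 (both populations monomorphic for the same allele)
    are undefined: both components are returned as NaN. Windowed estimates
    should combine markers as ratio of sums, never as a mean of ratios.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((n1 < 2) | (n2 < 2)):
        raise ValueError("need at least 2 observed alleles per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    undefined = den == 0
    num = np.where(undefined, np.nan, num)
    den = np.where(undefined, np.nan, den)
    return num, den


@dataclass
class PairFstSeries:
    """Per-window F_ST between one pair of breeds, with genome-wide moments."""

    breed_i: str
    breed_j: str
    windows: pd.DataFrame  # chrom, start, end
    fst_w: np.ndarray
    genome_mean: float
    genome_sd: float

    def zscores(self) -> np.ndarray:
        if self.genome_sd == 0:
            raise ZeroDivisionError(
                f"pair ({self.breed_i}, {self.breed_j}) has zero genome-wide sd"
            )
        return (self.fst_w - self.genome_mean) / self.genome_sd


def _window_assignment(positions: np.ndarray, window_bp: int) -> np.ndarray:
    return positions // window_bp


def _pair_components(
    panel: GenotypePanel, breed_i: str, breed_j: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (N, D, usable) for one breed pair."""
    usable = np.ones(panel.n_markers, dtype=bool)
    stats = []
    for breed in (breed_i, breed_j):
        b, n = panel.allele_stats(breed)
        ok = n >= 2
        if not ok.any():
            raise ValueError(f"breed {breed!r} has <2 genotyped samples everywhere")
        usable &= ok
        stats.append((b, n))
    (b1, n1), (b2, n2) = stats
    num = np.full(panel.n_markers, np.nan)
    den = np.full(panel.n_markers, np.nan)
    with np.errstate(invalid="ignore"):
        p1 = np.where(usable, b1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(usable, b2 / np.maximum(n2, 1), np.nan)
    idx = np.flatnonzero(usable)
    num[idx], den[idx] = hudson_fst(p1[idx], n1[idx], p2[idx], n2[idx])
    usable &= ~np.isnan(den)
    return num, den, usable


def window_fst(
    panel: GenotypePanel,
    breed_i: str,
    breed_j: str,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> PairFstSeries:
    """Windowed ratio-of-sums Hudson F_ST between two breeds.

    Windows with no usable SNP are dropped; genome mean and sd (population
    form) are taken over the retained windows. Negative window values are
    retained so downstream z-scores stay unbiased.
    """
    num, den, usable = _pair_components(panel, breed_i, breed_j)
    chroms = panel.markers["chrom"].to_numpy()
    pos = panel.markers["pos"].to_numpy()
    win = _window_assignment(pos, window_bp)

    df = pd.DataFrame(
        {"chrom": chroms, "win": win, "num": num, "den": den, "usable": usable}
    )
    df = df[df["usable"]]
    grouped = df.groupby(["chrom", "win"], sort=True)[["num", "den"]].sum()
    fst_w = (grouped["num"] / grouped["den"]).to_numpy()
    windows = pd.DataFrame(
        {
            "chrom": [c for c, _ in grouped.index],
            "start": [int(w * window_bp) for _, w in grouped.index],
            "end": [int((w + 1) * window_bp) for _, w in grouped.index],
        }
    )
    return PairFstSeries(
        breed_i,
        breed_j,
        windows,
        fst_w,
        float(np.mean(fst_w)),
        float(np.std(fst_w)),  # population sd
    )


@dataclass
class DiResult:
    """Per-breed, per-window differentiation scores with p, q and rank.

    ``table`` columns: breed, chrom, start, end, di, n_pairs, p, q, rank
    (p/q/rank filled by :func:`empirical_p_and_fdr`).
    """

    table: pd.DataFrame
    window_bp: int
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def breed_table(self, breed: str) -> pd.DataFrame:
        t = self.table[self.table["breed"] == breed]
        if t.empty:
            raise KeyError(f"unknown breed {breed!r}")
        return t.reset_index(drop=True)

    def top_window(self, breed: str) -> pd.Series:
        t = self.breed_table(breed)
        return t.loc[t["di"].idxmax()]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def di_scan(
    panel: GenotypePanel,
    window_bp: int = DEFAULT_WINDOW_BP,
    *,
    breeds: list[str] | None = None,
) -> DiResult:
    """Compute d_i for every breed and window of the panel.

    Requires >= 3 breeds. Pairs whose genome-wide window-F_ST sd is zero are
    excluded from every sum with a warning; an error is raised if a breed
    loses all its pairs.
    """
    breeds = list(breeds or panel.breeds)
    if len(breeds) < 3:
        raise ValueError("d_i needs at least 3 breeds")

    pair_z: dict[tuple[str, str], pd.Series] = {}
    excluded: list[tuple[str, str]] = []
    for bi, bj in itertools.combinations(breeds, 2):
        series = window_fst(panel, bi, bj, window_bp)
        if series.genome_sd == 0:
            warnings.warn(
                f"pair ({bi}, {bj}) has zero genome-wide sd; excluded from d_i"
            )
            excluded.append((bi, bj))
            continue
        idx = pd.MultiIndex.from_frame(series.windows)
        pair_z[(bi, bj)] = pd.Series(series.zscores(), index=idx)

    rows = []
    for breed in breeds:
        zs = [
            z
            for (bi, bj), z in pair_z.items()
            if breed in (bi, bj)
        ]
        if not zs:
            raise ValueError(f"all pairs excluded for breed {breed!r}")
        zmat = pd.concat(zs, axis=1)
        di = zmat.sum(axis=1, skipna=True)
        n_pairs = zmat.notna().sum(axis=1)
        for (chrom, start, end), d, np_ in zip(di.index, di.to_numpy(), n_pairs):
            rows.append((breed, chrom, int(start), int(end), float(d), int(np_)))
    table = pd.DataFrame(
        rows, columns=["breed", "chrom", "start", "end", "di", "n_pairs"]
    )
    table["p"] = np.nan
    table["q"] = np.nan
    table["rank"] = -1
    return DiResult(table, window_bp, excluded)


def empirical_p_and_fdr(result: DiResult) -> DiResult:
    """Fill empirical p, BH q and rank per breed, in place, and return it.

    p(w) = (1 + #{w': d(w') >= d(w)}) / (1 + N) over that breed's windows
    (the count includes w itself, so a unique maximum gets p = 2/(N+1) and a
    constant scan gets p = 1 everywhere).
    """
    t = result.table
    for breed, idx in t.groupby("breed").groups.items():
        d = t.loc[idx, "di"].to_numpy()
        n = d.size
        if n < 100:
            warnings.warn(
                f"breed {breed!r}: only {n} windows; empirical p resolution is coarse"
            )
        order = np.sort(d)
        count_ge = n - np.searchsorted(order, d, side="left")
        p = (1.0 + count_ge) / (1.0 + n)
        q = multipletests(p, method="fdr_bh")[1]
        # rank 1 = largest d_i; ties share order of appearance
        rank = np.empty(n, dtype=int)
        rank[np.argsort(-d, kind="stable")] = np.arange(1, n + 1)
        t.loc[idx, "p"] = p
        t.loc[idx, "q"] = q
        t.loc[idx, "rank"] = rank
    return result
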