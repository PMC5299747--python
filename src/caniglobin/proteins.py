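"""Ortholog protein curation, per-column residue-frequency profiles and
rare-substitution flagging.

A residue profile is the tabular form of a sequence logo: per alignment
column, counts and frequencies of the 20 amino acids (gaps in a 21st
category, excluded from modal determination). Rare-substitution flagging
asks, for one query sequence, at which columns its residue is carried by at
most ``max_count`` members of the whole set — the criterion behind calls
like "the only one of 43 with I at position 13".

Positions are reported dually — 1-based alignment column and 1-based
ungapped residue number in the query — because published residue numbering
may or may not count the initiator methionine.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import GAP_CHARS, Alignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class CurationRules:
    """Deterministic filters applied in fixed order:
    duplicates -> incomplete -> indel outliers -> pair collapse."""

    drop_duplicates: bool = True
    drop_incomplete: bool = True
    max_missing_frac: float = 0.05  # gap+ambiguity fraction tolerated
    drop_indel_outliers: bool = True
    max_indel_len: int = 5  # longest private indel tolerated, in columns
    keep_one_of: tuple[tuple[str, str], ...] = ()  # (kept, dropped) name pairs

    def __post_init__(self):
        if self.max_missing_frac < 0 or self.max_indel_len < 0:
            raise ValueError("thresholds must be non-negative")


def _private_indel_runs(aln: Alignment, name: str) -> int:
    """Length of the longest run where `name` disagrees with the column
    majority about gap vs residue (a private insertion or deletion)."""
    gap_mask = np.array(
        [[c in GAP_CHARS for c in s] for s in aln.seqs], dtype=bool
    )
    i = aln.names.index(name)
    majority_gap = gap_mask.sum(axis=0) > len(aln) / 2
    discord = gap_mask[i] != majority_gap
    best = run = 0
    for d in discord:
        run = run + 1 if d else 0
        best = max(best, run)
    return best


def curate_proteins(
    aln: Alignment, rules: CurationRules = CurationRules()
) -> tuple[Alignment, list[tuple[str, str]]]:
    """Apply curation rules; returns the kept alignment and a removal log
    of (name, reason). Idempotent: a second pass removes nothing.
    """
    removed: list[tuple[str, str]] = []
    names = list(aln.names)

    if rules.drop_duplicates:
        seen: dict[str, str] = {}
        keep = []
        for n in names:
            s = aln[n]
            if s in seen:
                removed.append((n, f"duplicate of {seen[s]}"))
            else:
                seen[s] = n
                keep.append(n)
        names = keep

    if rules.drop_incomplete:
        keep = []
        for n in names:
            s = aln[n]
            missing = sum(1 for c in s if c in GAP_CHARS or c not in AMINO_ACIDS)
            if missing / len(s) > rules.max_missing_frac:
                removed.append((n, f"incomplete ({missing}/{len(s)} missing/ambiguous)"))
            else:
                keep.append(n)
        names = keep

    if rules.drop_indel_outliers and names:
        current = aln.subset(names)
        keep = []
        for n in names:
            run = _private_indel_runs(current, n)
            if run > rules.max_indel_len:
                removed.append((n, f"indel outlier (private indel of {run} columns)"))
            else:
                keep.append(n)
        names = keep

    for kept, dropped in rules.keep_one_of:
        if kept in names and dropped in names:
            names.remove(dropped)
            removed.append((dropped, f"collapsed near-identical pair with {kept}"))

    if not names:
        raise ValueError("curation removed every sequence")
    return aln.subset(names), removed


@dataclass
class ResidueProfile:
    """Per-column amino-acid counts/frequencies with modal residues.

    ``counts`` is a (length x 21) DataFrame (20 residues + gap); per-column
    frequencies sum to 1 including the gap mass. Modal residues ignore the
    gap category; ties resolve alphabetically and are flagged.
    """

    counts: pd.DataFrame
    n_sequences: int
    modal: list[str] = field(default_factory=list)
    modal_freq: list[float] = field(default_factory=list)
    modal_tie: list[bool] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.counts)

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n_sequences

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "column", np.arange(1, self.length + 1))  # 1-based report
        df["modal"] = self.modal
        df["modal_freq"] = self.modal_freq
        df.to_csv(path, sep="\t", index=False)


def frequency_profile(aln: Alignment) -> ResidueProfile:
    """Exact per-column residue counts of an aligned protein set.

    Characters outside the 20-residue alphabet (gaps, X, ...) are pooled
    into the gap category, documented as the 21st column.
    """
    cats = list(AMINO_ACIDS) + [GAP]
    counts = np.zeros((aln.length, 21), dtype=int)
    aa_index = {c: i for i, c in enumerate(AMINO_ACIDS)}
    for _, seq in aln:
        for col, c in enumerate(seq):
            counts[col, aa_index.get(c, 20)] += 1
    df = pd.DataFrame(counts, columns=cats)
    modal, modal_freq, modal_tie = [], [], []
    for col in range(aln.length):
        res_counts = counts[col, :20]
        top = res_counts.max()
        if top == 0:
            modal.append(GAP)
            modal_freq.append(0.0)
            modal_tie.append(False)
            continue
        winners = [AMINO_ACIDS[i] for i in np.flatnonzero(res_counts == top)]
        modal.append(sorted(winners)[0])
        modal_freq.append(top / len(aln))
        modal_tie.append(len(winners) > 1)
    return ResidueProfile(df, len(aln), modal, modal_freq, modal_tie)


def modal_census(
    profile: ResidueProfile, *, initiator_col: int | None = 0
) -> tuple[dict[str, int], str | None]:
    """Count alignment columns per modal residue.

    ``initiator_col`` (0-based; default the first column) is reported
    separately as the initiation-codon residue and excluded from the census;
    pass None to census every column. All-gap columns are skipped.
    """
    census: Counter[str] = Counter()
    initiator = None
    for col, res in enumerate(profile.modal):
        if initiator_col is not None and col == initiator_col:
            initiator = res
            continue
        if res != GAP:
            census[res] += 1
    return dict(census), initiator


@dataclass(frozen=True)
class RareFlag:
    """A column where the query's residue is rare across the whole set."""

    column: int  # 1-based alignment column
    residue_number: int  # 1-based position in the ungapped query
    query_residue: str
    count: int  # sequences (incl. query) carrying this residue here
    n_total: int
    other_residues: tuple[tuple[str, int], ...]  # sorted by count desc


def flag_rare_substitutions(
    aln: Alignment,
    query: str,
    *,
    max_count: int = 2,
    profile: ResidueProfile | None = None,
) -> list[RareFlag]:
    """Columns where the query's residue occurs at most ``max_count`` times
    in the whole set. Gap positions of the query are never flagged.
    """
    if query not in aln:
        raise KeyError(f"query {query!r} not in alignment")
    if profile is None:
        profile = frequency_profile(aln)
    if profile.n_sequences != len(aln) or profile.length != aln.length:
        raise ValueError("profile does not match the alignment")
    qseq = aln[query]
    flags = []
    res_num = 0
    for col, q in enumerate(qseq):
        if q in GAP_CHARS:
            continue
        res_num += 1
        if q not in AMINO_ACIDS:
            continue
        count = int(profile.counts.at[col, q])
        if count <= max_count:
            others = [
                (res, int(profile.counts.at[col, res]))
                for res in AMINO_ACIDS
                if res != q and profile.counts.at[col, res] > 0
            ]
            others.sort(key=lambda rc: (-rc[1], rc[0]))
            flags.append(
                RareFlag(
                    column=col + 1,
                    residue_number=res_num,
                    query_residue=q,
                    count=count,
                    n_total=len(aln),
                    other_residues=tuple(others),
                )
            )
    return flags


def flags_to_frame(flags: list[RareFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                f.column,
                f.residue_number,
                f.query_residue,
                f.count,
                f.n_total,
                ";".join(f"{r}:{c}" for r, c in f.other_residues),
            )
            for f in flags
        ],
        columns=["column", "residue_number", "residue", "count", "n_total", "others"],
    )
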