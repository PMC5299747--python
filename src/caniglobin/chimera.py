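"""Segment-wise detection of gene-conversion chimerism among paralogs.

A gene that arose chimerically carries tracts copied from another paralog,
so its ancestry differs between gene-structure segments: trees built from
the promoter may group it with one paralog clade while trees from the 3'
end group it with the other. This module segments an alignment into
annotated gene-structure elements (complete gap deletion within each
segment), classifies each query segment by its nearest reference clade
under the TN93 distance, optionally attaches NJ bootstrap support, and
finds exact tracts shared identically across sequences (the footprint of a
recent conversion, e.g. an identical exon plus a few abutting intron bases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import tn93_distance
from .msa import Alignment, Segment, SegmentAnnotation
from .njtree import bootstrap_support


@dataclass
class SegmentAlignment:
    """A gap-stripped per-segment subalignment."""

    label: str
    alignment: Alignment
    n_positions: int  # columns retained after complete gap deletion


def segment_subalignments(
    aln: Alignment, annotation: SegmentAnnotation
) -> list[SegmentAlignment]:
    """Cut the alignment into annotated segments and apply complete gap
    deletion within each. Segments losing every column are returned with
    ``n_positions == 0`` and must be excluded from treeing by the caller.
    """
    out = []
    for seg in annotation:
        if seg.end > aln.length:
            raise ValueError(f"segment {seg.label} extends beyond the alignment")
        sub = aln.slice(seg.start, seg.end).drop_gap_columns()
        out.append(SegmentAlignment(seg.label, sub, sub.length))
    return out


@dataclass
class SegmentCall:
    """Clade assignment of one query segment."""

    label: str
    assignment: str  # clade name or "ambiguous"
    best_clade: str | None
    best_distance: float | None
    margin: float | None  # (second-best clade min - best)/best
    support: float | None  # bootstrap % for query+best-clade split, if computed
    reason: str = ""


@dataclass
class ChimeraMap:
    """Per-segment clade assignment for one query gene."""

    query: str
    calls: list[SegmentCall]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.label, c.assignment, c.best_clade, c.best_distance, c.margin, c.support, c.reason)
                for c in self.calls
            ],
            columns=[
                "segment",
                "assignment",
                "best_clade",
                "best_distance",
                "margin",
                "support",
                "reason",
            ],
        )

    def assignments(self) -> dict[str, str]:
        return {c.label: c.assignment for c in self.calls}


def classify_chimera(
    query: str,
    references: dict[str, list[str]],
    aln: Alignment,
    annotation: SegmentAnnotation,
    *,
    margin_threshold: float = 0.05,
    bootstrap: int = 0,
    seed: int = 0,
) -> ChimeraMap:
    """Assign each annotated segment of a query gene to its nearest clade.

    ``references`` maps clade names (e.g. ``"HBB"``, ``"HBD"``) to exemplar
    sequence names; an ``"outgroup"`` entry, if present, joins the trees but
    never wins an assignment. Per segment, the query is assigned the clade
    of the minimum-TN93-distance exemplar; the relative margin to the best
    exemplar of any other clade below ``margin_threshold`` yields
    ``ambiguous``. With ``bootstrap > 0``, NJ support for the split grouping
    the query with its assigned clade is attached.
    """
    clades = {c: list(names) for c, names in references.items() if c != "outgroup"}
    if len(clades) < 2:
        raise ValueError("need at least two non-outgroup reference clades")
    involved = [query] + [n for names in references.values() for n in names]
    sub = aln.subset(involved)
    calls = []
    for segaln in segment_subalignments(sub, annotation):
        label, seg = segaln.label, segaln.alignment
        if segaln.n_positions == 0:
            calls.append(
                SegmentCall(label, "ambiguous", None, None, None, None, "no columns after gap deletion")
            )
            continue
        qseq = seg[query]
        best: dict[str, tuple[float, str]] = {}
        for clade, names in clades.items():
            dists = []
            for name in names:
                d = tn93_distance(qseq, seg[name])
                if not math.isnan(d):
                    dists.append((d, name))
            if dists:
                best[clade] = min(dists)
        if not best:
            calls.append(
                SegmentCall(label, "ambiguous", None, None, None, None, "all distances undefined")
            )
            continue
        ranked = sorted(best.items(), key=lambda kv: kv[1][0])
        best_clade, (best_d, _) = ranked[0]
        if len(ranked) == 1:
            margin = math.inf
        else:
            second_d = ranked[1][1][0]
            margin = math.inf if best_d == 0 else (second_d - best_d) / best_d
            if best_d == 0 and second_d == 0:
                margin = 0.0
        assignment = best_clade if margin >= margin_threshold else "ambiguous"
        support = None
        if bootstrap > 0:
            tree = bootstrap_support(
                seg.names, seg.seqs, b=bootstrap, seed=seed
            )
            target = frozenset([query] + clades[best_clade])
            norm = tree._normalize(target)
            support = tree.support.get(norm, 0.0)
        calls.append(
            SegmentCall(label, assignment, best_clade, best_d, margin, support)
        )
    return ChimeraMap(query, calls)


@dataclass(frozen=True)
class SharedTract:
    """A maximal run of columns identical across a set of sequences."""

    members: tuple[str, ...]
    start: int
    end: int  # half-open

    @property
    def length(self) -> int:
        return self.end - self.start

    def overhang(self, segment: Segment) -> tuple[int, int]:
        """(left, right) extent of the tract beyond a segment's bounds."""
        return max(0, segment.start - self.start), max(0, self.end - segment.end)


def find_shared_identical_tracts(
    aln: Alignment, min_len: int = 1, *, members: list[str] | None = None
) -> list[SharedTract]:
    """Maximal byte-identical column runs across the listed sequences.

    Gap characters participate in the identity comparison (a shared gap is
    shared sequence state). Runs shorter than ``min_len`` are dropped.
    """
    if members is not None:
        aln = aln.subset(members)
    names = tuple(aln.names)
    mat = aln.matrix()
    same = (mat == mat[0]).all(axis=0)
    tracts = []
    start = None
    for i, ok in enumerate(same):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_len:
                tracts.append(SharedTract(names, start, i))
            start = None
    if start is not None and aln.length - start >= min_len:
        tracts.append(SharedTract(names, start, aln.length))
    return tracts
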