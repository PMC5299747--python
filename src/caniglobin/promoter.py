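"""Proximal-promoter analysis of adult beta-globin genes.

The adult beta-globin promoter carries a small set of conserved elements —
most importantly the CACC(C) box bound by erythroid Krüppel-like factor
(EKLF), required for strong adult expression, plus the CCAAT and TATA-type
boxes. A paralog that acquired the other paralog's promoter through gene
conversion shows up here twice: its proximal promoter is near-identical to
the donor's, and it gains (or loses) consensus copies of these motifs.

Motifs are IUPAC consensus strings scanned on the forward strand only
(promoters are supplied on the coding strand). When an alignment to an
exemplar promoter is available, the query's resident sequence at each
exemplar motif location is also reported, flagged non-consensus when it
mismatches — locating broken elements, not just intact ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .msa import GAP_CHARS, Alignment

IUPAC_SETS = {code: frozenset(vals) for code, vals in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class MotifEntry:
    name: str
    consensus: str
    description: str = ""

    def __post_init__(self):
        bad = [c for c in self.consensus.upper() if c not in IUPAC_SETS]
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC characters {bad}")


@dataclass
class MotifCatalog:
    entries: list[MotifEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "MotifCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            [
                MotifEntry(r["name"], r["consensus"], str(r.get("description", "")))
                for _, r in df.iterrows()
            ]
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(e.name, e.consensus, e.description) for e in self.entries],
            columns=["name", "consensus", "description"],
        ).to_csv(path, sep="\t", index=False)


def default_catalog() -> MotifCatalog:
    """Built-in catalog of beta-globin proximal-promoter elements.

    The bDRE consensus is a configurable placeholder: the exact element
    sequence should be supplied from the user's reference annotation (see
    the methods note); the default is deliberately short and generic.
    """
    return MotifCatalog(
        [
            MotifEntry("CACC_box", "CACCC", "EKLF/KLF1-bound element"),
            MotifEntry("CCAAT_box", "CCAAT", "NF-Y/CP1-bound element"),
            MotifEntry("TATA_box", "CATAAA", "beta-globin ATA/TATA element"),
            MotifEntry("bDRE", "GTCAAGG", "downstream element placeholder; override from reference annotation"),
        ]
    )


def _iupac_match(seq_char: str, consensus_char: str) -> bool:
    # an N in the query matches only a fully degenerate consensus position
    return seq_char in IUPAC_SETS[consensus_char]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int  # 0-based on the forward strand
    matched: str
    status: str  # "consensus" | "non-consensus"
    mismatches: int = 0


def scan_motifs(
    sequence: str,
    catalog: MotifCatalog,
    *,
    exemplar_pair: tuple[str, str] | None = None,
) -> list[MotifHit]:
    """All forward-strand IUPAC matches of the catalog in a DNA sequence.

    ``exemplar_pair`` is an optional (query_aligned, exemplar_aligned) pair
    of gapped strings whose ungapped query equals ``sequence``; motif
    occurrences found in the exemplar are then mapped through the alignment
    and the query's resident substring at each expected location is
    reported, flagged ``non-consensus`` with its mismatch count when it
    departs from the consensus. Exact duplicates of direct hits are merged.
    """
    seq = sequence.upper()
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    hits: list[MotifHit] = []
    for entry in catalog:
        cons = entry.consensus.upper()
        k = len(cons)
        for i in range(len(seq) - k + 1):
            if all(_iupac_match(seq[i + j], cons[j]) for j in range(k)):
                hits.append(MotifHit(entry.name, i, seq[i : i + k], "consensus"))

    if exemplar_pair is not None:
        q_aln, e_aln = (s.upper() for s in exemplar_pair)
        if len(q_aln) != len(e_aln):
            raise ValueError("exemplar pair must be aligned (equal length)")
        if "".join(c for c in q_aln if c not in GAP_CHARS) != seq:
            raise ValueError("aligned query does not match the scanned sequence")
        # map alignment column -> query ungapped coordinate (next residue)
        q_pos = []
        p = 0
        for c in q_aln:
            q_pos.append(p)
            if c not in GAP_CHARS:
                p += 1
        e_seq = "".join(c for c in e_aln if c not in GAP_CHARS)
        e_cols = [i for i, c in enumerate(e_aln) if c not in GAP_CHARS]
        direct = {(h.motif, h.position) for h in hits}
        for eh in scan_motifs(e_seq, catalog):
            col = e_cols[eh.position]
            qp = q_pos[col]
            cons = next(e.consensus.upper() for e in catalog if e.name == eh.motif)
            k = len(cons)
            if qp + k > len(seq):
                continue
            resident = seq[qp : qp + k]
            mism = sum(
                0 if _iupac_match(a, b) else 1 for a, b in zip(resident, cons)
            )
            if mism == 0:
                continue  # already reported as a direct consensus hit (or shifted)
            if (eh.motif, qp) not in direct:
                hits.append(MotifHit(eh.motif, qp, resident, "non-consensus", mism))
    return sorted(hits, key=lambda h: (h.position, h.motif))


@dataclass
class PromoterCall:
    """HBB-like vs HBD-like classification of a proximal promoter."""

    query: str
    identity_hbb: float  # percent
    identity_hbd: float
    call: str  # "HBB-like" | "HBD-like" | "ambiguous"
    track: list[str]  # per column: "B", "D", "both", "neither", "gap"


def classify_promoter(
    query_aln: str,
    hbb_aln: str,
    hbd_aln: str,
    *,
    query: str = "query",
    margin: float = 2.0,
) -> PromoterCall:
    """Classify a pre-aligned promoter trio by percent identity.

    Identity is computed over columns where the query is ungapped; the call
    goes to the exemplar with the higher identity when the gap is at least
    ``margin`` percentage points, else ``ambiguous``. The per-column
    nearest-exemplar track localises conversion breakpoints.
    """
    if not (len(query_aln) == len(hbb_aln) == len(hbd_aln)):
        raise ValueError("trio must be aligned (equal lengths)")
    track = []
    match_b = match_d = n = 0
    for q, b, d in zip(query_aln.upper(), hbb_aln.upper(), hbd_aln.upper()):
        if q in GAP_CHARS:
            track.append("gap")
            continue
        n += 1
        mb, md = q == b, q == d
        match_b += mb
        match_d += md
        track.append({(True, True): "both", (True, False): "B", (False, True): "D", (False, False): "neither"}[(mb, md)])
    if n == 0:
        raise ValueError("query is all-gap over the window")
    id_b, id_d = 100.0 * match_b / n, 100.0 * match_d / n
    if abs(id_b - id_d) < margin:
        call = "ambiguous"
    else:
        call = "HBB-like" if id_b > id_d else "HBD-like"
    return PromoterCall(query, id_b, id_d, call, track)


def estimate_breakpoint(track: list[str]) -> int:
    """Column index best splitting a mosaic track into a B-side and a D-side.

    Maximises (#B-matching columns left of the split) + (#D-matching columns
    right of it); informative for promoters whose 5' end was converted from
    the HBB exemplar. Returns the first argmax.
    """
    b = np.array([c == "B" for c in track], dtype=int)
    d = np.array([c == "D" for c in track], dtype=int)
    left_b = np.concatenate([[0], np.cumsum(b)])
    right_d = np.concatenate([np.cumsum(d[::-1])[::-1], [0]])
    return int(np.argmax(left_b + right_d))


@dataclass(frozen=True)
class DivergentSite:
    column: int  # 0-based alignment column
    consensus_base: str
    query_base: str
    nearest_motif: str | None = None
    motif_distance: int | None = None


def conserved_divergent_sites(
    aln: Alignment,
    query: str,
    *,
    conservation_min: float = 1.0,
    motif_hits: list[MotifHit] | None = None,
) -> list[DivergentSite]:
    """Columns conserved across the orthologs but divergent in the query.

    A column qualifies when the modal base among non-query, non-gap
    sequences reaches frequency >= ``conservation_min`` (of the non-query
    sequences present) and the query carries a different, non-gap base.
    With ``motif_hits`` (query coordinates == alignment coordinates), each
    site reports its distance to the nearest hit.
    """
    others = [n for n in aln.names if n != query]
    if query not in aln:
        raise KeyError(f"query {query!r} not in alignment")
    if len(others) < 3:
        raise ValueError("need at least 3 non-query sequences")
    qseq = aln[query]
    sites = []
    for col in range(aln.length):
        bases = [aln[o][col] for o in others if aln[o][col] not in GAP_CHARS]
        if not bases:
            continue
        vals, counts = np.unique(bases, return_counts=True)
        modal = vals[np.argmax(counts)]
        if counts.max() / len(others) < conservation_min:
            continue
        q = qseq[col]
        if q in GAP_CHARS or q == modal:
            continue
        nearest = dist = None
        if motif_hits:
            best = min(
                motif_hits,
                key=lambda h: min(abs(col - h.position), abs(col - (h.position + len(h.matched) - 1))),
            )
            nearest = best.motif
            dist = int(
                min(abs(col - best.position), abs(col - (best.position + len(best.matched) - 1)))
            )
        sites.append(DivergentSite(col, str(modal), q, nearest, dist))
    return sites
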