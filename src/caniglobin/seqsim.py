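"""Simulation of paralog gene families with gene conversion, and of ortholog
protein sets with planted lineage-unique residues.

Nucleotide evolution follows the Tamura–Nei (1993) substitution process:
separate rates for the two transition types (A<->G, C<->T) and for
transversions, with arbitrary stationary base frequencies. Branch lengths
are expected substitutions per site, matching the scale of the TN93 distance
estimator, so closed-form expectations exist for simulated divergence.

Gene conversion is modelled as a literal, non-reciprocal copy: after the
sequences have evolved down the guide tree, each event overwrites the
acceptor's alignment tract with the donor's current tract, in listed order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo
from scipy.linalg import expm

from .msa import Alignment, SegmentAnnotation

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TN93Params:
    """Rates of the TN93 process, normalised to one substitution/site.

    ``kappa_purine`` and ``kappa_pyrimidine`` are the A<->G and C<->T
    transition/transversion rate ratios (alpha1/beta, alpha2/beta).
    """

    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa_purine: float = 4.0
    kappa_pyrimidine: float = 4.0

    def __post_init__(self):
        if abs(sum(self.pi) - 1.0) > 1e-9 or any(p <= 0 for p in self.pi):
            raise ValueError("pi must be positive and sum to 1")
        if self.kappa_purine <= 0 or self.kappa_pyrimidine <= 0:
            raise ValueError("rate ratios must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix Q, scaled so -sum(pi_i * q_ii) = 1."""
        pi = np.asarray(self.pi)
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                purines = {0, 2}  # A, G
                if {i, j} == purines:
                    rate = self.kappa_purine
                elif {i, j} == {1, 3}:  # C, T
                    rate = self.kappa_pyrimidine
                else:
                    rate = 1.0
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t) for a branch of t substitutions/site."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if t == 0:
            return np.eye(4)
        return expm(self.rate_matrix() * t)

    def expected_p_distance(self, t: float) -> float:
        """Expected proportion of differing sites after divergence t."""
        p = self.transition_matrix(t)
        pi = np.asarray(self.pi)
        return float(1.0 - (pi * np.diag(p)).sum())


@dataclass(frozen=True)
class ConversionEvent:
    """Non-reciprocal copy of donor tract [tract_start, tract_end) into acceptor."""

    donor: str
    acceptor: str
    tract_start: int
    tract_end: int

    def __post_init__(self):
        if self.tract_start >= self.tract_end:
            raise ValueError("tract_start must be < tract_end")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


@dataclass
class GeneFamilyTruth:
    """Ground truth of a simulated paralog family."""

    guide_tree: str  # newick
    segments: SegmentAnnotation | None
    events: list[ConversionEvent]
    alignment: Alignment = field(default=None)  # filled by the simulator

    def to_json_dict(self) -> dict:
        return {
            "guide_tree": self.guide_tree,
            "segments": (
                None
                if self.segments is None
                else [[s.label, s.start, s.end] for s in self.segments]
            ),
            "events": [
                [e.donor, e.acceptor, e.tract_start, e.tract_end] for e in self.events
            ],
        }


def _evolve(seq_idx: np.ndarray, t: float, params: TN93Params, rng) -> np.ndarray:
    """Evolve an integer-coded sequence along a branch of length t."""
    p = params.transition_matrix(t)
    out = np.empty_like(seq_idx)
    for base in range(4):
        sites = seq_idx == base
        n = int(sites.sum())
        if n:
            out[sites] = rng.choice(4, size=n, p=p[base])
    return out


def simulate_gene_family(
    guide_tree: str,
    length: int,
    *,
    events: list[ConversionEvent] | None = None,
    segments: SegmentAnnotation | None = None,
    params: TN93Params = TN93Params(),
    seed: int = 0,
) -> GeneFamilyTruth:
    """Evolve a gapless gene family down a newick guide tree, then apply
    gene-conversion events to the tip sequences.

    The root sequence is drawn from the stationary distribution; every site
    evolves independently under the TN93 process. Events are applied in
    listed order, each overwriting the acceptor tract with the donor's
    *current* (possibly already-converted) tract. Deterministic given seed.
    """
    events = list(events or [])
    tree = Phylo.read(io.StringIO(guide_tree), "newick")
    rng = np.random.default_rng(seed)
    root_seq = rng.choice(4, size=length, p=np.asarray(params.pi))

    tips: dict[str, np.ndarray] = {}

    def recurse(clade, seq):
        for child in clade.clades:
            bl = child.branch_length
            if bl is None:
                bl = 0.0
            if bl < 0:
                raise ValueError("guide tree branch lengths must be non-negative")
            child_seq = _evolve(seq, float(bl), params, rng)
            if child.clades:
                recurse(child, child_seq)
            else:
                name = child.name
                if name is None:
                    raise ValueError("every leaf in the guide tree needs a name")
                tips[name] = child_seq

    root = tree.root
    if not root.clades:  # single-leaf tree
        tips[root.name] = root_seq
    else:
        recurse(root, root_seq)

    for ev in events:
        if ev.donor not in tips or ev.acceptor not in tips:
            raise KeyError(f"event names unknown in tree: {ev.donor}/{ev.acceptor}")
        if ev.tract_end > length:
            raise ValueError("conversion tract outside the alignment")
        tips[ev.acceptor] = tips[ev.acceptor].copy()
        tips[ev.acceptor][ev.tract_start : ev.tract_end] = tips[ev.donor][
            ev.tract_start : ev.tract_end
        ]

    names = list(tips)
    aln = Alignment(
        names, ["".join(NUCLEOTIDES[i] for i in tips[n]) for n in names]
    )
    truth = GeneFamilyTruth(guide_tree, segments, events, aln)
    return truth


@dataclass
class OrthologTruth:
    """Ground truth of a simulated ortholog protein set."""

    alignment: Alignment
    consensus: str
    plants: list[tuple[int, int, str]]  # (seq index, column, residue)


def simulate_ortholog_proteins(
    n_seqs: int,
    length: int,
    planted_unique: list[tuple[int, int, str]] | None = None,
    *,
    background_sub_rate: float = 0.05,
    seed: int = 0,
) -> OrthologTruth:
    """Simulate an aligned ortholog protein set with planted rare residues.

    Each column has a consensus residue (uniform over the 20 amino acids);
    every cell carries the consensus except with probability
    ``background_sub_rate``, when it is replaced by a uniformly random other
    residue. Planted residues are then written at the requested cells.
    Sequences that receive a plant are kept free of background substitutions
    so that their rare residues are exactly the planted ones.
    """
    plants = list(planted_unique or [])
    for s, pos, res in plants:
        if not (0 <= s < n_seqs and 0 <= pos < length):
            raise ValueError(f"plant ({s}, {pos}) outside the alignment")
        if res not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {res!r}")
    seen_cells: dict[tuple[int, int], str] = {}
    for s, pos, res in plants:
        if seen_cells.setdefault((s, pos), res) != res:
            raise ValueError(f"conflicting plants at sequence {s}, column {pos}")

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    consensus_idx = rng.integers(0, 20, size=length)
    mat = np.tile(consensus_idx, (n_seqs, 1))
    if background_sub_rate > 0:
        noise = rng.random((n_seqs, length)) < background_sub_rate
        clean = {s for s, _, _ in plants}
        for s in clean:
            noise[s, :] = False
        # replace with a uniformly random *different* residue
        shift = rng.integers(1, 20, size=noise.sum())
        mat[noise] = (mat[noise] + shift) % 20
    for s, pos, res in plants:
        mat[s, pos] = AMINO_ACIDS.index(res)
    # enforce the plant-count contract: no unplanted sequence may carry a
    # planted residue at its column through background noise
    planted_cells = {(s, pos) for s, pos, _ in plants}
    for s, pos, res in plants:
        res_idx = AMINO_ACIDS.index(res)
        if res_idx == consensus_idx[pos]:
            raise ValueError(
                f"plant at column {pos} equals the column consensus {res!r}; "
                "it would not be a substitution"
            )
        for other in range(n_seqs):
            if (other, pos) in planted_cells:
                continue
            if mat[other, pos] == res_idx:
                shift = int(rng.integers(1, 20))
                new = (res_idx + shift) % 20
                if new == consensus_idx[pos]:
                    mat[other, pos] = consensus_idx[pos]
                else:
                    mat[other, pos] = new

    names = [f"seq{{:0{len(str(max(n_seqs - 1, 1)))}d}}".format(i) for i in range(n_seqs)]
    seqs = ["".join(aa[row]) for row in mat]
    consensus = "".join(aa[consensus_idx])
    return OrthologTruth(Alignment(names, seqs), consensus, plants)
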