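"""End-to-end synthetic-data studies: each runs a full analysis pipeline on
generated data with known truth and measures recovery.

These are the package's reference experiments — the same routines back the
test suite and the reproduction script. Problem sizes follow the package's
standard study conditions: panels of 10 breeds x 25 dogs x 5,000 markers at
5 kb mean spacing (~25 Mb, 200 kb scan windows), paralog families of seven
gene-structure segments (~1.5 kb) with >= 5% between-clade divergence, and
43-sequence ortholog protein sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kstest

from .fst import di_scan, empirical_p_and_fdr, hudson_fst
from .msa import gene_structure_annotation
from .phasing import extend_block, split_homozygotes
from .chimera import classify_chimera
from .seqsim import ConversionEvent, simulate_gene_family, simulate_ortholog_proteins
from .simulate import PanelConfig, SweepSpec, inject_sweep, simulate_panel

WINDOW_BP = 200_000

FAMILY_TREE = (
    "((hbb_dog:0.03,hbb_cat:0.03,hbb_fer:0.03):0.05,"
    "(hbd_dog:0.03,hbd_cat:0.03,hbd_fer:0.03):0.05,outg:0.15);"
)
SEGMENT_LENGTHS = (300, 90, 120, 220, 400, 120, 300)
FAMILY_REFS = {
    "HBB": ["hbb_cat", "hbb_fer"],
    "HBD": ["hbd_cat", "hbd_fer"],
    "outgroup": ["outg"],
}


@dataclass
class SweepRecovery:
    """Per-seed sweep phasing and d_i ranking outcomes."""

    boundary_errors: list[tuple[int, int]]  # (left, right) marker offsets
    phase_within_1: int
    di_top1: int
    n_seeds: int

    @property
    def phase_rate(self) -> float:
        return 100.0 * self.phase_within_1 / self.n_seeds

    @property
    def di_top1_rate(self) -> float:
        return 100.0 * self.di_top1 / self.n_seeds


def sweep_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> SweepRecovery:
    """Plant a fully fixed one-window sweep in one breed; recover it.

    Per seed: simulate the standard panel, fix the haplotype over every
    marker of the window containing the map midpoint, then (a) directly
    phase from a mid-tract anchor and compare block boundaries with the
    planted tract, and (b) run the d_i scan and ask whether the sweep
    window is the swept breed's top-ranked window genome-wide.
    """
    errors, within, top1 = [], 0, 0
    for k in range(n_seeds):
        seed = base_seed + k
        panel, _ = simulate_panel(PanelConfig(seed=seed))
        pos = panel.markers["pos"].to_numpy()
        target_win = int(pos[len(pos) // 2] // WINDOW_BP)
        in_win = np.flatnonzero(pos // WINDOW_BP == target_win)
        first, last = int(in_win[0]), int(in_win[-1])
        spec = SweepSpec("breed00", first, last, tuple([1] * (last - first + 1)), 1.0)
        swept = inject_sweep(panel, spec, seed=seed)

        anchor = (first + last) // 2
        dogs = split_homozygotes(swept, anchor, "breed00")["B"]
        block = extend_block(swept, anchor, dogs)
        err = (block.left_idx - first, block.right_idx - last)
        errors.append(err)
        within += abs(err[0]) <= 1 and abs(err[1]) <= 1

        result = empirical_p_and_fdr(di_scan(swept, WINDOW_BP))
        top = result.top_window("breed00")
        top1 += int(top["start"]) == target_win * WINDOW_BP
    return SweepRecovery(errors, within, top1, n_seeds)


@dataclass
class NullCalibration:
    frac_p_le_05: float  # fraction, 0..1
    ks_pvalue: float
    n_pvalues: int


def null_calibration_study(n_panels: int = 3, base_seed: int = 100) -> NullCalibration:
    """d_i empirical p-values on panels with no sweep: uniformity check."""
    ps = []
    for k in range(n_panels):
        panel, _ = simulate_panel(PanelConfig(seed=base_seed + k))
        result = empirical_p_and_fdr(di_scan(panel, WINDOW_BP))
        ps.append(result.table["p"].to_numpy())
    ps = np.concatenate(ps)
    return NullCalibration(
        float((ps <= 0.05).mean()), float(kstest(ps, "uniform").pvalue), ps.size
    )


def drift_recovery(seed: int = 0, n_markers: int = 10_000) -> float:
    """Ratio-of-sums Hudson F_ST between two simulated breeds (truth 0.1)."""
    panel, _ = simulate_panel(
        PanelConfig(n_breeds=2, n_per_breed=50, n_markers=n_markers,
                    drift_fst=0.1, seed=seed)
    )
    b1, n1 = panel.allele_stats("breed00")
    b2, n2 = panel.allele_stats("breed01")
    num, den = hudson_fst(b1 / n1, n1, b2 / n2, n2)
    ok = ~np.isnan(den)
    return float(num[ok].sum() / den[ok].sum())


def chimera_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> float:
    """Percent of seeds where every segment's clade call matches truth.

    The planted conversion copies dog HBB into dog HBD over the first two
    gene-structure segments (390 sites); the query must come out HBB-like
    there and HBD-like elsewhere.
    """
    ann = gene_structure_annotation(list(SEGMENT_LENGTHS))
    tract_end = SEGMENT_LENGTHS[0] + SEGMENT_LENGTHS[1]
    events = [ConversionEvent("hbb_dog", "hbd_dog", 0, tract_end)]
    want = {s.label: ("HBB" if s.end <= tract_end else "HBD") for s in ann}
    hits = 0
    for k in range(n_seeds):
        truth = simulate_gene_family(
            FAMILY_TREE, sum(SEGMENT_LENGTHS), events=events, segments=ann,
            seed=base_seed + k,
        )
        got = classify_chimera(
            "hbd_dog", FAMILY_REFS, truth.alignment, ann
        ).assignments()
        hits += got == want
    return 100.0 * hits / n_seeds


def rare_flag_recovery(seed: int = 0, n_seqs: int = 43, length: int = 146) -> dict:
    """Plant one unique residue in a 43-sequence ortholog set; recover it.

    Returns the planted and recovered flag descriptions for comparison.
    """
    from .proteins import flag_rare_substitutions

    rng = np.random.default_rng(seed)
    pos = int(rng.integers(0, length))
    qi = int(rng.integers(0, n_seqs))
    try:
        truth = simulate_ortholog_proteins(
            n_seqs, length, [(qi, pos, "I")], seed=seed
        )
    except ValueError:
        # the column consensus happened to be I: redraw the study seed
        return rare_flag_recovery(seed + 7919, n_seqs, length)
    query = truth.alignment.names[qi]
    flags = flag_rare_substitutions(truth.alignment, query, max_count=2)
    return {
        "planted": [(pos + 1, "I", 1)],
        "recovered": [(f.column, f.query_residue, f.count) for f in flags],
        "n_total": n_seqs,
    }
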