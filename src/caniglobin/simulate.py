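"""Simulation of breed-structured SNP panels with optional selective sweeps.

The generator follows the Balding–Nichols model: each marker has a baseline
(ancestral) B-allele frequency p drawn from a Beta distribution, and each
breed draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), where F is
the drift parameter and equals the expected F_ST between breeds. Genotypes
are sampled under Hardy–Weinberg within breed, as two phased chromosome
copies per dog, so that sweep injection at partial fixation is exact.

A sweep is a fixed haplotype over a contiguous marker tract carried by a
configurable fraction of one breed's chromosomes — the genotype-level
signature of strong recent selection in an isolated breed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of a simulated breed-structured genotype panel.

    ``drift_fst`` is the Balding–Nichols differentiation parameter in (0, 1);
    ``baseline_af_dist`` are the Beta(a, b) parameters of the ancestral
    allele-frequency distribution (clipped to [0.05, 0.95] so every marker is
    informative). The default Beta(2, 2) weights intermediate frequencies,
    emulating the ascertainment of genotyping arrays toward common variants;
    it also keeps within-breed near-fixation of background markers rare, so
    a planted sweep tract stays identifiable against the background.
    ``marker_spacing_bp`` is the mean inter-marker distance.
    """

    n_breeds: int = 10
    n_per_breed: int = 25
    n_markers: int = 5000
    marker_spacing_bp: float = 5000.0
    drift_fst: float = 0.1
    baseline_af_dist: tuple[float, float] = (2.0, 2.0)
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self):
        if self.n_breeds < 1 or self.n_per_breed < 1 or self.n_markers < 1:
            raise ValueError("breed, sample and marker counts must be >= 1")
        if not 0.0 < self.drift_fst < 1.0:
            raise ValueError("drift_fst must lie in (0, 1)")
        if self.marker_spacing_bp <= 0:
            raise ValueError("marker_spacing_bp must be positive")
        a, b = self.baseline_af_dist
        if a <= 0 or b <= 0:
            raise ValueError("baseline Beta parameters must be positive")


@dataclass(frozen=True)
class SweepSpec:
    """A fixed haplotype planted over a contiguous marker tract in one breed.

    ``haplotype`` is a vector of B-allele indicators (0/1) covering markers
    ``first_marker``..``last_marker`` inclusive; ``fixation`` is the fraction
    of the breed's chromosomes carrying it.
    """

    breed: str
    first_marker: int
    last_marker: int
    haplotype: tuple[int, ...]
    fixation: float = 1.0

    def __post_init__(self):
        if self.first_marker > self.last_marker:
            raise ValueError("first_marker must be <= last_marker")
        if len(self.haplotype) != self.last_marker - self.first_marker + 1:
            raise ValueError("haplotype length must match tract length")
        if any(a not in (0, 1) for a in self.haplotype):
            raise ValueError("haplotype alleles must be 0/1")
        if not 0.0 <= self.fixation <= 1.0:
            raise ValueError("fixation must lie in [0, 1]")


@dataclass
class PanelTruth:
    """Ground truth recorded by :func:`simulate_panel`."""

    baseline_af: np.ndarray  # (n_markers,)
    breed_af: pd.DataFrame  # markers x breeds

    def to_json_dict(self) -> dict:
        return {
            "baseline_af": self.baseline_af.tolist(),
            "breed_af": {b: self.breed_af[b].tolist() for b in self.breed_af.columns},
        }


def simulate_panel(config: PanelConfig) -> tuple[GenotypePanel, PanelTruth]:
    """Simulate a breed-structured diploid SNP panel.

    Returns the panel (carrying phased haplotypes) and the true baseline and
    per-breed allele frequencies. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    a, b = config.baseline_af_dist
    baseline = np.clip(rng.beta(a, b, size=config.n_markers), 0.05, 0.95)

    f = config.drift_fst
    scale = (1.0 - f) / f
    breed_names = [f"breed{k:02d}" for k in range(config.n_breeds)]
    breed_af = np.empty((config.n_markers, config.n_breeds))
    for k in range(config.n_breeds):
        breed_af[:, k] = rng.beta(baseline * scale, (1.0 - baseline) * scale)

    n = config.n_per_breed
    haps = np.empty((config.n_markers, config.n_breeds * n, 2), dtype=np.uint8)
    for k in range(config.n_breeds):
        p = breed_af[:, k][:, None, None]
        haps[:, k * n : (k + 1) * n, :] = rng.random((config.n_markers, n, 2)) < p
    genotypes = haps.sum(axis=2).astype(np.int8)

    spacing = np.maximum(
        1, np.round(rng.exponential(config.marker_spacing_bp, config.n_markers))
    ).astype(np.int64)
    positions = np.cumsum(spacing)
    markers = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "id": [f"snp{i:06d}" for i in range(config.n_markers)],
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"{bn}_dog{d:03d}" for bn in breed_names for d in range(n)],
            "breed": np.repeat(breed_names, n),
        }
    )
    panel = GenotypePanel(markers, samples, genotypes, haplotypes=haps)
    truth = PanelTruth(baseline, pd.DataFrame(breed_af, columns=breed_names))
    return panel, truth


def inject_sweep(
    panel: GenotypePanel, spec: SweepSpec, *, seed: int = 0
) -> GenotypePanel:
    """Plant a swept haplotype into one breed of a panel.

    A fraction ``spec.fixation`` of the breed's chromosome copies is replaced
    by ``spec.haplotype`` over the tract; genotypes outside the tract and in
    other breeds are untouched. The carrier chromosomes are chosen uniformly
    at random (``seed``); at ``fixation=1.0`` every copy is replaced.
    Requires phased haplotypes when ``fixation < 1``.
    """
    if not (0 <= spec.first_marker and spec.last_marker < panel.n_markers):
        raise ValueError("sweep tract outside the panel's marker range")
    cols = panel.sample_indices(spec.breed)  # raises on unknown breed
    out = panel.copy()
    tract = slice(spec.first_marker, spec.last_marker + 1)
    hap = np.asarray(spec.haplotype, dtype=np.uint8)

    if spec.fixation >= 1.0:
        for j in cols:
            out.genotypes[tract, j] = 2 * hap
            if out.haplotypes is not None:
                out.haplotypes[tract, j, 0] = hap
                out.haplotypes[tract, j, 1] = hap
        return out

    if out.haplotypes is None:
        raise ValueError("partial fixation requires a panel with phased haplotypes")
    rng = np.random.default_rng(seed)
    n_chrom = 2 * cols.size
    k = int(round(spec.fixation * n_chrom))
    chosen = rng.choice(n_chrom, size=k, replace=False)
    for c in chosen:
        j, copy = cols[c // 2], c % 2
        out.haplotypes[tract, j, copy] = hap
    for j in cols:
        dosage = out.haplotypes[tract, j, :].sum(axis=1).astype(np.int8)
        was_missing = out.genotypes[tract, j] == MISSING
        dosage[was_missing] = MISSING
        out.genotypes[tract, j] = dosage
    return out
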