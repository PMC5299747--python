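"""The synthetic-data generators: drift calibration, HWE sampling, sweep
injection semantics and sequence-evolution expectations."""

import numpy as np
import pytest
from scipy.stats import chi2

import caniglobin as cg
from caniglobin.msa import gene_structure_annotation
from caniglobin.seqsim import (
    ConversionEvent,
    TN93Params,
    simulate_gene_family,
    simulate_ortholog_proteins,
)


def ratio_of_sums_fst(panel, breed_i, breed_j):
    b1, n1 = panel.allele_stats(breed_i)
    b2, n2 = panel.allele_stats(breed_j)
    num, den = cg.hudson_fst(b1 / n1, n1, b2 / n2, n2)
    ok = ~np.isnan(den)
    return num[ok].sum() / den[ok].sum()


class TestSimulatePanel:
    def test_determinism(self):
        cfg = cg.PanelConfig(n_breeds=3, n_per_breed=5, n_markers=100, seed=7)
        p1, t1 = cg.simulate_panel(cfg)
        p2, t2 = cg.simulate_panel(cfg)
        np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)
        np.testing.assert_array_equal(t1.baseline_af, t2.baseline_af)
        assert p1.markers.equals(p2.markers)

    def test_no_drift_means_no_differentiation(self):
        cfg = cg.PanelConfig(
            n_breeds=2, n_per_breed=50, n_markers=10_000, drift_fst=1e-6, seed=3
        )
        panel, truth = cg.simulate_panel(cfg)
        af = truth.breed_af.to_numpy()
        assert np.abs(af[:, 0] - truth.baseline_af).mean() < 0.01
        fst = ratio_of_sums_fst(panel, "breed00", "breed01")
        assert abs(fst) < 0.005

    def test_drift_fst_recovered(self):
        cfg = cg.PanelConfig(
            n_breeds=2, n_per_breed=50, n_markers=10_000, drift_fst=0.1, seed=11
        )
        panel, _ = cg.simulate_panel(cfg)
        fst = ratio_of_sums_fst(panel, "breed00", "breed01")
        assert fst == pytest.approx(0.1, abs=0.02)

    def test_genotypes_fit_hwe(self):
        """Per-SNP genotype counts match HWE proportions at the true breed
        frequency; with alpha=0.01 the rejection rate stays near nominal."""
        cfg = cg.PanelConfig(n_breeds=1, n_per_breed=200, n_markers=2000, seed=5)
        panel, truth = cg.simulate_panel(cfg)
        p = truth.breed_af["breed00"].to_numpy()
        g = panel.genotypes
        n = g.shape[1]
        counts = np.stack([(g == k).sum(axis=1) for k in (0, 1, 2)], axis=1)
        expected = np.stack(
            [n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2], axis=1
        )
        keep = (expected > 5).all(axis=1)  # chi-square validity
        stat = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum(axis=1)
        reject = (stat > chi2.ppf(0.99, df=2)).mean()
        assert reject < 0.02

    def test_marker_positions_strictly_increasing(self):
        panel, _ = cg.simulate_panel(cg.PanelConfig(n_markers=500, seed=2))
        assert panel.markers["pos"].is_monotonic_increasing

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cg.PanelConfig(drift_fst=0.0)
        with pytest.raises(ValueError):
            cg.PanelConfig(n_per_breed=0)


class TestInjectSweep:
    @pytest.fixture
    def panel(self):
        return cg.simulate_panel(
            cg.PanelConfig(n_breeds=3, n_per_breed=10, n_markers=200, seed=9)
        )[0]

    def test_full_fixation_makes_breed_homozygous(self, panel):
        hap = tuple(int(x) for x in np.random.default_rng(1).integers(0, 2, 21))
        swept = cg.inject_sweep(panel, cg.SweepSpec("breed01", 50, 70, hap, 1.0))
        cols = swept.sample_indices("breed01")
        expect = 2 * np.asarray(hap)
        for j in cols:
            np.testing.assert_array_equal(swept.genotypes[50:71, j], expect)

    def test_changes_confined_to_tract_and_breed(self, panel):
        hap = tuple([1] * 21)
        swept = cg.inject_sweep(panel, cg.SweepSpec("breed01", 50, 70, hap, 0.6), seed=4)
        diff = swept.genotypes != panel.genotypes
        changed_markers = np.flatnonzero(diff.any(axis=1))
        assert changed_markers.min() >= 50 and changed_markers.max() <= 70
        other = np.concatenate(
            [panel.sample_indices("breed00"), panel.sample_indices("breed02")]
        )
        assert not diff[:, other].any()

    def test_partial_fixation_frequency_by_direct_count(self, panel):
        """Tract B-allele frequency equals a brute-force count over the
        chromosome copies after replacement."""
        hap = tuple([1] * 21)
        swept = cg.inject_sweep(panel, cg.SweepSpec("breed01", 50, 70, hap, 0.5), seed=8)
        cols = swept.sample_indices("breed01")
        chrom_copies = swept.haplotypes[50:71][:, cols, :].reshape(21, -1)
        expect_freq = chrom_copies.mean(axis=1)
        b, n = swept.allele_stats("breed01")
        np.testing.assert_allclose(b[50:71] / n[50:71], expect_freq)
        # half the copies were replaced by the all-B haplotype
        assert (expect_freq >= 0.5).all()

    def test_errors(self, panel):
        with pytest.raises(KeyError):
            cg.inject_sweep(panel, cg.SweepSpec("nope", 0, 0, (1,)))
        with pytest.raises(ValueError):
            cg.inject_sweep(panel, cg.SweepSpec("breed00", 190, 210, tuple([1] * 21)))


class TestSimulateGeneFamily:
    def test_zero_branch_lengths_give_identical_sequences(self):
        truth = simulate_gene_family("((a:0.0,b:0.0):0.0,c:0.0);", 300, seed=1)
        assert truth.alignment["a"] == truth.alignment["b"] == truth.alignment["c"]

    def test_conversion_copies_donor_tract_exactly(self):
        truth = simulate_gene_family(
            "((a:0.1,b:0.1):0.05,c:0.2);",
            400,
            events=[ConversionEvent("a", "b", 100, 200)],
            seed=2,
        )
        a, b = truth.alignment["a"], truth.alignment["b"]
        assert a[100:200] == b[100:200]
        assert a != b  # divergence survives outside the tract

    def test_branch_divergence_matches_closed_form(self):
        params = TN93Params(pi=(0.3, 0.2, 0.3, 0.2), kappa_purine=5, kappa_pyrimidine=3)
        t = 0.1
        n_sites = 20_000
        truth = simulate_gene_family(
            f"(a:0.0,b:{t});", n_sites, params=params, seed=3
        )
        observed = np.mean(
            [x != y for x, y in zip(truth.alignment["a"], truth.alignment["b"])]
        )
        expected = params.expected_p_distance(t)
        tol = 4 * np.sqrt(expected * (1 - expected) / n_sites)
        assert observed == pytest.approx(expected, abs=tol)

    def test_determinism(self):
        kw = dict(events=[ConversionEvent("a", "b", 0, 50)], seed=42)
        t1 = simulate_gene_family("((a:0.1,b:0.1):0.05,c:0.2);", 200, **kw)
        t2 = simulate_gene_family("((a:0.1,b:0.1):0.05,c:0.2);", 200, **kw)
        assert t1.alignment == t2.alignment

    def test_tract_outside_alignment_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_family(
                "(a:0.1,b:0.1);", 100, events=[ConversionEvent("a", "b", 50, 150)]
            )


class TestSimulateOrthologProteins:
    def test_planted_residue_counts(self):
        truth = simulate_ortholog_proteins(
            43, 140, [(3, 13, "I")], background_sub_rate=0.05, seed=1
        )
        flags = cg.flag_rare_substitutions(
            truth.alignment, truth.alignment.names[3], max_count=2
        )
        mine = [f for f in flags if f.column == 14]  # 1-based report
        assert len(mine) == 1
        assert mine[0].query_residue == "I"
        assert mine[0].count == 1
        assert mine[0].n_total == 43

    def test_zero_entropy_background_flags_nothing(self):
        truth = simulate_ortholog_proteins(20, 50, background_sub_rate=0.0, seed=2)
        assert cg.flag_rare_substitutions(truth.alignment, "seq00") == []

    def test_plant_in_two_sequences_counts_two(self):
        truth = simulate_ortholog_proteins(
            43, 60, [(0, 7, "W"), (5, 7, "W")], seed=3
        )
        flags = cg.flag_rare_substitutions(truth.alignment, "seq00", max_count=2)
        hit = [f for f in flags if f.column == 8]
        assert hit and hit[0].count == 2

    def test_conflicting_plants_rejected(self):
        with pytest.raises(ValueError):
            simulate_ortholog_proteins(5, 10, [(0, 1, "A"), (0, 1, "C")])
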