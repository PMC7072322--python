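"""Synthetic-data generator: determinism, calibration, truth consistency."""

import dataclasses
import math

import numpy as np
import pytest

from earlygc.filters import exome_violations
from earlygc.simulate import (
    ArtifactRates,
    SimConfig,
    SimConfigError,
    expected_snv_count,
    generate_reference,
    simulate_cohort,
    simulate_msi_profiles,
)


class TestGenerateReference:
    def test_no_genes(self):
        config = SimConfig(seed=1, n_genes=0, n_samples=0,
                           chromosome_length=20_000)
        ref, genes = generate_reference(config)
        assert genes == [] and len(ref.chroms) == config.n_chromosomes

    def test_deterministic(self):
        config = SimConfig(seed=1, n_samples=0, chromosome_length=50_000,
                           n_genes=8, gene_cds_length=300)
        ref_a, genes_a = generate_reference(config)
        ref_b, genes_b = generate_reference(config)
        assert genes_a == genes_b
        assert all(ref_a.seq(c) == ref_b.seq(c) for c in ref_a.chroms)

    def test_cpg_density_realized(self):
        config = SimConfig(seed=7, n_chromosomes=1, chromosome_length=10**6,
                           cpg_density=0.02, n_samples=0)
        ref, _ = generate_reference(config)
        seq = ref.seq("chr1")
        cg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert 0.016 <= cg / (len(seq) - 1) <= 0.024

    def test_alphabet_and_gene_bounds(self):
        config = SimConfig(seed=3, n_samples=0, chromosome_length=30_000,
                           n_genes=6, gene_cds_length=300)
        ref, genes = generate_reference(config)
        assert set(ref.seq("chr1")) <= set("ACGT")
        for gene in genes:
            gene.validate_against(ref)
            assert gene.coding_length == 300
        # non-overlap within each chromosome
        by_chrom = {}
        for gene in genes:
            by_chrom.setdefault(gene.chrom, []).extend(gene.intervals)
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_capacity_error_names_limit(self):
        config = SimConfig(seed=1, n_samples=0, chromosome_length=5_000,
                           n_chromosomes=1, n_genes=50, gene_cds_length=300)
        with pytest.raises(SimConfigError, match="cannot place"):
            generate_reference(config)

    def test_invalid_config_rejected(self):
        with pytest.raises(SimConfigError, match="multiple of 3"):
            SimConfig(gene_cds_length=100).validate()
        with pytest.raises(SimConfigError, match="rates"):
            SimConfig(rate_cpg=-1e-6).validate()


class TestSimulateCohort:
    def test_zero_rates_give_empty_callsets(self):
        config = SimConfig(
            seed=2, n_samples=4, chromosome_length=50_000, n_genes=4,
            gene_cds_length=300, rate_cpg=0, rate_noncpg=0, rate_indel=0,
            artifact_rates=ArtifactRates(0, 0, 0, 0),
        )
        ref, genes = generate_reference(config)
        cohort = simulate_cohort(ref, genes, config)
        assert all(not calls for calls in cohort.calls.values())
        assert cohort.truth.empty

    def test_deterministic(self, small_config, small_reference):
        ref, genes = small_reference
        a = simulate_cohort(ref, genes, small_config)
        b = simulate_cohort(ref, genes, small_config)
        assert a.calls == b.calls
        assert a.truth.equals(b.truth)

    def test_truth_table_consistency(self, small_cohort):
        truth = small_cohort.truth
        emitted = {
            (c.sample_id, c.chrom, c.pos, c.ref, c.alt)
            for calls in small_cohort.calls.values()
            for c in calls
        }
        in_truth = {
            (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
            for r in truth.itertuples()
        }
        assert emitted == in_truth
        labels = set(truth.label)
        assert labels <= {"somatic", "EX1", "EX3", "EX4", "EX5"}

    def test_true_events_pass_and_artifacts_fail_as_labelled(self, small_cohort):
        truth_label = {
            (r.sample_id, r.chrom, r.pos, r.alt): r.label
            for r in small_cohort.truth.itertuples()
        }
        for calls in small_cohort.calls.values():
            for call in calls:
                label = truth_label[(call.sample_id, call.chrom, call.pos, call.alt)]
                codes = exome_violations(call)
                if label == "somatic":
                    assert codes == ()
                else:
                    assert codes == (label,)

    def test_single_record_per_site(self, small_cohort):
        for sample, calls in small_cohort.calls.items():
            sites = [(c.chrom, c.pos) for c in calls]
            assert len(sites) == len(set(sites))

    def test_snv_count_near_analytic_mean(self):
        """Realized SNV counts track the analytic Poisson mean (single draw,
        5 sigma guard; the tight multi-replicate envelope is checked in the
        acceptance suite)."""
        config = SimConfig(
            seed=9, n_samples=10, n_chromosomes=1, chromosome_length=500_000,
            n_genes=0, rate_indel=0, artifact_rates=ArtifactRates(0, 0, 0, 0),
        )
        ref, genes = generate_reference(config)
        cohort = simulate_cohort(ref, genes, config)
        mean = expected_snv_count(ref, config)
        observed = sum(len(c) for c in cohort.calls.values())
        assert abs(observed - mean) <= 5 * math.sqrt(mean)

    def test_unknown_driver_gene_rejected(self, small_reference, small_config):
        ref, genes = small_reference
        config = dataclasses.replace(small_config, driver_genes=(("NOPE", 10.0),))
        with pytest.raises(SimConfigError, match="NOPE"):
            simulate_cohort(ref, genes, config)


class TestMSIProfiles:
    def test_all_stable_and_all_unstable(self):
        stable = simulate_msi_profiles(20, [0.0] * 5, seed=1)
        assert all(r.msi_class == "MSS" and sum(r.flags) == 0 for r in stable)
        unstable = simulate_msi_profiles(20, [1.0] * 5, seed=1)
        assert all(r.msi_class == "MSI-H" and sum(r.flags) == 5 for r in unstable)

    def test_marker_fractions_near_half(self):
        results = simulate_msi_profiles(1000, [0.5] * 5, seed=11)
        flags = np.array([r.flags for r in results], dtype=float)
        se = math.sqrt(0.25 / 1000)
        assert np.all(np.abs(flags.mean(axis=0) - 0.5) <= 3 * se)

    def test_bad_probability_rejected(self):
        with pytest.raises(SimConfigError, match="probabilities"):
            simulate_msi_profiles(5, [0.5, 0.5, 0.5, 0.5, 1.5], seed=0)
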