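"""Background rates, site counting, per-gene exact test, BH adjustment."""

import random

import numpy as np
import pytest

from earlygc.annotate import (
    AnnotatedVariant,
    GeneModel,
    ReferenceGenome,
    annotate_cohort,
)
from earlygc.exactcheck import bh_stepup, fisher_exact_enum
from earlygc.filters import filter_exome
from earlygc.simulate import SimConfig, generate_reference, simulate_cohort
from earlygc.smg import (
    SMGError,
    adjust_bh,
    count_gene_sites,
    estimate_background_rates,
    expected_mutations,
    GeneOpportunity,
    run_smg,
)
from earlygc.smg import test_gene as gene_enrichment_p

from conftest import make_call


def noncoding_snv(chrom, pos0, ref_base, alt_base, is_cpg):
    call = make_call(chrom=chrom, pos=pos0 + 1, ref=ref_base, alt=alt_base)
    return AnnotatedVariant(call=call, gene_ids=(), effect="noncoding",
                            is_cpg=is_cpg, subclass6="C>T")


class TestCountGeneSites:
    def test_glycine_codon(self):
        """GGG: the three third-position changes are synonymous, the six
        first/second-position changes are not -> 1.0 syn, 2.0 nonsyn sites."""
        ref = ReferenceGenome({"c": "TTGGGTT"})
        gene = GeneModel(gene_id="G", chrom="c", strand="+", intervals=((2, 5),))
        opp = count_gene_sites(gene, ref)
        assert opp.syn_sites == pytest.approx(1.0)
        assert opp.nonsyn_sites == pytest.approx(2.0)

    def test_start_codon(self):
        ref = ReferenceGenome({"c": "TTATGTT"})
        gene = GeneModel(gene_id="G", chrom="c", strand="+", intervals=((2, 5),))
        opp = count_gene_sites(gene, ref)
        assert opp.syn_sites == 0.0
        assert opp.nonsyn_sites == pytest.approx(3.0)

    def test_conservation_identity_exact(self, small_reference):
        """syn + nonsyn fractional sites equal coding length exactly, in
        integer thirds, for every simulated gene."""
        ref, genes = small_reference
        for gene in genes:
            opp = count_gene_sites(gene, ref)
            thirds = (opp.syn_cpg_thirds + opp.syn_noncpg_thirds
                      + opp.nonsyn_cpg_thirds + opp.nonsyn_noncpg_thirds)
            assert thirds == 3 * gene.coding_length


class TestBackgroundRates:
    def test_no_mutations_all_zero(self, small_reference):
        ref, genes = small_reference
        rates = estimate_background_rates([], ref, genes, n_samples=5)
        assert rates.pooled_cpg == rates.pooled_noncpg == rates.pooled_indel == 0.0

    def test_exact_rate_arithmetic(self):
        """200,000 non-coding CpG sites, 10 samples, 40 CpG point mutations
        -> rate 2.0e-5 per site per sample."""
        ref = ReferenceGenome({"c": "CG" * 100_000})
        variants = [
            noncoding_snv("c", 2 * i, "C", "T", is_cpg=True) for i in range(40)
        ]
        rates = estimate_background_rates(variants, ref, [], n_samples=10)
        assert rates.pooled_cpg == pytest.approx(2.0e-5)
        assert rates.pooled_noncpg == 0.0  # zero eligible sites, no error

    def test_pooled_equals_totals_ratio(self, small_reference, small_cohort):
        ref, genes = small_reference
        kept = [c for calls in small_cohort.calls.values()
                for c in filter_exome(calls).kept]
        annotated = [v for v in annotate_cohort(kept, genes, ref)
                     if v.effect == "noncoding"]
        rates = estimate_background_rates(annotated, ref, genes, n_samples=6)
        bins = rates.bins
        assert rates.pooled_cpg == pytest.approx(
            bins.cpg_mutations.sum() / (bins.cpg_sites.sum() * 6)
        )

    def test_rejects_coding_variants(self, toy_pair):
        ref, fwd, _ = toy_pair
        call = make_call(chrom="chrF", pos=11, ref="G", alt="A")
        coding = AnnotatedVariant(call=call, gene_ids=("FWD",),
                                  effect="nonsynonymous")
        with pytest.raises(SMGError, match="non-coding"):
            estimate_background_rates([coding], ref, [fwd], n_samples=1)


class TestExpectedMutations:
    def test_zero_rates(self):
        opp = GeneOpportunity("G", 300, 2100, 900, 5700, 3000)
        assert expected_mutations(opp, (0.0, 0.0, 0.0), 20) == 0.0

    def test_linear_arithmetic(self):
        # 300 CpG-nonsyn sites, 600 non-CpG-nonsyn sites, 1000 bp gene
        opp = GeneOpportunity(
            gene_id="G",
            syn_cpg_thirds=0,
            syn_noncpg_thirds=3 * 1000 - 900 - 1800,
            nonsyn_cpg_thirds=900,
            nonsyn_noncpg_thirds=1800,
            coding_length=1000,
        )
        e = expected_mutations(opp, (2e-6, 1e-6, 0.0), 20)
        assert e == pytest.approx(0.024)

    def test_conservation_enforced(self):
        with pytest.raises(SMGError, match="conserve"):
            GeneOpportunity("G", 1, 1, 1, 1, 1000)


class TestFisherAndBH:
    def test_zero_observed_gives_p_one(self):
        assert gene_enrichment_p(0, 1000, 50, 100_000) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        p = gene_enrichment_p(5, 1000, 100, 1_000_000)
        oracle = fisher_exact_enum([[5, 995], [100, 999_900]], "greater")
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_monotone_in_observed(self):
        """Moving successes into the gene at fixed margins never raises p."""
        previous = 1.1
        for obs in (1, 2, 4, 8):
            p = gene_enrichment_p(obs, 1000, 100 - obs, 1_000_000)
            assert p <= previous + 1e-12
            previous = p

    def test_observed_exceeding_opportunity_is_a_bug(self):
        with pytest.raises(SMGError, match="opportunity"):
            gene_enrichment_p(10, 5, 0, 100)

    def test_bh_examples(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)
        with pytest.raises(SMGError):
            adjust_bh([0.5, 1.5])

    def test_bh_matches_stepup_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(adjust_bh(p), bh_stepup(p), atol=1e-12)
            assert np.all(adjust_bh(p) >= p - 1e-12)


@pytest.fixture(scope="module")
def smg_inputs():
    config = SimConfig(seed=21, n_samples=8, n_chromosomes=1,
                       chromosome_length=400_000, n_genes=20,
                       gene_cds_length=600)
    ref, genes = generate_reference(config)
    cohort = simulate_cohort(ref, genes, config)
    kept = [c for calls in cohort.calls.values()
            for c in filter_exome(calls).kept]
    annotated = annotate_cohort(kept, genes, ref)
    return config, ref, genes, annotated


class TestRunSMG:
    def test_refuses_without_noncoding_background(self, toy_pair):
        ref, fwd, _ = toy_pair
        call = make_call(chrom="chrF", pos=6, ref="A", alt="G")
        coding_only = [AnnotatedVariant(call=call, gene_ids=("FWD",),
                                        effect="nonsynonymous")]
        with pytest.raises(SMGError, match="unidentifiable"):
            run_smg(coding_only, ref, [fwd], n_samples=1)

    def test_results_complete_and_ordered(self, smg_inputs):
        config, ref, genes, annotated = smg_inputs
        results, rates = run_smg(annotated, ref, genes, config.n_samples)
        assert {r.gene_id for r in results} == {g.gene_id for g in genes}
        qs = [r.q_value for r in results]
        assert qs == sorted(qs)
        assert all(0 <= r.p_value <= r.q_value <= 1 for r in results)
        assert rates.pooled_noncpg > 0

    def test_gene_order_invariance(self, smg_inputs):
        config, ref, genes, annotated = smg_inputs
        results_a, _ = run_smg(annotated, ref, genes, config.n_samples)
        shuffled = list(genes)
        random.Random(0).shuffle(shuffled)
        results_b, _ = run_smg(annotated, ref, shuffled, config.n_samples)
        p_a = sorted(r.p_value for r in results_a)
        p_b = sorted(r.p_value for r in results_b)
        assert p_a == pytest.approx(p_b)

    def test_spiked_driver_ranks_first(self):
        config = SimConfig(seed=33, n_samples=20, n_chromosomes=1,
                           chromosome_length=400_000, n_genes=20,
                           gene_cds_length=600,
                           driver_genes=(("G0007", 80.0),))
        ref, genes = generate_reference(config)
        cohort = simulate_cohort(ref, genes, config)
        kept = [c for calls in cohort.calls.values()
                for c in filter_exome(calls).kept]
        annotated = annotate_cohort(kept, genes, ref)
        results, _ = run_smg(annotated, ref, genes, config.n_samples)
        assert results[0].gene_id == "G0007"
        assert results[0].observed > results[0].expected
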