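"""Calibration and validation experiments on the synthetic cohort.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns summary numbers: filter fidelity against the
truth table, background-rate recovery against the generator's rates,
false-discovery control and spiked-driver power for the SMG procedure,
spectrum composition under CpG-deamination bias, and agreement of the
exact-test/BH implementations with the brute-force references. They back
both the acceptance test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .annotate import annotate_cohort, spectrum_summary
from .cohort import TwoByTwo, fisher_2x2
from .exactcheck import bh_stepup, fisher_exact_enum
from .filters import filter_exome
from .msi import classify_msi
from .simulate import SimConfig, generate_reference, simulate_cohort
from .smg import adjust_bh, count_gene_sites, run_smg


def _child_seed(seed: int, label: int) -> int:
    return int(np.random.SeedSequence([seed, label]).generate_state(1)[0] % (2**31))


def filter_fidelity(seed: int, config: SimConfig | None = None) -> dict:
    """Exome-filter sensitivity on truth-table events and artifact handling.

    Returns percentages of true somatic events kept and of injected
    artifacts rejected under exactly their labelled criterion.
    """
    config = config or SimConfig(seed=seed, n_samples=10)
    ref, genes = generate_reference(config)
    cohort = simulate_cohort(ref, genes, config)
    truth = cohort.truth
    labels = {
        (r.sample_id, r.chrom, r.pos, r.alt): r.label for r in truth.itertuples()
    }
    n_true = n_true_kept = n_art = n_art_exact = 0
    for sample_calls in cohort.calls.values():
        report = filter_exome(sample_calls)
        for call in report.kept:
            if labels[(call.sample_id, call.chrom, call.pos, call.alt)] == "somatic":
                n_true_kept += 1
        for call, codes in report.rejected:
            label = labels[(call.sample_id, call.chrom, call.pos, call.alt)]
            if label != "somatic" and codes == (label,):
                n_art_exact += 1
    n_true = int((truth.label == "somatic").sum())
    n_art = int((truth.label != "somatic").sum())
    return dict(
        n_true=n_true,
        n_artifacts=n_art,
        sensitivity_pct=100.0 * n_true_kept / n_true if n_true else float("nan"),
        artifact_exact_pct=100.0 * n_art_exact / n_art if n_art else float("nan"),
    )


def spectrum_modal(seed: int, config: SimConfig | None = None) -> dict:
    """Modal substitution class under the CpG-deamination-biased generator."""
    config = config or SimConfig(seed=seed, n_samples=10)
    ref, genes = generate_reference(config)
    cohort = simulate_cohort(ref, genes, config)
    kept = [c for sample in cohort.calls.values() for c in filter_exome(sample).kept]
    annotated = annotate_cohort(kept, genes, ref)
    spectrum = spectrum_summary(annotated)
    total = spectrum.n_snvs
    return dict(
        modal_class=spectrum.modal_class,
        modal_share_pct=100.0 * spectrum.modal_count / total if total else float("nan"),
        n_snvs=total,
    )


def rate_recovery(
    seed: int, n_reps: int = 100, config: SimConfig | None = None
) -> dict:
    """Pooled background-rate recovery aggregated over replicate cohorts.

    One reference genome is generated; ``n_reps`` cohorts are drawn from it
    and their non-coding mutations pooled into the rate estimator. Reports,
    per category, the aggregate mutation count, its analytic Poisson mean,
    the |z| score, and the relative error of the pooled rate estimate.
    """
    config = config or SimConfig(seed=seed, n_samples=10, n_chromosomes=1,
                                 chromosome_length=1_000_000, n_genes=20)
    ref, genes = generate_reference(config)
    from .smg import _coding_mask  # shared mask logic

    site_counts = {"cpg": 0, "noncpg": 0, "indel_bp": 0}
    for chrom in ref.chroms:
        noncoding = ~_coding_mask(ref, genes, chrom)
        cpg = ref.cpg_mask(chrom)
        site_counts["cpg"] += int((noncoding & cpg).sum())
        site_counts["noncpg"] += int((noncoding & ~cpg).sum())
        site_counts["indel_bp"] += int(noncoding.sum())

    observed = {"cpg": 0, "noncpg": 0, "indel": 0}
    for rep in range(n_reps):
        rep_config = dataclasses.replace(config, seed=_child_seed(seed, rep))
        cohort = simulate_cohort(ref, genes, rep_config)
        kept = [c for sample in cohort.calls.values()
                for c in filter_exome(sample).kept]
        annotated = annotate_cohort(kept, genes, ref)
        for v in annotated:
            if v.effect != "noncoding":
                continue
            if v.call.var_class != "SNV":
                observed["indel"] += 1
            elif v.is_cpg:
                observed["cpg"] += 1
            else:
                observed["noncpg"] += 1

    draws = n_reps * config.n_samples
    expected = {
        "cpg": site_counts["cpg"] * config.rate_cpg * draws,
        "noncpg": site_counts["noncpg"] * config.rate_noncpg * draws,
        "indel": site_counts["indel_bp"] * config.rate_indel * draws,
    }
    out = {}
    for cat in ("cpg", "noncpg", "indel"):
        exp = expected[cat]
        obs = observed[cat]
        z = (obs - exp) / math.sqrt(exp) if exp > 0 else 0.0
        out[cat] = dict(
            observed=obs, expected=exp, z=z,
            rel_err_pct=100.0 * abs(obs - exp) / exp if exp > 0 else 0.0,
        )
    out["max_abs_z"] = max(abs(out[c]["z"]) for c in ("cpg", "noncpg", "indel"))
    return out


def _smg_panel_config(seed: int, n_samples: int, n_genes: int,
                      driver: tuple[str, float] | None) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_samples=n_samples,
        n_chromosomes=2,
        chromosome_length=1_100_000,
        n_genes=n_genes,
        gene_cds_length=999,
        driver_genes=(driver,) if driver else (),
    )


def smg_replicates(
    seed: int,
    n_reps: int,
    n_samples: int,
    n_genes: int = 200,
    driver: tuple[str, float] | None = None,
    q_threshold: float = 0.05,
) -> dict:
    """Replicate SMG runs on cohorts drawn from one simulated genome.

    Without a driver, reports the fraction of replicates with zero genes at
    q < threshold (false-discovery control). With a spiked driver, reports
    the fraction of replicates in which the driver attains the smallest
    q-value and q < threshold (power).
    """
    base = _smg_panel_config(seed, n_samples, n_genes, driver)
    ref, genes = generate_reference(base)
    opportunities = {g.gene_id: count_gene_sites(g, ref) for g in genes}
    clean = detected = 0
    for rep in range(n_reps):
        rep_config = dataclasses.replace(base, seed=_child_seed(seed, 1000 + rep))
        cohort = simulate_cohort(ref, genes, rep_config)
        kept = [c for sample in cohort.calls.values()
                for c in filter_exome(sample).kept]
        annotated = annotate_cohort(kept, genes, ref)
        results, _ = run_smg(
            annotated, ref, genes, n_samples, opportunities=opportunities
        )
        hits = [r for r in results if r.q_value < q_threshold]
        if not hits:
            clean += 1
        if driver is not None:
            best_q = results[0].q_value
            driver_result = next(r for r in results if r.gene_id == driver[0])
            if driver_result.q_value < q_threshold and driver_result.q_value == best_q:
                detected += 1
    out = dict(n_reps=n_reps, clean_pct=100.0 * clean / n_reps)
    if driver is not None:
        out["detected_pct"] = 100.0 * detected / n_reps
    return out


def fisher_vs_enumeration(
    seed: int, n_tables: int = 1000, max_margin: int = 200
) -> dict:
    """Max |difference| between the Fisher p and brute-force enumeration.

    Random 2x2 tables with all cells <= max_margin/2 (so margins <=
    max_margin), compared for two-sided, greater, and less alternatives.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, max_margin // 2 + 1, size=4))
        for alternative in ("two-sided", "greater", "less"):
            p_pkg = fisher_2x2(TwoByTwo(a, b, c, d), alternative=alternative)
            p_ref = fisher_exact_enum([[a, b], [c, d]], alternative=alternative)
            max_diff = max(max_diff, abs(p_pkg - p_ref))
    return dict(n_tables=n_tables, max_abs_diff=max_diff)


def bh_vs_formula(seed: int, n_vectors: int = 200, max_len: int = 50) -> dict:
    """Max |difference| between BH q-values and the direct step-up formula."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.random(m)
        max_diff = max(max_diff, float(np.max(np.abs(adjust_bh(p) - bh_stepup(p)))))
    return dict(n_vectors=n_vectors, max_abs_diff=max_diff)


def msi_oracle_agreement() -> dict:
    """Agreement of the Bethesda classifier with the 32-case enumeration."""
    agree = total = 0
    for bits in range(32):
        flags = tuple(bool(bits >> i & 1) for i in range(5))
        k = sum(flags)
        expected = "MSS" if k == 0 else ("MSI-H" if k / 5 > 0.30 else "MSI-L")
        total += 1
        agree += classify_msi(flags) == expected
    return dict(n_cases=total, agreement_pct=100.0 * agree / total)
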