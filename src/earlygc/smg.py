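"""Significantly-mutated-gene (SMG) detection under a CpG-aware background.

The background point-mutation rate is estimated from *non-coding* mutations
only, separately for CpG and non-CpG sites (CpG sites are hypermutable via
spontaneous deamination), plus an indel rate per non-coding bp, in 1-Mb
genomic bins with a pooled genome-wide fallback for sparse bins. Each
gene's mutational opportunity is obtained by fractional (Nei–Gojobori
style) site counting: every coding position contributes 1/3 "site" per
possible substitution, classified synonymous/nonsynonymous by codon effect
and assigned to the position's CpG category, so synonymous + nonsynonymous
sites equal the coding length exactly.

The per-gene test compares the observed cohort count of protein-altering
mutations (nonsynonymous SNVs + coding indels) against the background via a
one-sided (enrichment) Fisher exact test on a 2x2 table of rate-weighted
*effective opportunities*: heterogeneous site categories are converted to
effective trials by scaling with (category rate / non-CpG point rate), so a
CpG site counts for more trials in proportion to its elevated rate. This
exact-test construction is this package's reconstruction of "probability of
the observed protein-altering count given gene length and background rate";
see the methods note. P-values are adjusted with Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import CODON_AA, AnnotatedVariant, GeneModel, ReferenceGenome

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_MIN_BIN_MUTATIONS = 50
DEFAULT_Q_THRESHOLD = 0.05


class SMGError(ValueError):
    """Raised when the SMG procedure cannot run (e.g. no background data)."""


# ---------------------------------------------------------------------------
# background rates


@dataclass(frozen=True)
class BackgroundRates:
    """Per-bin and pooled background mutation rates.

    ``bins`` has one row per (chrom, bin) with eligible non-coding site
    counts, non-coding mutation counts, per-category rates (mutations per
    eligible site per sample), and a ``low_count`` flag marking bins that
    fall back to the pooled rates.
    """

    bins: pd.DataFrame
    pooled_cpg: float
    pooled_noncpg: float
    pooled_indel: float
    n_samples: int
    bin_size: int

    def rates_for_gene(self, gene: GeneModel) -> tuple[float, float, float]:
        """Length-weighted average of the rates of the bins a gene overlaps.

        Bins flagged ``low_count`` (or absent) contribute the pooled rates.
        """
        weights: dict[tuple[str, int], int] = {}
        for start, end in gene.intervals:
            b = start // self.bin_size
            while b * self.bin_size < end:
                lo = max(start, b * self.bin_size)
                hi = min(end, (b + 1) * self.bin_size)
                key = (gene.chrom, b)
                weights[key] = weights.get(key, 0) + (hi - lo)
                b += 1
        total = sum(weights.values())
        lookup = self.bins.set_index(["chrom", "bin"]) if len(self.bins) else None
        rates = np.zeros(3)
        for (chrom, b), w in weights.items():
            if lookup is not None and (chrom, b) in lookup.index:
                row = lookup.loc[(chrom, b)]
                if not row["low_count"]:
                    rates += (w / total) * np.array(
                        [row["rate_cpg"], row["rate_noncpg"], row["rate_indel"]]
                    )
                    continue
            rates += (w / total) * np.array(
                [self.pooled_cpg, self.pooled_noncpg, self.pooled_indel]
            )
        return float(rates[0]), float(rates[1]), float(rates[2])


def _coding_mask(ref: ReferenceGenome, genes: Sequence[GeneModel], chrom: str) -> np.ndarray:
    mask = np.zeros(ref.length(chrom), dtype=bool)
    for gene in genes:
        if gene.chrom != chrom:
            continue
        for start, end in gene.intervals:
            mask[start:end] = True
    return mask


def estimate_background_rates(
    noncoding_variants: Iterable[AnnotatedVariant],
    ref: ReferenceGenome,
    genes: Sequence[GeneModel],
    n_samples: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_bin_mutations: int = DEFAULT_MIN_BIN_MUTATIONS,
) -> BackgroundRates:
    """Estimate CpG / non-CpG point and indel rates from non-coding events.

    Rates are mutations divided by (eligible non-coding sites x n_samples).
    A category with zero eligible sites yields rate 0 with a logged warning,
    never a division error. Bins with fewer than ``min_bin_mutations``
    non-coding mutations are flagged to fall back to the pooled rates.
    """
    if n_samples < 1:
        raise SMGError("n_samples must be >= 1")
    variants = list(noncoding_variants)
    for v in variants:
        if v.effect != "noncoding":
            raise SMGError(
                f"background estimation requires non-coding variants only; got "
                f"effect {v.effect!r} at {v.call.chrom}:{v.call.pos}"
            )

    rows = []
    for chrom in ref.chroms:
        length = ref.length(chrom)
        noncoding = ~_coding_mask(ref, genes, chrom)
        cpg = ref.cpg_mask(chrom)
        positions = np.arange(length)
        bin_ids = positions // bin_size
        n_bins = int(bin_ids[-1]) + 1 if length else 0
        cpg_sites = np.bincount(bin_ids, weights=(noncoding & cpg), minlength=n_bins)
        noncpg_sites = np.bincount(bin_ids, weights=(noncoding & ~cpg), minlength=n_bins)
        nc_bp = np.bincount(bin_ids, weights=noncoding, minlength=n_bins)
        for b in range(n_bins):
            rows.append(
                dict(chrom=chrom, bin=b, cpg_sites=int(cpg_sites[b]),
                     noncpg_sites=int(noncpg_sites[b]), noncoding_bp=int(nc_bp[b]),
                     cpg_mutations=0, noncpg_mutations=0, indel_mutations=0)
            )
    bins = pd.DataFrame(rows)
    key = {(r["chrom"], r["bin"]): i for i, r in bins.iterrows()} if len(bins) else {}

    for v in variants:
        b = (v.call.pos - 1) // bin_size
        i = key[(v.call.chrom, b)]
        if v.call.var_class != "SNV":
            bins.at[i, "indel_mutations"] += 1
        elif v.is_cpg:
            bins.at[i, "cpg_mutations"] += 1
        else:
            bins.at[i, "noncpg_mutations"] += 1

    def _rate(muts, sites, label):
        if sites == 0:
            if muts:
                logger.warning("%s: %d mutations but zero eligible sites; rate set to 0",
                               label, muts)
            return 0.0
        return muts / (sites * n_samples)

    if len(bins):
        bins["rate_cpg"] = [
            _rate(m, s, f"{c}:bin{b} CpG")
            for m, s, c, b in zip(bins.cpg_mutations, bins.cpg_sites, bins.chrom, bins.bin)
        ]
        bins["rate_noncpg"] = [
            _rate(m, s, f"{c}:bin{b} non-CpG")
            for m, s, c, b in zip(bins.noncpg_mutations, bins.noncpg_sites, bins.chrom, bins.bin)
        ]
        bins["rate_indel"] = [
            _rate(m, s, f"{c}:bin{b} indel")
            for m, s, c, b in zip(bins.indel_mutations, bins.noncoding_bp, bins.chrom, bins.bin)
        ]
        total_muts = bins.cpg_mutations + bins.noncpg_mutations + bins.indel_mutations
        bins["low_count"] = total_muts < min_bin_mutations
    else:
        for col in ("rate_cpg", "rate_noncpg", "rate_indel", "low_count"):
            bins[col] = []

    pooled_cpg = _rate(int(bins.cpg_mutations.sum()), int(bins.cpg_sites.sum()), "pooled CpG") if len(bins) else 0.0
    pooled_noncpg = _rate(int(bins.noncpg_mutations.sum()), int(bins.noncpg_sites.sum()), "pooled non-CpG") if len(bins) else 0.0
    pooled_indel = _rate(int(bins.indel_mutations.sum()), int(bins.noncoding_bp.sum()), "pooled indel") if len(bins) else 0.0

    return BackgroundRates(
        bins=bins,
        pooled_cpg=pooled_cpg,
        pooled_noncpg=pooled_noncpg,
        pooled_indel=pooled_indel,
        n_samples=n_samples,
        bin_size=bin_size,
    )


# ---------------------------------------------------------------------------
# gene opportunities (fractional site counting)


@dataclass(frozen=True)
class GeneOpportunity:
    """Fractional synonymous/nonsynonymous sites of a gene, split by CpG.

    Counts are stored in integer *thirds* (each of the 9 substitutions per
    codon position contributes one third), so the conservation identity
    synonymous + nonsynonymous == coding length holds exactly.
    """

    gene_id: str
    syn_cpg_thirds: int
    syn_noncpg_thirds: int
    nonsyn_cpg_thirds: int
    nonsyn_noncpg_thirds: int
    coding_length: int

    def __post_init__(self) -> None:
        total = (self.syn_cpg_thirds + self.syn_noncpg_thirds
                 + self.nonsyn_cpg_thirds + self.nonsyn_noncpg_thirds)
        if total != 3 * self.coding_length:
            raise SMGError(
                f"{self.gene_id}: site counts ({total} thirds) do not conserve "
                f"coding length {self.coding_length}"
            )

    @property
    def syn_cpg(self) -> float:
        return self.syn_cpg_thirds / 3.0

    @property
    def syn_noncpg(self) -> float:
        return self.syn_noncpg_thirds / 3.0

    @property
    def nonsyn_cpg(self) -> float:
        return self.nonsyn_cpg_thirds / 3.0

    @property
    def nonsyn_noncpg(self) -> float:
        return self.nonsyn_noncpg_thirds / 3.0

    @property
    def syn_sites(self) -> float:
        return (self.syn_cpg_thirds + self.syn_noncpg_thirds) / 3.0

    @property
    def nonsyn_sites(self) -> float:
        return (self.nonsyn_cpg_thirds + self.nonsyn_noncpg_thirds) / 3.0


def count_gene_sites(gene: GeneModel, ref: ReferenceGenome) -> GeneOpportunity:
    """Fractional site counts for one gene.

    Each coding position contributes 1/3 site per possible substitution,
    classified by codon effect (standard code, stop as a symbol) and by the
    position's CpG status on the genome.
    """
    gene.validate_against(ref)
    cds = gene.cds_sequence(ref)
    gpos = gene.genomic_positions()
    cpg_mask = ref.cpg_mask(gene.chrom)
    counts = {(s, c): 0 for s in ("syn", "nonsyn") for c in ("cpg", "noncpg")}
    for i, pos0 in enumerate(gpos):
        codon_start = 3 * (i // 3)
        codon = cds[codon_start : codon_start + 3]
        within = i % 3
        cat = "cpg" if cpg_mask[pos0] else "noncpg"
        aa = CODON_AA[codon]
        for alt in "ACGT":
            if alt == codon[within]:
                continue
            mutant = codon[:within] + alt + codon[within + 1 :]
            kind = "syn" if CODON_AA[mutant] == aa else "nonsyn"
            counts[(kind, cat)] += 1
    return GeneOpportunity(
        gene_id=gene.gene_id,
        syn_cpg_thirds=counts[("syn", "cpg")],
        syn_noncpg_thirds=counts[("syn", "noncpg")],
        nonsyn_cpg_thirds=counts[("nonsyn", "cpg")],
        nonsyn_noncpg_thirds=counts[("nonsyn", "noncpg")],
        coding_length=gene.coding_length,
    )


def expected_mutations(
    opp: GeneOpportunity,
    rates: tuple[float, float, float],
    n_samples: int,
) -> float:
    """Expected protein-altering count: nonsynonymous point opportunities at
    their category rates plus coding length times the indel rate, times the
    number of samples. ``rates`` is (cpg, noncpg, indel)."""
    rate_cpg, rate_noncpg, rate_indel = rates
    return n_samples * (
        rate_cpg * opp.nonsyn_cpg
        + rate_noncpg * opp.nonsyn_noncpg
        + rate_indel * opp.coding_length
    )


def effective_opportunity(
    opp: GeneOpportunity,
    rates: tuple[float, float, float],
    n_samples: int,
) -> int:
    """Rate-weighted effective trial count for the 2x2 exact test.

    Site counts are scaled by (category rate / non-CpG point rate) — the
    non-CpG rate is the reference category — and the indel opportunity is
    coding length scaled by (indel rate / non-CpG rate), rounded to the
    nearest integer after multiplying by the sample count. When the
    reference rate is zero all weights degenerate to 1 (pure length).
    """
    rate_cpg, rate_noncpg, rate_indel = rates
    if rate_noncpg > 0:
        w_cpg = rate_cpg / rate_noncpg
        w_indel = rate_indel / rate_noncpg
    else:
        w_cpg, w_indel = 1.0, 0.0
    trials = n_samples * (
        opp.nonsyn_noncpg + w_cpg * opp.nonsyn_cpg + w_indel * opp.coding_length
    )
    return int(round(trials))


def test_gene(
    observed_g: int,
    opportunity_g: int,
    observed_rest: int,
    opportunity_rest: int,
) -> float:
    """One-sided (enrichment) Fisher exact p for one gene against the rest.

    The 2x2 table is [[obs_g, opp_g - obs_g], [obs_rest, opp_rest - obs_rest]]
    with opportunities as effective trial counts.
    """
    for name, obs, opp in (
        ("gene", observed_g, opportunity_g),
        ("rest", observed_rest, opportunity_rest),
    ):
        if obs < 0 or opp < 0:
            raise SMGError(f"negative counts for {name}")
        if obs > opp:
            raise SMGError(
                f"observed ({obs}) exceeds effective opportunity ({opp}) for "
                f"{name}: opportunity construction bug"
            )
    table = [[observed_g, opportunity_g - observed_g],
             [observed_rest, opportunity_rest - observed_rest]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise SMGError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# end-to-end procedure


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    observed: int
    expected: float
    opportunity: int
    p_value: float
    q_value: float


def run_smg(
    variants: Iterable[AnnotatedVariant],
    ref: ReferenceGenome,
    genes: Sequence[GeneModel],
    n_samples: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_bin_mutations: int = DEFAULT_MIN_BIN_MUTATIONS,
    opportunities: Mapping[str, GeneOpportunity] | None = None,
) -> tuple[list[GeneTestResult], BackgroundRates]:
    """Full SMG procedure on a filtered, annotated cohort.

    Splits the cohort into non-coding events (rate estimation) and per-gene
    protein-altering counts, computes per-gene expectations and one-sided
    Fisher p-values on effective opportunities, adjusts with BH, and returns
    results sorted by (q, p, gene id) plus the background-rate estimates.
    Precomputed ``opportunities`` may be supplied to skip site counting.

    Raises :class:`SMGError` when the cohort contains no non-coding
    mutations at all (the background would be unidentifiable).
    """
    variants = list(variants)
    noncoding = [v for v in variants if v.effect == "noncoding"]
    if not noncoding:
        raise SMGError(
            "no non-coding mutations in the cohort: background mutation rate "
            "is unidentifiable; cannot test genes"
        )
    rates = estimate_background_rates(
        noncoding, ref, genes, n_samples, bin_size, min_bin_mutations
    )

    observed: dict[str, int] = {g.gene_id: 0 for g in genes}
    for v in variants:
        if v.protein_altering and v.gene_id is not None:
            observed[v.gene_id] += 1  # counted once, on the primary gene

    if opportunities is None:
        opportunities = {g.gene_id: count_gene_sites(g, ref) for g in genes}

    per_gene = []
    for gene in genes:
        gene_rates = rates.rates_for_gene(gene)
        opp = opportunities[gene.gene_id]
        eff = effective_opportunity(opp, gene_rates, n_samples)
        exp = expected_mutations(opp, gene_rates, n_samples)
        per_gene.append((gene.gene_id, observed[gene.gene_id], exp, eff))

    total_obs = sum(o for _, o, _, _ in per_gene)
    total_eff = sum(e for _, _, _, e in per_gene)
    p_values = [
        test_gene(obs, eff, total_obs - obs, total_eff - eff)
        for _, obs, _, eff in per_gene
    ]
    q_values = adjust_bh(p_values)
    results = [
        GeneTestResult(gene_id=gid, observed=obs, expected=exp, opportunity=eff,
                       p_value=p, q_value=float(q))
        for (gid, obs, exp, eff), p, q in zip(per_gene, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.gene_id))
    logger.info(
        "SMG run: %d genes, %d protein-altering events, pooled rates "
        "cpg=%.3g noncpg=%.3g indel=%.3g",
        len(results), total_obs, rates.pooled_cpg, rates.pooled_noncpg,
        rates.pooled_indel,
    )
    return results, rates


def results_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene=r.gene_id, observed=r.observed, expected=r.expected,
                 opportunity=r.opportunity, p_value=r.p_value, q_value=r.q_value)
            for r in results
        ]
    )
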