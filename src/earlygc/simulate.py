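"""Synthetic tumor/normal cohort generator.

Produces a toy reference genome with a controlled CpG dinucleotide density,
non-overlapping gene models, per-sample somatic variant calls with read
evidence engineered to exercise every exome-filter criterion, and 5-marker
microsatellite-instability profiles — so the whole analysis pipeline is
testable without any external data.

The statistical model is deliberately simple and fully documented in the
package methods note:

* true somatic SNVs are Poisson per site category (CpG vs non-CpG), drawn
  uniformly over the category's sites; CpG mutations are deamination-biased
  (C>T / G>A with probability ``cpg_ct_bias``);
* "driver" genes receive extra nonsynonymous events at ``(multiplier - 1)``
  times the per-substitution background rate over their CDS, so the gene's
  total nonsynonymous rate is exactly ``multiplier`` times background;
* indels are Poisson per bp, uniform over the genome, length 1–3;
* true events are made filter-passing *by construction* (depths and strand
  counts are drawn stochastically, then minimally and deterministically
  adjusted to honour the pass label), so filter sensitivity on truth is 1
  by design; injected artifact records each violate exactly one named
  exome criterion and probe specificity.

A truth table accompanies every cohort: one row per emitted record with its
category and, for artifacts, the single criterion code it violates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import CODON_AA, COMPLEMENT, GeneModel, ReferenceGenome
from .filters import VariantCall
from .msi import BETHESDA_MARKERS, MSIPanelResult, classify_panel

BASES = np.array(["A", "C", "G", "T"])

# artifact type -> exome criterion code it is built to violate
ARTIFACT_CRITERION = {
    "low_depth": "EX1",
    "normal_support": "EX3",
    "strand_bias": "EX4",
    "known": "EX5",
}

TRUTH_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "var_class", "category", "label",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ArtifactRates:
    """Per-bp per-sample rates of injected filter-failing records."""

    low_depth: float = 1e-6
    normal_support: float = 1e-6
    strand_bias: float = 1e-6
    known: float = 1e-6

    def as_dict(self) -> dict[str, float]:
        return {
            "low_depth": self.low_depth,
            "normal_support": self.normal_support,
            "strand_bias": self.strand_bias,
            "known": self.known,
        }


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate a small whole-exome tumor/normal cohort: 19 samples
    (the screening-cohort size), ~105x mean depth, a 10-fold CpG excess in
    the point-mutation rate, and per-sample burdens within the per-Mb range
    such cohorts display. Rates are per eligible site (or bp) per sample.
    """

    seed: int = 0
    n_samples: int = 19
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    cpg_density: float = 0.02
    n_genes: int = 50
    gene_cds_length: int = 999
    rate_cpg: float = 5.5e-5
    rate_noncpg: float = 5.5e-6
    rate_indel: float = 5.5e-7
    driver_genes: tuple[tuple[str, float], ...] = ()
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    depth_mean: float = 105.0
    vaf_mean: float = 0.30
    cpg_ct_bias: float = 0.8

    def validate(self) -> None:
        if self.n_samples < 0 or self.n_chromosomes < 1:
            raise SimConfigError("n_samples must be >= 0 and n_chromosomes >= 1")
        if self.chromosome_length < 10:
            raise SimConfigError("chromosome_length too small")
        if not 0.0 <= self.cpg_density <= 0.4:
            raise SimConfigError("cpg_density must be in [0, 0.4]")
        if self.gene_cds_length % 3 != 0 or self.gene_cds_length <= 0:
            raise SimConfigError("gene_cds_length must be a positive multiple of 3")
        for rate in (self.rate_cpg, self.rate_noncpg, self.rate_indel):
            if not (math.isfinite(rate) and rate >= 0):
                raise SimConfigError("mutation rates must be finite and >= 0")
        for _, mult in self.driver_genes:
            if mult < 1:
                raise SimConfigError("driver multipliers must be >= 1")
        for name, rate in self.artifact_rates.as_dict().items():
            if rate < 0:
                raise SimConfigError(f"artifact rate {name} must be >= 0")
        if self.depth_mean < 1:
            raise SimConfigError("depth_mean must be >= 1")
        if not 0 < self.vaf_mean <= 1:
            raise SimConfigError("vaf_mean must be in (0, 1]")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _chromosome_sequence(rng: np.random.Generator, length: int, cpg_density: float) -> str:
    """Random A/C/G/T sequence with an exact planted CpG dinucleotide count.

    The background is drawn CpG-free (existing CG dinucleotides are broken
    by resampling the G), then ``round(cpg_density * (length-1))`` CG pairs
    are planted at distinct even offsets, which cannot create or destroy
    other CpGs — the realized density is the requested one exactly.
    """
    arr = BASES[rng.integers(0, 4, size=length)]
    while True:
        cg = np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G"))
        if cg.size == 0:
            break
        arr[cg + 1] = np.array(["A", "C", "T"])[rng.integers(0, 3, size=cg.size)]
    n_plant = int(round(cpg_density * (length - 1)))
    if n_plant > 0:
        even = np.arange(0, length - 1, 2)
        if n_plant > even.size:
            raise SimConfigError(
                f"cpg_density {cpg_density} needs {n_plant} CpG sites but only "
                f"{even.size} non-overlapping slots exist"
            )
        sites = rng.choice(even, size=n_plant, replace=False)
        arr[sites] = "C"
        arr[sites + 1] = "G"
    return "".join(arr)


def _place_genes(
    rng: np.random.Generator, config: SimConfig, chrom_names: Sequence[str]
) -> list[GeneModel]:
    margin, gap, intron = 100, 60, 90
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for i in range(config.n_genes):
        per_chrom[chrom_names[i % len(chrom_names)]].append(i)
    genes: list[GeneModel] = []
    width = max(4, len(str(max(config.n_genes, 1))))
    for chrom, idxs in per_chrom.items():
        if not idxs:
            continue
        footprints = [
            config.gene_cds_length + (intron if i % 3 == 2 else 0) for i in idxs
        ]
        available = config.chromosome_length - 2 * margin
        slot = available // len(idxs)
        needed = max(footprints) + gap
        if slot < needed:
            raise SimConfigError(
                f"cannot place {len(idxs)} genes on {chrom}: each needs "
                f"{needed} bp but only {slot} bp per slot are available "
                f"(chromosome_length={config.chromosome_length})"
            )
        for k, i in enumerate(idxs):
            jitter = int(rng.integers(0, slot - footprints[k] - gap + 1))
            start = margin + k * slot + jitter
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if i % 3 == 2:  # two-exon gene
                half = (config.gene_cds_length // 2) // 3 * 3
                intervals = (
                    (start, start + half),
                    (start + half + intron, start + config.gene_cds_length + intron),
                )
            else:
                intervals = ((start, start + config.gene_cds_length),)
            genes.append(
                GeneModel(
                    gene_id=f"G{i + 1:0{width}d}",
                    chrom=chrom,
                    strand=strand,
                    intervals=intervals,
                )
            )
    return sorted(genes, key=lambda g: g.gene_id)


def generate_reference(config: SimConfig) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Generate the toy reference genome and its gene models.

    Deterministic in ``config.seed``; gene CDS intervals are non-overlapping
    and within chromosome bounds, and the realized CpG dinucleotide density
    equals ``config.cpg_density`` by construction.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        c: _chromosome_sequence(rng, config.chromosome_length, config.cpg_density)
        for c in chrom_names
    }
    ref = ReferenceGenome(seqs)
    genes = _place_genes(rng, config, chrom_names) if config.n_genes else []
    return ref, genes


# ---------------------------------------------------------------------------
# read-evidence construction


def _true_evidence(rng: np.random.Generator, config: SimConfig) -> dict:
    """Filter-passing tumor/normal read evidence.

    Draws depth ~ Poisson, alt ~ Binomial(depth, VAF), strand split ~
    Binomial(alt, 1/2), then clips each quantity to the minimal value that
    satisfies the exome criteria (the deterministic adjustment rule).
    """
    depth = max(30, int(rng.poisson(config.depth_mean)))
    alt = int(rng.binomial(depth, config.vaf_mean))
    alt = min(depth, max(alt, 3, math.ceil(0.10 * depth)))
    fwd = int(rng.binomial(alt, 0.5))
    min_strand = math.ceil(0.2 * alt)
    fwd = min(max(fwd, min_strand), alt - min_strand)
    normal_depth = max(30, int(rng.poisson(config.depth_mean)))
    normal_alt = min(1, int(rng.binomial(normal_depth, 0.001)))
    return dict(
        tumor_depth=depth,
        tumor_alt=alt,
        alt_forward=fwd,
        alt_reverse=alt - fwd,
        normal_depth=normal_depth,
        normal_alt=normal_alt,
        known_variant=False,
        variant_score=round(float(rng.uniform(0.5, 1.0)), 3),
        base_quality_min=int(rng.integers(30, 41)),
        call_quality=round(float(rng.uniform(120.0, 500.0)), 1),
        barcode_pairs=int(rng.integers(2, 11)),
    )


def _artifact_evidence(rng: np.random.Generator, config: SimConfig, kind: str) -> dict:
    """Read evidence violating exactly the one exome criterion for ``kind``."""
    ev = _true_evidence(rng, config)
    if kind == "low_depth":
        depth = int(rng.integers(10, 30))
        ev.update(tumor_depth=depth, tumor_alt=3, alt_forward=2, alt_reverse=1)
    elif kind == "normal_support":
        ev.update(normal_alt=int(rng.integers(2, 7)))
    elif kind == "strand_bias":
        alt = max(5, ev["tumor_alt"])
        ev.update(
            tumor_depth=max(alt, ev["tumor_depth"]),
            tumor_alt=alt, alt_forward=0, alt_reverse=alt,
        )
    elif kind == "known":
        ev.update(known_variant=True)
    else:  # pragma: no cover
        raise ValueError(f"unknown artifact kind {kind!r}")
    return ev


# ---------------------------------------------------------------------------
# cohort simulation


def _driver_substitution_table(
    gene: GeneModel, ref: ReferenceGenome, cpg_mask: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(genomic position, genomic-strand alt base, per-substitution rate)
    arrays for every nonsynonymous substitution available in ``gene``."""
    cds = gene.cds_sequence(ref)
    gpos = gene.genomic_positions()
    positions, alts, weights = [], [], []
    for i, pos0 in enumerate(gpos):
        codon_start = 3 * (i // 3)
        codon = cds[codon_start : codon_start + 3]
        within = i % 3
        site_rate = config.rate_cpg if cpg_mask[pos0] else config.rate_noncpg
        for alt in "ACGT":
            if alt == codon[within]:
                continue
            mutant = codon[:within] + alt + codon[within + 1 :]
            if CODON_AA[mutant] != CODON_AA[codon]:
                genomic_alt = alt if gene.strand == "+" else alt.translate(COMPLEMENT)
                positions.append(pos0)
                alts.append(genomic_alt)
                weights.append(site_rate / 3.0)
    return (
        np.asarray(positions, dtype=np.int64),
        np.asarray(alts, dtype="U1"),
        np.asarray(weights, dtype=float),
    )


@dataclass
class CohortSim:
    """A simulated cohort: per-sample call lists plus the truth table."""

    calls: dict[str, list[VariantCall]]
    truth: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls)

    def all_calls(self) -> list[VariantCall]:
        return [c for sample in self.calls.values() for c in sample]


def _mutant_alt(rng: np.random.Generator, base: str, is_cpg: bool, bias: float) -> str:
    if is_cpg and base in "CG":
        deaminated = "T" if base == "C" else "A"
        if rng.random() < bias:
            return deaminated
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def simulate_cohort(
    ref: ReferenceGenome, genes: Sequence[GeneModel], config: SimConfig
) -> CohortSim:
    """Draw per-sample somatic call sets (plus artifacts) from the reference.

    Deterministic in ``config.seed``. Multi-allelic sites are never emitted:
    at most one record per (sample, chromosome, position), with indel
    reference spans reserved too.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    gene_by_id = {g.gene_id: g for g in genes}
    for gid, _ in config.driver_genes:
        if gid not in gene_by_id:
            raise SimConfigError(f"driver gene {gid!r} not in gene set")

    per_chrom: dict[str, dict] = {}
    for chrom in ref.chroms:
        mask = ref.cpg_mask(chrom)
        per_chrom[chrom] = {
            "cpg_pos": np.flatnonzero(mask),
            "noncpg_pos": np.flatnonzero(~mask),
            "mask": mask,
        }
    driver_tables = {
        gid: _driver_substitution_table(
            gene_by_id[gid], ref, per_chrom[gene_by_id[gid].chrom]["mask"], config
        )
        for gid, _ in config.driver_genes
    }

    width = max(2, len(str(config.n_samples)))
    calls: dict[str, list[VariantCall]] = {}
    truth_rows: list[tuple] = []

    for s in range(config.n_samples):
        sample_id = f"S{s + 1:0{width}d}"
        sample_calls: list[VariantCall] = []
        taken: dict[str, set[int]] = {c: set() for c in ref.chroms}

        def emit(chrom, pos0, ref_allele, alt_allele, var_class, category, label, ev):
            span = range(pos0, pos0 + len(ref_allele))
            if any(p in taken[chrom] for p in span):
                return
            taken[chrom].update(span)
            call = VariantCall(
                sample_id=sample_id,
                chrom=chrom,
                pos=pos0 + 1,
                ref=ref_allele,
                alt=alt_allele,
                var_class=var_class,
                **ev,
            )
            sample_calls.append(call)
            truth_rows.append(
                (sample_id, chrom, pos0 + 1, ref_allele, alt_allele, var_class,
                 category, label)
            )

        for chrom in ref.chroms:
            seq = ref.seq(chrom)
            info = per_chrom[chrom]
            # point mutations per site category
            for category, sites, rate in (
                ("snv_cpg", info["cpg_pos"], config.rate_cpg),
                ("snv_noncpg", info["noncpg_pos"], config.rate_noncpg),
            ):
                if rate == 0 or sites.size == 0:
                    continue
                n = min(int(rng.poisson(sites.size * rate)), sites.size)
                if n == 0:
                    continue
                chosen = rng.choice(sites, size=n, replace=False)
                for pos0 in sorted(int(p) for p in chosen):
                    base = seq[pos0]
                    alt = _mutant_alt(
                        rng, base, category == "snv_cpg", config.cpg_ct_bias
                    )
                    emit(chrom, pos0, base, alt, "SNV", category, "somatic",
                         _true_evidence(rng, config))
            # indels
            if config.rate_indel > 0:
                n_indel = int(rng.poisson(len(seq) * config.rate_indel))
                for _ in range(n_indel):
                    pos0 = int(rng.integers(1, len(seq) - 4))
                    size = int(rng.integers(1, 4))
                    if rng.integers(0, 2) == 0:  # deletion
                        ref_allele = seq[pos0 : pos0 + size + 1]
                        alt_allele = seq[pos0]
                        var_class = "deletion"
                    else:
                        ins = "".join(BASES[rng.integers(0, 4, size=size)])
                        ref_allele = seq[pos0]
                        alt_allele = seq[pos0] + ins
                        var_class = "insertion"
                    emit(chrom, pos0, ref_allele, alt_allele, var_class, "indel",
                         "somatic", _true_evidence(rng, config))

        # driver spike-ins: extra nonsynonymous events on top of background
        for gid, mult in config.driver_genes:
            gene = gene_by_id[gid]
            positions, alts, weights = driver_tables[gid]
            total = float(weights.sum())
            if total == 0 or mult <= 1:
                continue
            n_extra = int(rng.poisson((mult - 1.0) * total))
            if n_extra == 0:
                continue
            idx = rng.choice(positions.size, size=n_extra, p=weights / total)
            for j in sorted(int(i) for i in idx):
                pos0 = int(positions[j])
                emit(gene.chrom, pos0, ref.base(gene.chrom, pos0), str(alts[j]),
                     "SNV", "snv_driver", "somatic", _true_evidence(rng, config))

        # artifact records, each violating exactly one exome criterion
        for kind, rate in config.artifact_rates.as_dict().items():
            if rate == 0:
                continue
            for chrom in ref.chroms:
                seq = ref.seq(chrom)
                n_art = int(rng.poisson(len(seq) * rate))
                for _ in range(n_art):
                    pos0 = int(rng.integers(1, len(seq) - 1))
                    base = seq[pos0]
                    alt_choices = [b for b in "ACGT" if b != base]
                    alt = alt_choices[int(rng.integers(0, 3))]
                    emit(chrom, pos0, base, alt, "SNV", f"artifact_{kind}",
                         ARTIFACT_CRITERION[kind],
                         _artifact_evidence(rng, config, kind))

        calls[sample_id] = sample_calls

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return CohortSim(calls=calls, truth=truth)


def expected_snv_count(ref: ReferenceGenome, config: SimConfig) -> float:
    """Analytic Poisson mean of true SNVs over the whole cohort (no drivers)."""
    total = 0.0
    for chrom in ref.chroms:
        n_cpg = int(ref.cpg_mask(chrom).sum())
        n_noncpg = ref.length(chrom) - n_cpg
        total += n_cpg * config.rate_cpg + n_noncpg * config.rate_noncpg
    return total * config.n_samples


def simulate_msi_profiles(
    n_samples: int,
    marker_instability_prob: Sequence[float],
    seed: int,
) -> list[MSIPanelResult]:
    """Independent Bernoulli instability flags for the 5 Bethesda markers."""
    probs = list(marker_instability_prob)
    if len(probs) != len(BETHESDA_MARKERS):
        raise SimConfigError(
            f"need {len(BETHESDA_MARKERS)} marker probabilities, got {len(probs)}"
        )
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise SimConfigError("marker probabilities must be in [0, 1]")
    rng = _rng(seed, 2)
    width = max(2, len(str(max(n_samples, 1))))
    results = []
    for s in range(n_samples):
        flags = tuple(bool(rng.random() < p) for p in probs)
        results.append(classify_panel(f"S{s + 1:0{width}d}", flags))
    return results
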