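"""Somatic variant filtering for tumor/normal candidate calls.

Two rulesets are provided, matching the two sequencing stages of a
tumor/normal study design:

* :func:`filter_exome` — the whole-exome (screening) ruleset: tumor depth
  and alt-read support, variant allele fraction, matched-normal evidence,
  per-strand support balance, and known-variant (population database)
  exclusion.
* :func:`filter_targeted` — the targeted-panel (replication) ruleset:
  variant score, base quality, call quality, allele fraction, alt-read
  support, barcode read-pair support, and known-variant exclusion.

Both return a :class:`FilterReport` with every rejected record annotated
with *all* criteria it violates (codes ``EX1``–``EX5`` / ``TG1``–``TG6``),
so filter behaviour is fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable

logger = logging.getLogger(__name__)

VAR_CLASSES = ("SNV", "insertion", "deletion")


class FilterError(ValueError):
    """Raised for malformed variant records or missing annotations."""


class MissingAnnotationError(FilterError):
    """A field required by the active ruleset is absent from a record."""


def infer_var_class(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV, insertion, or deletion."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    raise FilterError(f"cannot classify alleles {ref!r}>{alt!r} (MNV unsupported)")


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic event with tumor/normal read evidence.

    Coordinates are 1-based (VCF convention). ``alt_forward``/``alt_reverse``
    are the per-strand counts of tumor reads supporting the alternate allele
    and must sum to ``tumor_alt``. Targeted-stage annotations
    (``variant_score``, ``base_quality_min``, ``call_quality``,
    ``barcode_pairs``) are optional and only required by
    :func:`filter_targeted`.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    alt_forward: int
    alt_reverse: int
    known_variant: bool = False
    variant_score: float | None = None
    base_quality_min: int | None = None
    call_quality: float | None = None
    barcode_pairs: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FilterError(f"position must be >= 1, got {self.pos}")
        if self.var_class not in VAR_CLASSES:
            raise FilterError(f"unknown var_class {self.var_class!r}")
        if self.var_class == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise FilterError(
                    f"SNV alleles must be single differing bases, got "
                    f"{self.ref!r}>{self.alt!r}"
                )
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise FilterError(
                f"tumor_alt {self.tumor_alt} outside [0, tumor_depth={self.tumor_depth}]"
            )
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise FilterError(
                f"normal_alt {self.normal_alt} outside [0, normal_depth={self.normal_depth}]"
            )
        if self.alt_forward < 0 or self.alt_reverse < 0:
            raise FilterError("strand counts must be non-negative")
        if self.alt_forward + self.alt_reverse != self.tumor_alt:
            raise FilterError(
                f"alt_forward+alt_reverse ({self.alt_forward}+{self.alt_reverse}) "
                f"!= tumor_alt ({self.tumor_alt})"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction in the tumor (0 when depth is 0)."""
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def is_indel(self) -> bool:
        return self.var_class != "SNV"


EXOME_CRITERIA = {
    "EX1": "tumor read depth >= 30 with >= 3 reads harboring the mutation",
    "EX2": "mutant allele present in >= 10% of all reads",
    "EX3": "normal read depth >= 30 with <= 1 read harboring the mutation",
    "EX4": "minimum per-strand fraction of mutant reads >= 0.2",
    "EX5": "not listed in dbSNP 137, HapMap, or 1000 Genomes",
}

TARGETED_CRITERIA = {
    "TG1": "variant score >= 0.3 and minimum base quality >= 30",
    "TG2": "variant call quality >= 100",
    "TG3": "allele frequency >= 0.1",
    "TG4": ">= 10 reads supporting the variant allele",
    "TG5": ">= 2 read pairs per barcode",
    "TG6": "not listed in dbSNP 137, HapMap, or 1000 Genomes",
}


@dataclass(frozen=True)
class ExomeThresholds:
    """Exome-stage thresholds. Defaults are the study values; any override
    is logged as a non-default setting."""

    min_tumor_depth: int = 30
    min_tumor_alt: int = 3
    min_vaf: float = 0.10
    min_normal_depth: int = 30
    max_normal_alt: int = 1
    min_strand_fraction: float = 0.2


@dataclass(frozen=True)
class TargetedThresholds:
    """Targeted-stage thresholds; defaults are the study values."""

    min_variant_score: float = 0.3
    min_base_quality: int = 30
    min_call_quality: float = 100.0
    min_vaf: float = 0.1
    min_tumor_alt: int = 10
    min_barcode_pairs: int = 2


@dataclass
class FilterReport:
    """Outcome of a filtering pass.

    ``kept`` and ``rejected`` partition the input; each rejected record
    carries the full tuple of violated criterion codes.
    """

    kept: list[VariantCall]
    rejected: list[tuple[VariantCall, tuple[str, ...]]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def rejection_counts(self) -> dict[str, int]:
        """Number of rejected records per criterion code (multi-counted)."""
        counts: dict[str, int] = {}
        for _, codes in self.rejected:
            for code in codes:
                counts[code] = counts.get(code, 0) + 1
        return counts


def _warn_non_default(thresholds, default_cls, ruleset: str) -> None:
    default = default_cls()
    diffs = {
        f.name: getattr(thresholds, f.name)
        for f in dc_fields(default)
        if getattr(thresholds, f.name) != getattr(default, f.name)
    }
    if diffs:
        logger.warning("non-paper settings for %s filter: %s", ruleset, diffs)


def exome_violations(
    call: VariantCall, thresholds: ExomeThresholds | None = None
) -> tuple[str, ...]:
    """Criterion codes violated by ``call`` under the exome ruleset.

    The strand-balance test (EX4) is only evaluated when there is at least
    one mutant read; with ``tumor_alt == 0`` the record already fails EX1
    and the undefined strand fraction is never computed.
    """
    th = thresholds or ExomeThresholds()
    codes: list[str] = []
    if call.tumor_depth < th.min_tumor_depth or call.tumor_alt < th.min_tumor_alt:
        codes.append("EX1")
    if call.vaf < th.min_vaf:
        codes.append("EX2")
    if call.normal_depth < th.min_normal_depth or call.normal_alt > th.max_normal_alt:
        codes.append("EX3")
    if call.tumor_alt > 0:
        strand_min = min(call.alt_forward, call.alt_reverse) / call.tumor_alt
        if strand_min < th.min_strand_fraction:
            codes.append("EX4")
    if call.known_variant:
        codes.append("EX5")
    return tuple(codes)


def targeted_violations(
    call: VariantCall, thresholds: TargetedThresholds | None = None
) -> tuple[str, ...]:
    """Criterion codes violated by ``call`` under the targeted ruleset.

    Raises :class:`MissingAnnotationError` naming the first absent
    annotation field; records are never passed silently.
    """
    th = thresholds or TargetedThresholds()
    for name in ("variant_score", "base_quality_min", "call_quality", "barcode_pairs"):
        if getattr(call, name) is None:
            raise MissingAnnotationError(
                f"targeted filter requires field {name!r} on record "
                f"{call.chrom}:{call.pos} {call.ref}>{call.alt}"
            )
    codes: list[str] = []
    if call.variant_score < th.min_variant_score or call.base_quality_min < th.min_base_quality:
        codes.append("TG1")
    if call.call_quality < th.min_call_quality:
        codes.append("TG2")
    if call.vaf < th.min_vaf:
        codes.append("TG3")
    if call.tumor_alt < th.min_tumor_alt:
        codes.append("TG4")
    if call.barcode_pairs < th.min_barcode_pairs:
        codes.append("TG5")
    if call.known_variant:
        codes.append("TG6")
    return tuple(codes)


def _run_filter(calls, violations, thresholds) -> FilterReport:
    kept: list[VariantCall] = []
    rejected: list[tuple[VariantCall, tuple[str, ...]]] = []
    for call in calls:
        codes = violations(call, thresholds)
        if codes:
            rejected.append((call, codes))
        else:
            kept.append(call)
    return FilterReport(kept=kept, rejected=rejected)


def filter_exome(
    calls: Iterable[VariantCall], thresholds: ExomeThresholds | None = None
) -> FilterReport:
    """Apply the exome-stage somatic filter.

    A record is kept iff tumor depth >= 30 with >= 3 mutant reads, VAF >=
    10%, normal depth >= 30 with <= 1 mutant read, the minor strand carries
    >= 20% of mutant reads, and the variant is not a known population
    variant. All thresholds are inclusive.
    """
    if thresholds is not None:
        _warn_non_default(thresholds, ExomeThresholds, "exome")
    return _run_filter(calls, exome_violations, thresholds)


def filter_targeted(
    calls: Iterable[VariantCall], thresholds: TargetedThresholds | None = None
) -> FilterReport:
    """Apply the targeted-stage somatic filter.

    A record is kept iff variant score >= 0.3, minimum base quality >= 30,
    call quality >= 100, VAF >= 0.1, >= 10 alt reads, >= 2 read pairs per
    barcode, and the variant is not a known population variant.
    """
    if thresholds is not None:
        _warn_non_default(thresholds, TargetedThresholds, "targeted")
    return _run_filter(calls, targeted_violations, thresholds)
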