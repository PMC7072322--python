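"""Coding-effect, CpG, and trinucleotide-context annotation of variants.

The central objects are :class:`ReferenceGenome` (chromosome name to
uppercase sequence, with cached CpG masks), :class:`GeneModel` (strand-aware
CDS intervals in 0-based half-open coordinates), and
:class:`AnnotatedVariant` (a filtered call plus gene assignment, coding
effect, CpG status, and pyrimidine-centred substitution context).

Effects follow the standard nuclear codon table: an SNV inside a CDS is
synonymous iff the mutant codon translates to the same amino-acid symbol
(stop ``*`` included as a symbol, so gained/lost stops are nonsynonymous);
any indel overlapping a CDS is ``coding_indel``; everything else is
``noncoding``. Protein-altering means nonsynonymous SNV or coding indel.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .filters import VariantCall

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PYRIMIDINES = frozenset("CT")
SUBCLASS6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

EFFECTS = ("synonymous", "nonsynonymous", "coding_indel", "noncoding")

# codon -> amino-acid symbol (stop as '*'), standard nuclear table
CODON_AA: dict[str, str] = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
}


class AnnotationError(ValueError):
    """Raised on reference mismatches or invalid gene models."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ReferenceGenome:
    """Uppercase nucleotide sequences with positional and context lookup.

    Alphabet is restricted to A/C/G/T/N. Context queries at sequence edges
    return ``None`` (a defined sentinel) rather than wrapping.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise AnnotationError(f"{chrom}: invalid characters {bad}")
            self._seqs[chrom] = seq
        self._cpg_masks: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos0: int) -> str:
        return self._seqs[chrom][pos0]

    def context(self, chrom: str, pos0: int) -> str | None:
        """The +/-1 trinucleotide around ``pos0``, or None at an edge."""
        seq = self._seqs[chrom]
        if pos0 < 1 or pos0 > len(seq) - 2:
            return None
        return seq[pos0 - 1 : pos0 + 2]

    def cpg_mask(self, chrom: str) -> np.ndarray:
        """Boolean mask marking both the C and the G of every CpG."""
        if chrom not in self._cpg_masks:
            arr = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype="S1")
            mask = np.zeros(arr.shape[0], dtype=bool)
            if arr.shape[0] >= 2:
                pair = (arr[:-1] == b"C") & (arr[1:] == b"G")
                mask[:-1] |= pair
                mask[1:] |= pair
            self._cpg_masks[chrom] = mask
        return self._cpg_masks[chrom]

    def is_cpg(self, chrom: str, pos0: int) -> bool:
        """True iff the base is the C or the G of a CpG dinucleotide.

        A/T sites (and N-context sites) are False by definition.
        """
        return bool(self.cpg_mask(chrom)[pos0])


def cpg_status(ref: ReferenceGenome, chrom: str, pos0: int) -> bool:
    """Functional alias for :meth:`ReferenceGenome.is_cpg` (0-based)."""
    return ref.is_cpg(chrom, pos0)


@dataclass(frozen=True)
class GeneModel:
    """A gene's CDS as ordered, non-overlapping 0-based half-open intervals.

    ``intervals`` are stored in genomic order; for minus-strand genes the
    spliced CDS is the reverse complement of the concatenated intervals.
    Coding length must be a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not self.intervals:
            raise AnnotationError(f"{self.gene_id}: no CDS intervals")
        prev_end = -1
        for start, end in self.intervals:
            if start < 0 or end <= start:
                raise AnnotationError(f"{self.gene_id}: bad interval ({start}, {end})")
            if start < prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: CDS intervals overlap or are unsorted"
                )
            prev_end = end
        if self.coding_length % 3 != 0:
            raise AnnotationError(
                f"{self.gene_id}: coding length {self.coding_length} not a multiple of 3"
            )

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]

    def validate_against(self, ref: ReferenceGenome) -> None:
        if self.chrom not in ref:
            raise AnnotationError(f"{self.gene_id}: chromosome {self.chrom} not in reference")
        if self.intervals[-1][1] > ref.length(self.chrom):
            raise AnnotationError(
                f"{self.gene_id}: CDS interval exceeds {self.chrom} length "
                f"{ref.length(self.chrom)}"
            )

    def genomic_positions(self) -> np.ndarray:
        """Genomic positions of coding bases in translation (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.intervals])
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, ref: ReferenceGenome) -> str:
        seq = "".join(ref.seq(self.chrom)[s:e] for s, e in self.intervals)
        return revcomp(seq) if self.strand == "-" else seq

    def coding_offset(self, pos0: int) -> int | None:
        """Offset of a genomic position within the spliced CDS, or None."""
        cum = 0
        plus_off = None
        for start, end in self.intervals:
            if start <= pos0 < end:
                plus_off = cum + (pos0 - start)
                break
            cum += end - start
        if plus_off is None:
            return None
        return self.coding_length - 1 - plus_off if self.strand == "-" else plus_off


class GeneIndex:
    """Interval index over gene CDS footprints with cached CDS sequences."""

    def __init__(self, genes: Iterable[GeneModel], ref: ReferenceGenome):
        self.ref = ref
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._cds_cache: dict[str, str] = {}
        for gene in genes:
            gene.validate_against(ref)
            if gene.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for start, end in gene.intervals:
                tree.addi(start, end, gene.gene_id)

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        ids = sorted({iv.data for iv in tree.overlap(start0, end0)})
        return [self.genes[g] for g in ids]

    def cds_sequence(self, gene: GeneModel) -> str:
        if gene.gene_id not in self._cds_cache:
            self._cds_cache[gene.gene_id] = gene.cds_sequence(self.ref)
        return self._cds_cache[gene.gene_id]


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call plus annotation.

    ``gene_id`` is the deterministic primary assignment (lexicographically
    smallest overlapping gene), used for burden counting; ``gene_ids`` lists
    every overlapping gene for cohort matrices. ``is_cpg``/``context96``/
    ``subclass6`` are defined for SNVs only; ``context96`` is ``None`` when
    the +/-1 context is unavailable (chromosome edge).
    """

    call: VariantCall
    gene_ids: tuple[str, ...]
    effect: str
    is_cpg: bool | None = None
    context96: str | None = None
    subclass6: str | None = None

    @property
    def gene_id(self) -> str | None:
        return self.gene_ids[0] if self.gene_ids else None

    @property
    def sample_id(self) -> str:
        return self.call.sample_id

    @property
    def protein_altering(self) -> bool:
        return self.effect in ("nonsynonymous", "coding_indel")


def _snv_effect(call: VariantCall, gene: GeneModel, index: GeneIndex) -> str:
    pos0 = call.pos - 1
    offset = gene.coding_offset(pos0)
    if offset is None:  # overlaps the gene footprint but falls in an intron
        return "noncoding"
    cds = index.cds_sequence(gene)
    codon_start = 3 * (offset // 3)
    codon = cds[codon_start : codon_start + 3]
    within = offset % 3
    alt_coding = call.alt if gene.strand == "+" else call.alt.translate(COMPLEMENT)
    mutant = codon[:within] + alt_coding + codon[within + 1 :]
    return "synonymous" if CODON_AA[mutant] == CODON_AA[codon] else "nonsynonymous"


def classify_coding_effect(
    call: VariantCall, index: GeneIndex
) -> tuple[str, tuple[str, ...]]:
    """Coding effect of a variant plus its overlapping gene ids.

    Raises :class:`AnnotationError` if the reference does not match the
    record's REF allele at its position.
    """
    ref = index.ref
    pos0 = call.pos - 1
    if call.chrom not in ref:
        raise AnnotationError(f"chromosome {call.chrom} not in reference")
    ref_slice = ref.seq(call.chrom)[pos0 : pos0 + len(call.ref)]
    if ref_slice != call.ref:
        raise AnnotationError(
            f"reference mismatch at {call.chrom}:{call.pos}: "
            f"record REF {call.ref!r} vs reference {ref_slice!r}"
        )
    span_end = pos0 + max(len(call.ref), 1)
    genes = index.overlapping(call.chrom, pos0, span_end)
    if call.var_class == "SNV":
        genes = [g for g in genes if g.coding_offset(pos0) is not None]
        if not genes:
            return "noncoding", ()
        gene_ids = tuple(g.gene_id for g in genes)
        # non-overlapping gene sets share the effect; compute on the primary
        return _snv_effect(call, genes[0], index), gene_ids
    if genes:
        return "coding_indel", tuple(g.gene_id for g in genes)
    return "noncoding", ()


def trinucleotide_context(ref: ReferenceGenome, call: VariantCall) -> str | None:
    """Pyrimidine-centred 96-class context label, e.g. ``T[C>T]G``.

    Purine reference bases are reverse-complemented so the centre is C or T.
    Returns None at chromosome edges where a full +/-1 context is missing.
    """
    triplet = ref.context(call.chrom, call.pos - 1)
    if triplet is None or "N" in triplet:
        return None
    r, a = call.ref, call.alt
    if r not in PYRIMIDINES:
        triplet = revcomp(triplet)
        r = r.translate(COMPLEMENT)
        a = a.translate(COMPLEMENT)
    return f"{triplet[0]}[{r}>{a}]{triplet[2]}"


def substitution_class(ref_base: str, alt_base: str) -> str:
    """Pyrimidine-normalized 6-class substitution label (e.g. ``C>T``)."""
    if ref_base not in PYRIMIDINES:
        ref_base = ref_base.translate(COMPLEMENT)
        alt_base = alt_base.translate(COMPLEMENT)
    return f"{ref_base}>{alt_base}"


def annotate_variant(call: VariantCall, index: GeneIndex) -> AnnotatedVariant:
    effect, gene_ids = classify_coding_effect(call, index)
    if call.var_class != "SNV":
        return AnnotatedVariant(call=call, gene_ids=gene_ids, effect=effect)
    return AnnotatedVariant(
        call=call,
        gene_ids=gene_ids,
        effect=effect,
        is_cpg=index.ref.is_cpg(call.chrom, call.pos - 1),
        context96=trinucleotide_context(index.ref, call),
        subclass6=substitution_class(call.ref, call.alt),
    )


def annotate_cohort(
    calls: Iterable[VariantCall],
    genes: Sequence[GeneModel],
    ref: ReferenceGenome,
) -> list[AnnotatedVariant]:
    """Annotate a collection of calls against one gene set and reference."""
    index = GeneIndex(genes, ref)
    return [annotate_variant(call, index) for call in calls]


@dataclass(frozen=True)
class SpectrumSummary:
    """Substitution-spectrum tabulation of a set of annotated SNVs."""

    counts6: dict[str, int]
    counts96: dict[str, int]
    modal_class: str | None
    modal_count: int

    @property
    def n_snvs(self) -> int:
        return sum(self.counts6.values())


def export_4col(variants: Iterable[AnnotatedVariant | VariantCall], path) -> None:
    """Write a CHROM/POS/REF/ALT TSV (one row per variant, order preserved)."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\n")
        for v in variants:
            call = v.call if isinstance(v, AnnotatedVariant) else v
            fh.write(f"{call.chrom}\t{call.pos}\t{call.ref}\t{call.alt}\n")


def spectrum_summary(variants: Iterable[AnnotatedVariant]) -> SpectrumSummary:
    """Tabulate 6-class and 96-class substitution counts.

    6-class counts cover every SNV; 96-class counts cover SNVs with an
    available +/-1 context. The modal 6-class is None for empty input.
    """
    c6: Counter = Counter()
    c96: Counter = Counter()
    for v in variants:
        if v.call.var_class != "SNV":
            continue
        c6[v.subclass6] += 1
        if v.context96 is not None:
            c96[v.context96] += 1
    counts6 = {k: c6.get(k, 0) for k in SUBCLASS6}
    if c6:
        modal, modal_count = c6.most_common(1)[0]
    else:
        modal, modal_count = None, 0
    return SpectrumSummary(
        counts6=counts6, counts96=dict(sorted(c96.items())), modal_class=modal,
        modal_count=modal_count,
    )
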