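"""Cohort-level descriptive and inferential statistics.

Builds the samples x genes mutation matrix from filtered, annotated
variants, reports per-gene mutated-sample frequencies (half-up rounding to
one decimal, in percent), selects recurrently mutated genes (mutated in at
least ``min_patients`` samples with a cohort-aggregate burden above
``min_rate_per_mb`` mutations per Mb of coding footprint), and runs 2x2
Fisher exact association tests — including mutual-exclusivity summaries and
cohort-vs-cohort frequency comparisons on user-supplied counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .annotate import AnnotatedVariant


class CohortError(ValueError):
    """Invalid cohort-level input."""


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table [[a, b], [c, d]] with optional labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CohortError("2x2 cell counts must be non-negative")

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_2x2(table: TwoByTwo, alternative: str = "two-sided") -> float:
    """Exact conditional p-value for a 2x2 table.

    The two-sided p is the sum of the probabilities of all tables (at fixed
    margins) no more probable than the observed one.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise CohortError(f"unknown alternative {alternative!r}")
    return float(stats.fisher_exact(table.table, alternative=alternative)[1])


def build_matrix(
    variants: Iterable[AnnotatedVariant],
    gene_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x genes matrix of protein-altering mutation counts.

    A variant overlapping several genes increments every overlapping gene's
    cell (cohort-matrix convention; burden tests count it once elsewhere).
    Unknown gene ids in the input raise an error.
    """
    variants = list(variants)
    known = set(gene_ids)
    samples = list(sample_ids) if sample_ids is not None else sorted(
        {v.sample_id for v in variants}
    )
    matrix = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                          columns=pd.Index(gene_ids, name="gene"), dtype=int)
    for v in variants:
        if not v.protein_altering:
            continue
        for gid in v.gene_ids:
            if gid not in known:
                raise CohortError(f"variant assigned to unknown gene {gid!r}")
            if v.sample_id not in matrix.index:
                raise CohortError(f"variant from unknown sample {v.sample_id!r}")
            matrix.at[v.sample_id, gid] += 1
    return matrix


def percent_half_up(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (14/49 -> 28.6)."""
    if denominator <= 0:
        raise CohortError("denominator must be positive")
    pct = Decimal(numerator * 100) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gene_frequencies(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene mutated-sample fraction, in percent to one decimal."""
    n = len(matrix.index)
    if n == 0:
        raise CohortError("cohort must contain at least one sample")
    mutated = (matrix > 0).sum(axis=0)
    return pd.Series(
        {g: percent_half_up(int(m), n) for g, m in mutated.items()}, name="percent"
    )


def select_recurrent(
    matrix: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    min_patients: int = 4,
    min_rate_per_mb: float = 10.0,
) -> list[str]:
    """Recurrently mutated genes.

    A gene is selected iff it is mutated in at least ``min_patients``
    samples ("more than three patients" with the default) and its
    cohort-aggregate mutation count per Mb of coding footprint is strictly
    greater than ``min_rate_per_mb``.
    """
    selected = []
    mutated = (matrix > 0).sum(axis=0)
    totals = matrix.sum(axis=0)
    for gene in matrix.columns:
        length = gene_lengths[gene]
        if length <= 0:
            raise CohortError(f"gene {gene!r} has non-positive coding length")
        rate = totals[gene] / (length / 1e6)
        if mutated[gene] >= min_patients and rate > min_rate_per_mb:
            selected.append(gene)
    return selected


@dataclass(frozen=True)
class ExclusivityResult:
    """Overlap counts between gene A and a gene (or gene set) B."""

    gene_a: str
    genes_b: tuple[str, ...]
    both: int
    a_only: int
    b_only: int
    neither: int
    p_value: float

    @property
    def table(self) -> TwoByTwo:
        return TwoByTwo(self.both, self.a_only, self.b_only, self.neither,
                        row_labels=(f"{self.gene_a}+", f"{self.gene_a}-"),
                        col_labels=("B+", "B-"))


def mutual_exclusivity(
    matrix: pd.DataFrame,
    gene_a: str,
    genes_b: str | Sequence[str],
    alternative: str = "two-sided",
) -> ExclusivityResult:
    """Co-occurrence / exclusivity of gene A versus gene (set) B.

    Reports co-mutated / A-only / B-only / neither sample counts and the
    Fisher exact p on the derived 2x2 table; pass ``alternative='less'`` for
    a one-sided exclusivity test.
    """
    genes_b = (genes_b,) if isinstance(genes_b, str) else tuple(genes_b)
    for g in (gene_a, *genes_b):
        if g not in matrix.columns:
            raise CohortError(f"gene {g!r} not in matrix")
    a = matrix[gene_a] > 0
    b = (matrix[list(genes_b)] > 0).any(axis=1)
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    table = TwoByTwo(both, a_only, b_only, neither)
    return ExclusivityResult(
        gene_a=gene_a, genes_b=genes_b, both=both, a_only=a_only, b_only=b_only,
        neither=neither, p_value=fisher_2x2(table, alternative=alternative),
    )


def cohort_comparison(
    mutated_1: int, total_1: int, mutated_2: int, total_2: int,
    alternative: str = "two-sided",
) -> float:
    """Fisher exact p comparing a gene's mutation frequency in two cohorts."""
    if mutated_1 > total_1 or mutated_2 > total_2:
        raise CohortError("mutated counts cannot exceed cohort sizes")
    table = TwoByTwo(mutated_1, total_1 - mutated_1, mutated_2, total_2 - mutated_2,
                     row_labels=("cohort1", "cohort2"),
                     col_labels=("mutated", "unmutated"))
    return fisher_2x2(table, alternative=alternative)


def oncoprint_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (sample, gene, count, mutated) table of the matrix."""
    long = matrix.stack().reset_index()
    long.columns = ["sample", "gene", "count"]
    long["mutated"] = long["count"] > 0
    return long
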