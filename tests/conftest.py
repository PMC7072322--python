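import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from earlygc.annotate import GeneModel, ReferenceGenome, revcomp
from earlygc.filters import VariantCall
from earlygc.simulate import SimConfig, generate_reference, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=11,
        n_samples=6,
        n_chromosomes=2,
        chromosome_length=120_000,
        n_genes=12,
        gene_cds_length=300,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_reference):
    ref, genes = small_reference
    return simulate_cohort(ref, genes, small_config)


#: hand-built reference: a forward-strand gene and its reverse-complement
#: mirror on a second chromosome, encoding the same protein (M G P stop).
FORWARD_SEQ = "TTTTT" + "ATGGGGCCATAA" + "TTTTT"


@pytest.fixture(scope="session")
def toy_pair():
    reverse_seq = revcomp(FORWARD_SEQ)
    ref = ReferenceGenome({"chrF": FORWARD_SEQ, "chrR": reverse_seq})
    length = len(FORWARD_SEQ)
    fwd = GeneModel(gene_id="FWD", chrom="chrF", strand="+", intervals=((5, 17),))
    rev = GeneModel(
        gene_id="REV", chrom="chrR", strand="-",
        intervals=((length - 17, length - 5),),
    )
    return ref, fwd, rev


def make_call(**kwargs) -> VariantCall:
    """A fully passing exome+targeted record, with overrides.

    When tumor_alt is overridden without explicit strand counts, the strand
    split is recomputed as an even split.
    """
    base = dict(
        sample_id="S1", chrom="chr1", pos=100, ref="A", alt="T", var_class="SNV",
        tumor_depth=100, tumor_alt=30, normal_depth=60, normal_alt=0,
        alt_forward=15, alt_reverse=15, known_variant=False,
        variant_score=0.9, base_quality_min=35, call_quality=200.0,
        barcode_pairs=4,
    )
    base.update(kwargs)
    if "tumor_alt" in kwargs and "alt_forward" not in kwargs:
        alt = base["tumor_alt"]
        base["alt_forward"] = alt - alt // 2
        base["alt_reverse"] = alt // 2
    return VariantCall(**base)
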