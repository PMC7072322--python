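"""End-to-end pipeline: simulate -> filter -> annotate -> SMG -> MSI -> cohort.

``run_pipeline`` drives every stage into a run directory with a JSON
manifest recording the full configuration, the package version, a config
hash, and every non-default parameter. Outputs are deterministic given the
seed. Any stage failure aborts with the stage name in the error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import annotate_cohort, export_4col, spectrum_summary
from .cohort import build_matrix, gene_frequencies, oncoprint_long, select_recurrent
from .filters import filter_exome, filter_targeted
from .io import (
    write_fasta,
    write_genes_gff3,
    write_genes_tsv,
    write_msi_tsv,
    write_rejections_tsv,
    write_truth_table,
    write_vcf,
)
from .simulate import (
    ArtifactRates,
    SimConfig,
    generate_reference,
    simulate_cohort,
    simulate_msi_profiles,
)
from .smg import DEFAULT_BIN_SIZE, DEFAULT_MIN_BIN_MUTATIONS, results_frame, run_smg

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's printed values."""

    outdir: str = "earlygc_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    filter_ruleset: str = "exome"
    bin_size: int = DEFAULT_BIN_SIZE
    min_bin_mutations: int = DEFAULT_MIN_BIN_MUTATIONS
    recurrence_min_patients: int = 4
    recurrence_min_rate_per_mb: float = 10.0
    q_threshold: float = 0.05
    msi_marker_prob: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1, 0.1)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        art_raw = sim_raw.pop("artifact_rates", None)
        drivers = sim_raw.pop("driver_genes", None)
        sim_kwargs = dict(sim_raw)
        if art_raw is not None:
            sim_kwargs["artifact_rates"] = ArtifactRates(**art_raw)
        if drivers is not None:
            sim_kwargs["driver_genes"] = tuple(
                (str(g), float(m)) for g, m in drivers
            )
        config = cls(**raw, sim=SimConfig(**sim_kwargs))
        if "seed" in raw and "seed" not in sim_kwargs:
            config.sim = dataclasses.replace(config.sim, seed=config.seed)
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["msi_marker_prob"] = list(self.msi_marker_prob)
        d["sim"]["driver_genes"] = [list(x) for x in self.sim.driver_genes]
        return d

    def non_default(self) -> dict:
        """Every parameter that differs from the package defaults."""
        default = RunConfig().to_dict()
        current = self.to_dict()

        def diff(cur, ref, prefix=""):
            out = {}
            for k, v in cur.items():
                if isinstance(v, dict):
                    out.update(diff(v, ref[k], prefix=f"{prefix}{k}."))
                elif v != ref[k]:
                    out[f"{prefix}{k}"] = v
            return out

        return diff(current, default)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("earlygc")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    stderr = logging.StreamHandler(sys.stderr)
    root.addHandler(stderr)
    try:
        return _run_pipeline(config, outdir)
    finally:
        root.removeHandler(handler)
        root.removeHandler(stderr)
        handler.close()


def _run_pipeline(config: RunConfig, outdir: Path) -> Path:
    logger.info("pipeline start: outdir=%s seed=%d", outdir, config.seed)

    @_stage("simulate")
    def stage_simulate():
        ref, genes = generate_reference(config.sim)
        cohort = simulate_cohort(ref, genes, config.sim)
        write_fasta(ref, outdir / "reference.fa")
        write_genes_gff3(genes, outdir / "genes.gff3", ref)
        write_genes_tsv(genes, outdir / "genes.tsv")
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for sample_id, calls in cohort.calls.items():
            write_vcf(calls, vcf_dir / f"{sample_id}.vcf", ref, sample_id)
        write_truth_table(cohort.truth, outdir / "truth.tsv")
        return ref, genes, cohort

    ref, genes, cohort = stage_simulate()

    @_stage("filter")
    def stage_filter():
        filt_dir = outdir / "filtered"
        filt_dir.mkdir(exist_ok=True)
        run = filter_exome if config.filter_ruleset == "exome" else filter_targeted
        kept = []
        all_rejected = []
        for sample_id, calls in cohort.calls.items():
            report = run(calls)
            kept.extend(report.kept)
            all_rejected.extend(report.rejected)
            write_vcf(report.kept, filt_dir / f"{sample_id}.vcf", ref, sample_id)
        from .filters import FilterReport

        combined = FilterReport(kept=kept, rejected=all_rejected)
        write_rejections_tsv(combined, filt_dir / "rejections.tsv")
        logger.info("filter: kept %d, rejected %d", len(kept), len(all_rejected))
        return combined

    report = stage_filter()

    @_stage("annotate")
    def stage_annotate():
        annotated = annotate_cohort(report.kept, genes, ref)
        import pandas as pd

        rows = [
            dict(sample_id=v.sample_id, chrom=v.call.chrom, pos=v.call.pos,
                 ref=v.call.ref, alt=v.call.alt, var_class=v.call.var_class,
                 gene_id=v.gene_id or "", effect=v.effect,
                 is_cpg="" if v.is_cpg is None else int(v.is_cpg),
                 context96=v.context96 or "", subclass6=v.subclass6 or "")
            for v in annotated
        ]
        pd.DataFrame(rows).to_csv(outdir / "annotated.tsv", sep="\t", index=False)
        export_4col(annotated, outdir / "variants_4col.tsv")
        spectrum = spectrum_summary(annotated)
        pd.Series(spectrum.counts6, name="count").rename_axis("class").to_csv(
            outdir / "spectrum6.tsv", sep="\t"
        )
        pd.Series(spectrum.counts96, name="count").rename_axis("context").to_csv(
            outdir / "spectrum96.tsv", sep="\t"
        )
        logger.info("annotate: %d variants, modal class %s",
                    len(annotated), spectrum.modal_class)
        return annotated

    annotated = stage_annotate()

    @_stage("smg")
    def stage_smg():
        results, rates = run_smg(
            annotated, ref, genes, config.sim.n_samples,
            bin_size=config.bin_size, min_bin_mutations=config.min_bin_mutations,
        )
        smg_dir = outdir / "smg"
        smg_dir.mkdir(exist_ok=True)
        results_frame(results).to_csv(smg_dir / "gene_results.tsv", sep="\t", index=False)
        rates.bins.to_csv(smg_dir / "rates_bins.tsv", sep="\t", index=False)
        significant = [r.gene_id for r in results if r.q_value < config.q_threshold]
        summary = dict(
            n_genes=len(results),
            n_protein_altering=int(sum(r.observed for r in results)),
            pooled_rate_cpg=rates.pooled_cpg,
            pooled_rate_noncpg=rates.pooled_noncpg,
            pooled_rate_indel=rates.pooled_indel,
            q_threshold=config.q_threshold,
            significant_genes=significant,
        )
        (smg_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
        return results

    smg_results = stage_smg()

    @_stage("msi")
    def stage_msi():
        profiles = simulate_msi_profiles(
            config.sim.n_samples, config.msi_marker_prob, config.seed
        )
        msi_dir = outdir / "msi"
        msi_dir.mkdir(exist_ok=True)
        write_msi_tsv(profiles, msi_dir / "msi_calls.tsv")
        return profiles

    stage_msi()

    @_stage("cohort")
    def stage_cohort():
        cohort_dir = outdir / "cohort"
        cohort_dir.mkdir(exist_ok=True)
        gene_ids = [g.gene_id for g in genes]
        sample_ids = list(cohort.calls)
        matrix = build_matrix(annotated, gene_ids, sample_ids)
        matrix.to_csv(cohort_dir / "matrix.tsv", sep="\t")
        oncoprint_long(matrix).to_csv(cohort_dir / "oncoprint_long.tsv",
                                      sep="\t", index=False)
        gene_frequencies(matrix).rename_axis("gene").to_csv(
            cohort_dir / "frequencies.tsv", sep="\t"
        )
        lengths = {g.gene_id: g.coding_length for g in genes}
        recurrent = select_recurrent(
            matrix, lengths,
            min_patients=config.recurrence_min_patients,
            min_rate_per_mb=config.recurrence_min_rate_per_mb,
        )
        (cohort_dir / "recurrent_genes.tsv").write_text(
            "gene\n" + "".join(f"{g}\n" for g in recurrent)
        )
        return matrix

    stage_cohort()

    manifest = dict(
        package="earlygc",
        version=__version__,
        config=config.to_dict(),
        config_sha256=hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        non_default_parameters=config.non_default(),
        n_significant_genes=sum(
            r.q_value < config.q_threshold for r in smg_results
        ),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return outdir
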