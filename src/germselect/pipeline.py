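"""End-to-end pipeline orchestration.

Stages run in dependency order (simulate -> qc -> annotation -> burden ->
dnds -> disease -> report), each reading its inputs from and writing its
outputs to a single run directory, so stages can be re-run individually.
Every TSV output starts with a reproducibility header line recording the
seed and the configuration hash; rerunning with an identical configuration
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, burden, disease, io, qc, selection, simulate
from .coverage import CoverageTrack
from .reference import ConfigurationError, ReferenceBundle

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "annotation", "burden", "dnds", "disease", "report"]


@dataclass
class RunConfig:
    mode: str = "full"  # simulate | analyze | full
    seed: int = 0
    outdir: str = "germselect_run"
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    dnds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # analyze-mode paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": self.simulate,
            "qc": self.qc,
            "dnds": self.dnds,
            "inputs": self.inputs,
        }

    @property
    def config_hash(self) -> str:
        # the output location is not an analysis parameter
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self, stages: list[str]) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze":
            required = ["reference_fasta", "exon_bed", "coverage_dir",
                        "variants_tsv", "metadata_tsv"]
            if self.dnds.get("use_methylation", True):
                required.append("methylation_bedgraph")
            for key in required:
                if key not in self.inputs:
                    raise ConfigurationError(f"analyze mode is missing input {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigurationError(
                        f"input {key!r} not found: {self.inputs[key]}"
                    )


SIM_DEFAULTS = {
    "n_genes": 30,
    "exons_per_gene": 3,
    "exon_len": 150,
    "intron_len": 80,
    "intergenic_len": 150,
    "n_donors": 20,
    "mean_dx": 2000.0,
    "coverage_dispersion": 20.0,
    "tissue": "sperm",
    "driver_genes": {},
    "hotspot_folds": {},
}


class PipelineRun:
    """Stateful runner bound to one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._header = f"# germselect seed={config.seed} config={config.config_hash}"

    # --- helpers ---------------------------------------------------------

    def _write_tsv(self, name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(self._header + "\n")
            df.to_csv(fh, sep="\t", index=index)

    def _read_tsv(self, name: str, **kw) -> pd.DataFrame:
        return pd.read_csv(self.outdir / name, sep="\t", comment="#", **kw)

    def _load_reference(self) -> ReferenceBundle:
        chrom, seq = io.read_fasta(self.outdir / "genome.fasta")
        genes = io.read_exon_bed(self.outdir / "exons.bed")
        cpg, meth = io.read_methylation_bedgraph(self.outdir / "methylation.bedgraph")
        return ReferenceBundle(chrom, seq, genes, cpg, meth)

    def _load_coverage(self, ref: ReferenceBundle) -> CoverageTrack:
        return io.read_coverage_dir(self.outdir / "coverage", ref.chrom, ref.length)

    # --- stages ----------------------------------------------------------

    def stage_import_inputs(self) -> None:
        """Analyze mode: normalize external inputs into the run directory."""
        import shutil

        inp = self.config.inputs
        shutil.copy(inp["reference_fasta"], self.outdir / "genome.fasta")
        shutil.copy(inp["exon_bed"], self.outdir / "exons.bed")
        if "methylation_bedgraph" in inp:
            shutil.copy(inp["methylation_bedgraph"], self.outdir / "methylation.bedgraph")
        else:
            (self.outdir / "methylation.bedgraph").write_text("")
        cov_out = self.outdir / "coverage"
        cov_out.mkdir(exist_ok=True)
        for f in Path(inp["coverage_dir"]).glob("*.coverage.bedgraph"):
            shutil.copy(f, cov_out / f.name)
        self._write_tsv("variants.tsv", pd.read_csv(inp["variants_tsv"], sep="\t", comment="#"))
        self._write_tsv("metadata.tsv", pd.read_csv(inp["metadata_tsv"], sep="\t", comment="#"))

    def stage_simulate(self) -> None:
        p = {**SIM_DEFAULTS, **self.config.simulate}
        seed = self.config.seed
        ref = simulate.generate_toy_genome(
            p["n_genes"], p["exons_per_gene"], p["exon_len"], seed,
            intron_len=p["intron_len"], intergenic_len=p["intergenic_len"],
        )
        meta = simulate.generate_cohort_metadata(
            p["n_donors"], seed + 1, tissue=p["tissue"]
        )
        coverage = simulate.simulate_coverage(
            ref, meta, p["mean_dx"], p["coverage_dispersion"], seed + 2
        )
        hotspots = {
            (int(k.split(":")[0]), k.split(":")[1]): float(v)
            for k, v in p["hotspot_folds"].items()
        }
        cfg = simulate.SelectionConfig(
            driver_genes={g: tuple(f) for g, f in p["driver_genes"].items()},
            hotspots=hotspots,
        )
        variants = simulate.simulate_cohort_variants(ref, coverage, cfg, meta, seed + 3)

        io.write_fasta(self.outdir / "genome.fasta", ref.chrom, ref.sequence)
        io.write_exon_bed(self.outdir / "exons.bed", ref.chrom, ref.genes)
        io.write_methylation_bedgraph(self.outdir / "methylation.bedgraph", ref)
        io.write_coverage_dir(self.outdir / "coverage", coverage)
        self._write_tsv("variants.tsv", variants)
        self._write_tsv("metadata.tsv", meta)
        io.write_json(
            self.outdir / "truth.json",
            {"config": cfg.to_dict(), "seed": seed, "config_hash": self.config.config_hash},
        )

    def stage_qc(self) -> None:
        thr = qc.QCThresholds(**self.config.qc)
        meta = self._read_tsv("metadata.tsv")
        variants = self._read_tsv("variants.tsv")
        ref = self._load_reference()
        coverage = self._load_coverage(ref)

        masked_pos, decontam, ratio, coverage_masked = qc.insilico_decontaminate(
            variants, coverage, thr.mask_reads, thr.mask_vaf
        )
        reports = qc.filter_samples(meta, thr)
        for r in reports:
            r.masked_passed_ratio = float(ratio.get(r.sample_id, 0.0))
            if r.masked_passed_ratio > thr.mask_ratio_max:
                r.reasons.append("high_mask_ratio")
                r.passed = False
        report = qc.qc_report_frame(reports)
        passed = set(report.loc[report["pass"], "sample_id"])
        filtered = qc.filter_variants(decontam, thr.vaf_max)
        filtered = filtered[filtered["sample_id"].isin(passed)].reset_index(drop=True)

        self._write_tsv("qc_report.tsv", report)
        with open(self.outdir / "masked_sites.bed", "w") as fh:
            for pos in masked_pos:
                fh.write(f"{ref.chrom}\t{pos - 1}\t{pos}\n")
        self._write_tsv("variants_pass.tsv", filtered)
        io.write_coverage_dir(self.outdir / "coverage_masked", coverage_masked)

    def stage_annotation(self) -> None:
        ref = self._load_reference()
        variants = self._read_tsv("variants_pass.tsv")
        annotated = annotate.annotate_variants(variants, ref)
        self._write_tsv("variants_annotated.tsv", annotated)

    def _masked_coverage(self, ref) -> CoverageTrack:
        d = self.outdir / "coverage_masked"
        if d.exists():
            return io.read_coverage_dir(d, ref.chrom, ref.length)
        return self._load_coverage(ref)

    def stage_burden(self) -> None:
        ref = self._load_reference()
        coverage = self._masked_coverage(ref)
        meta = self._read_tsv("metadata.tsv")
        variants = self._read_tsv("variants_annotated.tsv")
        meta = meta[meta["sample_id"].isin(coverage.sample_ids)]
        burdens = burden.cohort_burdens(variants, coverage, ref, meta)
        self._write_tsv("burdens.tsv", burdens)

        fit = burden.fit_burden_regression(
            burdens, n_boot=200, seed=self.config.seed
        )
        io.write_json(
            self.outdir / "burden_regression.json",
            {
                "slope_per_year": fit.slope,
                "slope_ci": list(fit.slope_ci),
                "intercept": fit.intercept,
                "model_kind": fit.model_kind,
                "ages": fit.ages,
                "prediction": fit.prediction,
                "band_lo": fit.band_lo,
                "band_hi": fit.band_hi,
                "seed": self.config.seed,
                "config_hash": self.config.config_hash,
            },
        )

        spec = burden.spectrum_96(variants, ref, coverage)
        self._write_tsv("spectrum96.tsv", spec)
        catalog = burden.load_signature_catalog()
        expo = burden.fit_signature_exposures(spec["normalized"].to_numpy(), catalog)
        self._write_tsv(
            "signature_exposures.tsv",
            pd.DataFrame(
                {"signature": expo.signatures, "proportion": expo.weights,
                 "fitted_count": expo.counts}
            ),
        )

    def stage_dnds(self) -> None:
        ref = self._load_reference()
        coverage = self._masked_coverage(ref)
        variants = self._read_tsv("variants_annotated.tsv")
        opts = self.config.dnds
        model = selection.fit_context_rate_model(
            variants, ref, coverage,
            use_methylation=opts.get("use_methylation", True),
            use_pentanucleotide=opts.get("use_pentanucleotide", False),
        )
        obs = selection.observed_counts_by_gene(variants, ref)
        exp = selection.expected_counts_by_gene(model, ref, coverage)
        genes = selection.gene_dnds_test(obs, exp)
        self._write_tsv("gene_dnds.tsv", genes, index=True)

        glob = selection.global_dnds(obs, exp)
        io.write_json(
            self.outdir / "global_dnds.json",
            {
                "omega": glob.omega,
                "ci": list(glob.ci),
                "excess_fraction": glob.excess_fraction,
                "excess_count": glob.excess_count,
                "n_obs_nonsyn": glob.n_obs,
                "exp_nonsyn": glob.n_exp,
                "seed": self.config.seed,
                "config_hash": self.config.config_hash,
            },
        )
        hotspots = selection.sitewise_hotspot_test(variants, ref, model, coverage)
        self._write_tsv("hotspots.tsv", hotspots)

    def stage_disease(self) -> None:
        ref = self._load_reference()
        coverage = self._masked_coverage(ref)
        meta = self._read_tsv("metadata.tsv")
        variants = self._read_tsv("variants_annotated.tsv")
        genes = self._read_tsv("gene_dnds.tsv").set_index("gene_id")
        hotspots = self._read_tsv("hotspots.tsv")
        q_thr = self.config.dnds.get("q_threshold", 0.1)

        sel_table = selection.build_selection_gene_table(genes, q_threshold=q_thr)
        sig_hotspots = hotspots[hotspots["q"] < q_thr]
        # toy disease-gene table: configured driver genes act as monoallelic
        # absent-gene-product developmental-disorder genes
        truth_path = self.outdir / "truth.json"
        if truth_path.exists():
            truth = io.read_json(truth_path)
            dd = pd.DataFrame(
                {
                    "gene_id": list(truth["config"]["driver_genes"]),
                    "allelic_requirement": "monoallelic_autosomal",
                    "confidence": "definitive",
                    "mutation_consequence": "absent gene product",
                }
            )
        else:
            dd = None
        labelled = annotate.label_disease_and_driver(
            variants, None, dd, None, sel_table, sig_hotspots
        )
        self._write_tsv("variants_labelled.tsv", labelled)

        sample_ids = sorted(set(variants["sample_id"]))
        frames = []
        for cls, sel_kw in [
            ("synonymous", {"impact_classes": ["synonymous"]}),
            ("missense", {"impact_classes": ["missense"]}),
            ("lof", {"impact_classes": ["nonsense", "essential_splice", "frameshift_indel"]}),
            ("likely_disease", {"label_col": "likely_disease"}),
            ("likely_driver", {"label_col": "likely_driver"}),
        ]:
            frames.append(
                disease.sum_vaf_fraction(labelled, cls, sample_ids=sample_ids, **sel_kw)
            )
        fractions = pd.concat(frames, ignore_index=True).merge(
            meta[["sample_id", "age_years"]], on="sample_id"
        )
        self._write_tsv("cell_fractions.tsv", fractions)

        dis = fractions[fractions["variant_class"] == "likely_disease"]
        if dis["observed_fraction"].max() <= 1:
            fit = disease.fit_fraction_regression(dis)
            io.write_json(
                self.outdir / "disease_fraction_regression.json",
                {
                    "slope": fit.slope,
                    "slope_p": fit.slope_p,
                    "predictions": fit.predictions.to_dict("list"),
                },
            )

    def stage_report(self) -> None:
        q_thr = self.config.dnds.get("q_threshold", 0.1)
        genes = self._read_tsv("gene_dnds.tsv")
        glob = io.read_json(self.outdir / "global_dnds.json")
        reg = io.read_json(self.outdir / "burden_regression.json")
        qc_rep = self._read_tsv("qc_report.tsv")
        fractions = self._read_tsv("cell_fractions.tsv")

        sig = genes[genes["q_gene"] < q_thr].sort_values("q_gene")
        by_class = (
            fractions.groupby("variant_class")["observed_fraction"].mean().to_dict()
        )
        summary = {
            "n_samples_pass": int(qc_rep["pass"].sum()),
            "n_samples_fail": int((~qc_rep["pass"]).sum()),
            "burden_slope_per_year": reg["slope_per_year"],
            "burden_slope_ci": reg["slope_ci"],
            "global_omega": glob["omega"],
            "global_omega_ci": glob["ci"],
            "excess_fraction": glob["excess_fraction"],
            "significant_genes": sig["gene_id"].tolist(),
            "mean_cell_fraction_by_class": by_class,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash,
        }
        io.write_json(self.outdir / "report.json", summary)

        lines = [
            "germselect run report",
            f"seed={self.config.seed} config={self.config.config_hash}",
            "",
            f"Samples passing QC: {summary['n_samples_pass']} "
            f"(failed: {summary['n_samples_fail']})",
            f"Burden slope: {reg['slope_per_year']:.3g} per year "
            f"(95% CI {reg['slope_ci'][0]:.3g}-{reg['slope_ci'][1]:.3g}, "
            f"{reg['model_kind']})",
            f"Global dN/dS: {glob['omega']:.3f} "
            f"(95% CI {glob['ci'][0]:.3f}-{glob['ci'][1]:.3f}); "
            f"excess nonsynonymous fraction {100 * glob['excess_fraction']:.1f}%",
            f"Genes significant at q<{q_thr}: "
            + (", ".join(summary["significant_genes"]) or "none"),
            "",
            "Mean cell fraction by class:",
        ]
        for cls, val in by_class.items():
            lines.append(f"  {cls}: {val:.4g}")
        (self.outdir / "report.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in dependency order."""
    if stages is None:
        if config.mode == "simulate":
            stages = ["simulate"]
        else:
            stages = STAGES
    stages = [s for s in STAGES if s in stages]
    config.validate(stages)
    run = PipelineRun(config)
    if config.mode == "analyze":
        stages = [s for s in stages if s != "simulate"]
        run.stage_import_inputs()
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            getattr(run, f"stage_{stage}")()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return run.outdir


def write_report(run_dir: str | Path) -> Path:
    """Regenerate the consolidated report from an existing run directory."""
    run_dir = Path(run_dir)
    if not (run_dir / "gene_dnds.tsv").exists():
        raise ConfigurationError(f"no pipeline outputs in {run_dir}")
    cfg = RunConfig(outdir=str(run_dir))
    PipelineRun(cfg).stage_report()
    return run_dir / "report.txt"
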