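"""End-to-end orchestration: catalog → ingest → popstats → concord →
annotate → report, driven by one TOML/JSON config.

Stages whose inputs are absent are skipped with a logged notice.  Every run
writes a machine-readable manifest (parameters and input checksums) and a
summary report; both are deterministically serialized so identical configs
and inputs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, annotate, concordance, genotype_io, population_stats
from .repeat_catalog import (
    AlignParams,
    DetectionParams,
    build_catalog,
    canonical_motif_frames,
    write_bed,
    write_variant_catalog,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    fasta: str | None = None
    vcf: str | None = None
    vcf_b: str | None = None
    gff3: str | None = None
    panel: str | None = None
    universe: str | None = None
    scores: str | None = None
    motif: str = "CGG"
    seed: int = 0
    flank_bp: int = 1000
    hi_cutoff: float = 40.0
    pli_cutoff: float = 0.75
    log_level: str = "INFO"
    detection: DetectionParams = field(default_factory=DetectionParams)
    alignment: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if self.flank_bp <= 0 or self.hi_cutoff <= 0 or self.pli_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        for name in ("fasta", "vcf", "vcf_b", "gff3", "panel", "universe", "scores"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".json":
            raw = json.loads(path.read_text())
        else:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        det = DetectionParams(**raw.pop("detection", {}))
        aln = AlignParams(**raw.pop("alignment", {}))
        return cls(detection=det, alignment=aln, **raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all runnable stages and return the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "stages": []}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "detection": dataclasses.asdict(config.detection),
        "alignment": dataclasses.asdict(config.alignment),
        "motif": config.motif,
        "flank_bp": config.flank_bp,
        "inputs": {},
    }
    for name in ("fasta", "vcf", "vcf_b", "gff3", "panel", "universe", "scores"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    loci = None
    if config.fasta:
        try:
            motif_class = canonical_motif_frames(config.motif)
            loci = build_catalog(config.fasta, motif_class, config.detection, config.alignment)
            write_bed(loci, out / "catalog.bed")
            write_variant_catalog(loci, out / "catalog.json")
        except Exception as exc:
            raise StageError("catalog", exc) from exc
        summary["stages"].append("catalog")
        summary["n_loci_detected"] = len(loci)
    else:
        logger.info("no FASTA configured; skipping catalog stage")

    callset = None
    if config.vcf:
        try:
            callset = genotype_io.read_str_vcf(config.vcf)
            kept, excluded = genotype_io.exclude_uncovered_loci(callset)
            genotype_io.write_call_table(callset, out / "calls.tsv")
        except Exception as exc:
            raise StageError("ingest", exc) from exc
        summary["stages"].append("ingest")
        summary["n_samples"] = len(callset.samples)
        summary["n_loci_genotyped"] = len(callset.loci)
        summary["n_loci_excluded"] = len(excluded)
        summary["excluded_loci"] = sorted([list(x) for x in excluded])
        summary["allele_call_rate"] = round(
            genotype_io.allele_call_rate(callset, kept), 6
        )

        try:
            kept_calls = genotype_io.CallSet(
                samples=callset.samples,
                loci=kept,
                calls={k: v for k, v in callset.calls.items() if k[1] in set(kept)},
            )
            summaries, no_data = population_stats.summarize_callset(kept_calls)
            population_stats.write_locus_summaries(summaries, out / "locus_summary.tsv")
            sample_summaries = [
                population_stats.summarize_sample(s, kept_calls, summaries)
                for s in kept_calls.samples
            ]
            population_stats.write_sample_summaries(sample_summaries, out / "sample_summary.tsv")
            population_stats.deviation_table(kept_calls, summaries).to_csv(
                out / "deviation.tsv", sep="\t", index=False
            )
        except Exception as exc:
            raise StageError("popstats", exc) from exc
        summary["stages"].append("popstats")
        n_poly = sum(1 for s in summaries.values() if s.polymorphic)
        summary["n_loci_summarized"] = len(summaries)
        summary["n_loci_no_data"] = len(no_data)
        summary["n_polymorphic_loci"] = n_poly
        summary["polymorphic_fraction"] = round(n_poly / len(summaries), 6) if summaries else None
    else:
        logger.info("no VCF configured; skipping ingest/popstats stages")

    if config.vcf and config.vcf_b:
        try:
            callset_b = genotype_io.read_str_vcf(config.vcf_b)
            comp = concordance.concordance_summary(callset, callset_b)
            concordance.write_records(comp.records, out / "concordance_records.tsv")
            concordance.write_summary(comp, out / "concordance.json")
        except Exception as exc:
            raise StageError("concord", exc) from exc
        summary["stages"].append("concord")
        summary["concordance_consistency"] = round(comp.consistency, 6)

    if config.gff3 and loci is not None:
        try:
            genes = annotate.load_gene_models_gff3(config.gff3)
            annotated = annotate.annotate_loci(loci, genes, config.flank_bp)
            annotate.write_annotated_loci(annotated, out / "annotated_loci.tsv")
            assoc = annotate.gene_association_table(annotated, genes)
            assoc.to_csv(out / "gene_association.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("annotate", exc) from exc
        summary["stages"].append("annotate")
        region_counts: dict[str, int] = {}
        for al in annotated:
            region_counts[al.region] = region_counts.get(al.region, 0) + 1
        summary["region_counts"] = region_counts

        if config.panel and config.universe:
            try:
                panel = set(Path(config.panel).read_text().split())
                universe = set(Path(config.universe).read_text().split())
                repeat_genes = set(assoc.loc[assoc["any_repeat"], "gene"]) & universe
                result = annotate.enrichment_chi2(repeat_genes, panel & universe, universe)
                annotate.write_enrichment(result, out / "enrichment.json")
            except Exception as exc:
                raise StageError("enrichment", exc) from exc
            summary["stages"].append("enrichment")
            summary["enrichment_chi2"] = round(result.chi2, 6)
            summary["enrichment_p"] = result.p_value
    elif config.gff3:
        logger.info("gene models configured but no catalog; skipping annotate stage")

    _dump_json(manifest, out / "manifest.json")
    _dump_json(summary, out / "summary.json")
    return summary
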