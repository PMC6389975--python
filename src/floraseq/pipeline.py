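"""End-to-end orchestration: counts -> FPKM -> SDEGs -> homolog assignment ->
annotation transfer -> enrichment -> Jaccard / correlation / clustering
reports, from one configuration, with a reproducible JSON manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import yaml

from . import enrichment as enr
from . import expression as expr
from . import homology as hom
from . import sdeg as sdegmod
from . import similarity as sim
from .errors import ContractError, PipelineError

log = logging.getLogger(__name__)


class AnnotationRate(NamedTuple):
    """Percentage of genes related to a homolog, raw and rounded."""

    raw: float
    rounded: int

    @property
    def formatted(self) -> str:
        return f"{self.rounded}%"


def report_annotation_rate(n_assigned: int, n_total: int) -> AnnotationRate:
    """100 * n_assigned / n_total, raw and rounded to the nearest percent."""
    if n_total <= 0:
        raise ContractError("n_total must be > 0")
    if not (0 <= n_assigned <= n_total):
        raise ContractError("n_assigned must lie in [0, n_total]")
    raw = 100.0 * n_assigned / n_total
    return AnnotationRate(raw=raw, rounded=int(round(raw)))


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds, and output directory.

    The defaults house the published constants: FPKM > 5 and > 5-fold for
    SDEGs, E < 1e-20 for one-to-one homologs, FDR q = 0.01 for the enrichment
    significance level, FPKM > 100 for the clustering heatmap.
    """

    counts: str = "counts.tsv"
    metadata: str = "samples.tsv"
    blast: str = "blast_hits.tsv"
    go_terms: str = "go_terms.tsv"
    pathway_terms: str = "pathway_terms.tsv"
    output_dir: str = "results"
    fpkm_threshold: float = 5.0
    fold_threshold: float = 5.0
    e_cutoff: float = 1e-20
    fdr_q: float = 0.01
    heatmap_fpkm_floor: float = 100.0
    pseudocount: float = 1.0
    contrasts: list[dict] | None = None  # [{organ, stage, sex_a, sex_b}, ...]; None = derive all
    seed: int = 0

    def __post_init__(self):
        for name in ("fpkm_threshold", "fold_threshold", "e_cutoff", "fdr_q",
                     "heatmap_fpkm_floor", "pseudocount"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write every report plus manifest.json to the output
    directory and return the manifest.  A stage failure raises PipelineError
    naming the stage."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise PipelineError(name, str(exc)) from exc

    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": {},
        "stages": {},
    }
    inputs = {
        "counts": Path(config.counts),
        "metadata": Path(config.metadata),
        "blast": Path(config.blast),
        "go_terms": Path(config.go_terms),
        "pathway_terms": Path(config.pathway_terms),
    }

    def checksum_inputs():
        for key, p in inputs.items():
            if not p.is_file():
                raise FileNotFoundError(f"input '{key}' not found: {p}")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    stage("inputs", checksum_inputs)

    cm = stage("load_counts", lambda: expr.read_counts(config.counts, config.metadata))
    manifest["stages"]["load_counts"] = {"n_genes": len(cm.gene_ids), "n_samples": len(cm.sample_ids)}
    log.info("loaded %d genes x %d samples", len(cm.gene_ids), len(cm.sample_ids))

    em = stage("fpkm", lambda: expr.compute_fpkm(cm))

    def write_fpkm():
        em.values.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id", float_format="%.6g")

    stage("fpkm", write_fpkm)

    def do_sdeg():
        if config.contrasts:
            contrasts = [sdegmod.Contrast(**c) for c in config.contrasts]
        else:
            contrasts = sdegmod.derive_contrasts(cm.samples)
        sets: list[sdegmod.SDEGSet] = []
        for c in contrasts:
            sets.extend(
                sdegmod.extract_sdegs(em, c, config.fpkm_threshold, config.fold_threshold)
            )
        sdegmod.write_sdeg_sets(sets, outdir / "sdeg_sets.tsv")
        jm = sdegmod.jaccard_matrix(sets)
        jm.to_csv(outdir / "jaccard.tsv", sep="\t", index_label="set_name", float_format="%.6g")
        return sets

    sdeg_sets = stage("sdeg", do_sdeg)
    manifest["stages"]["sdeg"] = {s.name: len(s) for s in sdeg_sets}
    for s in sdeg_sets:
        log.info("SDEG set %s: %d genes", s.name, len(s))

    def do_homology():
        hits = hom.read_blast_tab(config.blast)
        m = hom.assign_one_to_one(hits, e_cutoff=config.e_cutoff)
        hom.write_one_to_one(m, outdir / "one_to_one.tsv")
        return m

    one2one = stage("homology", do_homology)
    rate = report_annotation_rate(len(one2one), len(cm.gene_ids))
    manifest["stages"]["homology"] = {
        "n_assigned": len(one2one),
        "annotation_rate_raw_pct": round(rate.raw, 4),
        "annotation_rate": rate.formatted,
    }
    log.info("one-to-one homologs: %d of %d genes (%s)", len(one2one), len(cm.gene_ids), rate.formatted)

    def do_enrichment(kind: str, assoc_path: str):
        protein_terms = hom.read_term_associations(assoc_path)
        gene_terms = hom.transfer_annotations(one2one, protein_terms)
        bg = enr.build_background(gene_terms, em, fpkm_floor=config.fpkm_threshold)
        res = enr.enrich_sets(sdeg_sets, gene_terms, bg, q=config.fdr_q)
        res.to_frame().to_csv(outdir / f"enrichment_{kind}.tsv", sep="\t", index=False, float_format="%.6g")
        return res

    res_go = stage("enrichment_go", lambda: do_enrichment("go", config.go_terms))
    res_pwy = stage("enrichment_pathway", lambda: do_enrichment("pathway", config.pathway_terms))
    manifest["stages"]["enrichment"] = {
        "alpha_go": res_go.alpha,
        "alpha_pathway": res_pwy.alpha,
        "n_records_go": len(res_go.records),
        "n_records_pathway": len(res_pwy.records),
    }
    log.info("significance levels: GO alpha=%g, pathway alpha=%g", res_go.alpha, res_pwy.alpha)

    def do_similarity():
        corr = sim.pearson_matrix(em)
        corr.to_csv(outdir / "correlation.tsv", sep="\t", index_label="sample_id", float_format="%.6g")
        high = expr.filter_min_fpkm(em, config.heatmap_fpkm_floor, mode="any_sample")
        logged = expr.log_transform(high, pseudocount=config.pseudocount)
        n_high = logged.shape[0]
        if n_high >= 2:
            gene_link = sim.hcluster(sim.manhattan_log_distance(logged, axis="genes"), "group_average")
            (outdir / "gene_dendrogram.nwk").write_text(gene_link.to_newick() + "\n")
        sample_link = sim.hcluster(sim.manhattan_log_distance(logged, axis="samples"), "ward")
        (outdir / "sample_dendrogram.nwk").write_text(sample_link.to_newick() + "\n")
        sim.normalize_for_heatmap(logged).to_csv(
            outdir / "heatmap_matrix.tsv", sep="\t", index_label="gene_id", float_format="%.6g"
        )
        return n_high

    n_heatmap_genes = stage("similarity", do_similarity)
    manifest["stages"]["similarity"] = {"n_heatmap_genes": n_heatmap_genes}

    def finalize():
        for p in sorted(outdir.iterdir()):
            if p.name == "manifest.json" or not p.is_file():
                continue
            manifest["outputs"][p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    stage("manifest", finalize)
    return manifest
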