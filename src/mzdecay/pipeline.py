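"""End-to-end orchestration: profiles -> significance -> kinetics ->
classification -> enrichment / motif landscapes, with a reproducibility
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .classify import ClassifyConfig, classify_dataset, PRELOADED_CLASSES
from .enrichment import enrichment_grid, grid_to_matrix
from .io import read_expression, read_fasta, read_gmt
from .kinetics import compute_kinetics, net_decay
from .matrix import ExpressionMatrix
from .motifs import top_motifs, word_landscape
from .profiles import cluster_samples, default_detection_threshold, summarize_replicates

logger = logging.getLogger("mzdecay")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    matrix_path: str
    design_path: str
    out_dir: str
    gene_sets_path: str | None = None
    utr_fasta_path: str | None = None
    run_motifs: bool = False
    fdr: float = 0.10
    min_effect: float = 0.5
    detection_threshold: float | None = None
    dt_min: float = 60.0
    k_word: int = 6
    n_bins: int = 40
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError(f"fdr must be in (0, 1], got {self.fdr}")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        for label, path in (("matrix", self.matrix_path), ("design", self.design_path)):
            if not Path(path).exists():
                raise ValueError(f"{label} file not found: {path}")
        if self.gene_sets_path and not Path(self.gene_sets_path).exists():
            raise ValueError(f"gene sets file not found: {self.gene_sets_path}")
        if self.run_motifs:
            if not self.utr_fasta_path:
                raise ValueError("motifs stage requested but no UTR FASTA configured")
            if not Path(self.utr_fasta_path).exists():
                raise ValueError(f"UTR FASTA not found: {self.utr_fasta_path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("[%s] running", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary.

    Outputs are written as TSV under ``out_dir`` together with a JSON
    manifest recording package version, parameters, input checksums and
    the produced files.  Given identical inputs and configuration the
    stage outputs are byte-identical across reruns.
    """
    config.validate()
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    matrix = _stage("load")(read_expression)(config.matrix_path, config.design_path)

    @_stage("profiles")
    def stage_profiles(matrix: ExpressionMatrix):
        threshold = config.detection_threshold
        if threshold is None:
            threshold = default_detection_threshold(matrix)
        profiles = summarize_replicates(matrix, detection_threshold=threshold)
        clustering = cluster_samples(matrix, k=6)
        return profiles, clustering, threshold

    profiles, clustering, threshold = stage_profiles(matrix)
    profiles.to_csv(out / "profiles.tsv", sep="\t")
    outputs["profiles"] = "profiles.tsv"
    clustering.labels.to_csv(out / "sample_clusters.tsv", sep="\t")
    outputs["sample_clusters"] = "sample_clusters.tsv"

    @_stage("classify")
    def stage_classify(matrix):
        cfg = ClassifyConfig(
            fdr=config.fdr,
            min_effect=config.min_effect,
            detection_threshold=threshold,
        )
        return classify_dataset(matrix, cfg)

    calls, summary = stage_classify(matrix)
    calls.to_csv(out / "calls.tsv", sep="\t")
    summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    outputs["calls"] = "calls.tsv"
    outputs["class_summary"] = "class_summary.tsv"

    @_stage("kinetics")
    def stage_kinetics():
        return compute_kinetics(profiles, calls["class_label"], dt_min=config.dt_min)

    kin = stage_kinetics()
    kin.to_csv(out / "kinetics.tsv", sep="\t")
    outputs["kinetics"] = "kinetics.tsv"

    if config.gene_sets_path:

        @_stage("enrich")
        def stage_enrich():
            collections = read_gmt(config.gene_sets_path)
            classified = calls["class_label"].isin(PRELOADED_CLASSES)
            universe = set(calls.index[classified])
            class_genes = {
                label: set(calls.index[calls["class_label"] == label])
                for label in sorted(calls.loc[classified, "class_label"].unique())
            }
            return enrichment_grid(class_genes, collections, universe, fdr=config.fdr)

        grid = stage_enrich()
        grid.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        grid_to_matrix(grid).to_csv(out / "enrichment_log2or.tsv", sep="\t")
        outputs["enrichment"] = "enrichment.tsv"
        outputs["enrichment_log2or"] = "enrichment_log2or.tsv"

    if config.run_motifs:

        @_stage("motifs")
        def stage_motifs():
            utrs = read_fasta(config.utr_fasta_path)
            nd = net_decay(profiles, late="E3")
            ranked = [g for g in nd.sort_values().index if g in utrs]
            usable = {g: utrs[g] for g in ranked if len(utrs[g]) >= config.k_word}
            ranked = [g for g in ranked if g in usable]
            landscape = word_landscape(ranked, usable, k=config.k_word, nbins=config.n_bins)
            return landscape

        landscape = stage_motifs()
        landscape.to_frame().to_csv(out / "word_landscape.tsv", sep="\t")
        top_motifs(landscape, n=5).to_csv(out / "top_motifs.tsv", sep="\t", index=False)
        outputs["word_landscape"] = "word_landscape.tsv"
        outputs["top_motifs"] = "top_motifs.tsv"

    manifest = {
        "mzdecay_version": __version__,
        "parameters": {
            "fdr": config.fdr,
            "min_effect": config.min_effect,
            "detection_threshold": threshold,
            "dt_min": config.dt_min,
            "k_word": config.k_word,
            "n_bins": config.n_bins,
            "seed": config.seed,
        },
        "inputs": {
            "matrix": {"path": str(config.matrix_path), "sha256": _sha256(config.matrix_path)},
            "design": {"path": str(config.design_path), "sha256": _sha256(config.design_path)},
        },
        "outputs": outputs,
    }
    if config.gene_sets_path:
        manifest["inputs"]["gene_sets"] = {
            "path": str(config.gene_sets_path),
            "sha256": _sha256(config.gene_sets_path),
        }
    if config.run_motifs:
        manifest["inputs"]["utr_fasta"] = {
            "path": str(config.utr_fasta_path),
            "sha256": _sha256(config.utr_fasta_path),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
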