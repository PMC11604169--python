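"""End-to-end orchestration: regions -> count -> test -> peaks -> genes -> GO -> plots.

Every stage writes its table to the output directory and records a
SHA-256 hash of each input and output file in a JSON provenance
manifest.  Identical inputs and configuration therefore produce an
identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import counting, dm_testing, gatc_index, gene_annotation, go_testing, peak_calling, viz

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str = ""
    samplesheet: str = ""
    gff: str = ""
    categories: str = ""
    outdir: str = "damid_out"
    max_region_width: int = 10_000
    min_cpm: float = 0.5
    p_threshold: float = 0.01
    lfc_threshold: float = 1.0
    gap_bp: int = 150
    go_window: int = 2000
    max_gene_distance: int = 5000
    min_mapq: int = 10
    count_unit: str = "read"
    replicate_factor: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("max_region_width", "p_threshold", "lfc_threshold", "gap_bp",
                     "go_window", "max_gene_distance"):
            if getattr(self, name) <= 0:
                raise gatc_index.ConfigError(f"{name} must be positive")
        if self.min_cpm < 0:
            raise gatc_index.ConfigError("min_cpm must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise gatc_index.ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the provenance manifest (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # regions
    def _regions():
        sites = gatc_index.scan_motifs(config.fasta)
        from pyfaidx import Fasta

        fa = Fasta(config.fasta)
        lengths = {name: len(fa[name]) for name in fa.keys()}
        regions = gatc_index.build_regions(sites, lengths)
        bed = out / "regions.bed"
        gatc_index.write_regions(regions, bed, "bed")
        record("regions", [Path(config.fasta)], [bed])
        return regions

    regions = stage("regions", _regions)

    # counting
    def _count():
        samples = counting.read_samplesheet(config.samplesheet)
        matrix = counting.count_regions(
            regions, samples, min_mapq=config.min_mapq, count_unit=config.count_unit
        )
        counts_path = out / "counts.tsv"
        matrix.to_frame().to_csv(counts_path, sep="\t", index=False)
        qc = counting.qc_report(matrix)
        qc_path = out / "qc_samples.tsv"
        qc["samples"].to_csv(qc_path, sep="\t", index=False)
        qc["correlations"].to_csv(out / "qc_correlations.tsv", sep="\t")
        record("count", [Path(config.samplesheet)] + [Path(s.bam_path) for s in samples],
               [counts_path, qc_path])
        return matrix

    matrix = stage("count", _count)

    # testing
    def _test():
        cfg = dm_testing.FilterConfig(
            max_region_width=config.max_region_width, min_cpm=config.min_cpm
        )
        kept, removed = dm_testing.filter_regions(matrix, cfg)
        factors = dm_testing.tmm_factors(kept)
        fits = dm_testing.fit_ql_nb(
            kept, factors, dm_testing.DesignSpec(replicate_factor=config.replicate_factor)
        )
        results = dm_testing.test_regions(
            fits, config.p_threshold, config.lfc_threshold, removed=removed
        )
        dm_path = out / "dm.tsv"
        results.to_csv(dm_path, sep="\t", index=False)
        record("test", [out / "counts.tsv"], [dm_path])
        return results

    results = stage("test", _test)

    # peaks
    def _peaks():
        peaks = peak_calling.call_peaks(results, gap_bp=config.gap_bp)
        path = out / "peaks.tsv"
        peak_calling.write_peaks(peaks, path)
        record("peaks", [out / "dm.tsv"], [path])
        return peaks

    peaks = stage("peaks", _peaks)

    # genes
    def _genes():
        genes = gene_annotation.load_genes(config.gff)
        table = gene_annotation.annotate_peaks(
            peaks, genes, max_distance_bp=config.max_gene_distance
        )
        path = out / "peak_genes.tsv"
        table.to_csv(path, sep="\t", index=False)
        record("genes", [Path(config.gff), out / "peaks.tsv"], [path])
        return genes, table

    genes, peak_genes = stage("genes", _genes)

    # GO
    def _go():
        if not config.categories:
            logger.info("no category file configured; skipping GO stage")
            return None
        cat_map = go_testing.read_categories(config.categories)
        bias = go_testing.compute_bias(genes, regions, window_bp=config.go_window)
        records = go_testing.make_records(peak_genes, genes, bias)
        try:
            pwf = go_testing.fit_pwf(records)
        except gatc_index.InputError as exc:
            logger.warning("GO stage skipped: %s", exc)
            return None
        go_table = go_testing.test_categories(records, pwf, cat_map)
        path = out / "go.tsv"
        go_table.to_csv(path, sep="\t", index=False)
        record("go", [Path(config.categories)], [path])
        return go_table

    stage("go", _go)

    # plots
    def _plots():
        qc_path = out / "qc_depth.svg"
        viz.plot_qc(matrix, results, peaks, qc_path)
        outputs = [qc_path]
        if peaks:
            top = min(peaks, key=lambda p: p.rank)
            span = max(top.end - top.start, 2000)
            window = (max(0, top.start - span), top.end + span)
            track_path = out / "top_peak.svg"
            viz.plot_region(
                top.chrom, window[0], window[1], track_path,
                matrix=matrix, dm_results=results, peaks=peaks,
                regions=regions, genes=genes,
            )
            outputs.append(track_path)
        record("plots", [], outputs)

    stage("plots", _plots)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
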