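"""Read/fragment counting over GATC regions from coordinate-sorted BAM files.

Each usable alignment unit (a single-end read, or a properly paired
fragment spanning the full template) is assigned to exactly one region by
largest overlap, with ties broken to the leftmost region.  Because GATC
regions tile each chromosome, an overlap-based single assignment avoids
double counting across the dense tiling.  Unmapped, secondary,
supplementary, QC-fail and sub-MAPQ records are excluded; duplicates are
kept, since PCR amplification of methylated fragments is part of the
DamID signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .gatc_index import ConsistencyError, GatcRegion, InputError

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 10


@dataclass
class SampleInfo:
    sample_id: str
    bam_path: str | Path
    group: str  # "Dam" or "Fusion"
    replicate: int
    paired: bool = False
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.group not in {"Dam", "Fusion"}:
            raise ValueError(f"group must be 'Dam' or 'Fusion', got {self.group!r}")


@dataclass
class RegionCountMatrix:
    """Integer counts with shape (n_regions, n_samples) plus metadata."""

    regions: list[GatcRegion]
    samples: list[SampleInfo]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape does not match regions x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": self.region_ids,
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "width": [r.width for r in self.regions],
            }
        )
        for j, s in enumerate(self.samples):
            df[s.sample_id] = self.counts[:, j]
        return df


def read_samplesheet(path: str | Path) -> list[SampleInfo]:
    """Read a TSV samplesheet with columns sample_id, bam, group, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "bam", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"samplesheet missing columns: {sorted(missing)}")
    return [
        SampleInfo(
            sample_id=str(row.sample_id),
            bam_path=row.bam,
            group=str(row.group),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def _assign_unit(
    starts: np.ndarray, ends: np.ndarray, unit_start: int, unit_end: int
) -> int:
    """Index of the region with the largest overlap with [unit_start, unit_end).

    ``starts``/``ends`` are the sorted region bounds of one chromosome.
    Returns -1 if the unit overlaps no region.  Ties go to the leftmost
    region.
    """
    lo = int(np.searchsorted(ends, unit_start, side="right"))
    hi = int(np.searchsorted(starts, unit_end, side="left"))
    if lo >= hi:
        return -1
    overlaps = np.minimum(ends[lo:hi], unit_end) - np.maximum(starts[lo:hi], unit_start)
    return lo + int(np.argmax(overlaps))  # argmax takes first max -> leftmost


def count_regions(
    regions: list[GatcRegion],
    samples: list[SampleInfo],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    count_unit: str = "read",
) -> RegionCountMatrix:
    """Count reads or fragments per GATC region for every sample.

    ``count_unit`` is ``"read"`` (each passing alignment counted once) or
    ``"fragment"`` (each properly paired template counted once using its
    full TLEN-derived span; orphan or discordant mates fall back to
    single-read counting and are logged).
    """
    if count_unit not in {"read", "fragment"}:
        raise ValueError(f"count_unit must be 'read' or 'fragment', got {count_unit!r}")

    region_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx_arr = np.array(sorted(idx, key=lambda i: regions[i].start))
        starts = np.array([regions[i].start for i in idx_arr])
        ends = np.array([regions[i].end for i in idx_arr])
        region_index[chrom] = (starts, ends, idx_arr)

    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        bam_path = Path(sample.bam_path)
        try:
            bam = pysam.AlignmentFile(str(bam_path), "rb")
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot open BAM {bam_path}: {exc}") from exc
        if not bam.has_index():
            raise InputError(f"BAM {bam_path} has no index (.bai)")

        bam_chroms = set(bam.references)
        missing = sorted(set(region_index) - bam_chroms)
        if missing:
            raise ConsistencyError(
                f"BAM {bam_path} header is missing region chromosomes: {missing}"
            )

        n_orphan = 0
        total = 0
        for chrom, (starts, ends, idx_arr) in region_index.items():
            for aln in bam.fetch(chrom):
                if (
                    aln.is_unmapped
                    or aln.is_secondary
                    or aln.is_supplementary
                    or aln.is_qcfail
                    or aln.mapping_quality < min_mapq
                ):
                    continue
                if count_unit == "fragment" and aln.is_paired:
                    if aln.is_proper_pair and aln.template_length != 0:
                        # count the template once, at its leftmost read
                        if aln.template_length < 0:
                            continue
                        unit_start = aln.reference_start
                        unit_end = aln.reference_start + aln.template_length
                    else:
                        n_orphan += 1
                        unit_start = aln.reference_start
                        unit_end = aln.reference_end
                else:
                    unit_start = aln.reference_start
                    unit_end = aln.reference_end
                k = _assign_unit(starts, ends, unit_start, unit_end)
                if k >= 0:
                    counts[idx_arr[k], j] += 1
                    total += 1
        bam.close()
        if n_orphan:
            logger.info(
                "%s: %d orphan/discordant mate(s) counted as single reads",
                sample.sample_id,
                n_orphan,
            )
        sample.library_size = int(total)
        if total == 0:
            logger.warning("sample %s has zero usable counted units", sample.sample_id)

    return RegionCountMatrix(regions=regions, samples=samples, counts=counts)


def qc_report(matrix: RegionCountMatrix) -> dict[str, pd.DataFrame]:
    """Per-sample QC totals and pairwise Pearson correlations of log1p counts.

    Returns ``{"samples": ..., "correlations": ...}``.  A sample with zero
    variance yields NA correlations rather than an error.
    """
    if len(matrix.regions) == 0 or len(matrix.samples) == 0:
        raise InputError("empty count matrix")
    totals = matrix.counts.sum(axis=0)
    nonzero = (matrix.counts > 0).sum(axis=0)
    sample_df = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": [s.group for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
            "total_counts": totals,
            "n_regions_nonzero": nonzero,
        }
    )
    logc = np.log1p(matrix.counts.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = pd.DataFrame(logc, columns=matrix.sample_ids).corr(method="pearson")
    return {"samples": sample_df, "correlations": corr}
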