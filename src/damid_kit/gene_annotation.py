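"""Associate peaks with candidate target genes.

In compact genomes such as *Drosophila*, genes overlap extensively and
the closest gene is not necessarily the functional target, so every peak
is reported with a ranked list of candidates: all genes overlapping the
peak span, plus all genes whose transcription start site lies within a
configurable distance of the peak midpoint.  Distances are signed, from
the peak midpoint to the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .gatc_index import InputError
from .peak_calling import Peak

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE_BP = 5000


@dataclass(frozen=True)
class GeneModel:
    """A gene span; coordinates 0-based half-open, TSS strand-aware."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def load_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 or GTF (plain or gzipped).

    Features of type ``gene`` are used; if none exist, transcripts are
    unioned per gene_id.  1-based inclusive file coordinates are
    converted to 0-based half-open.  Duplicate gene ids are merged to
    their union span with a warning.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"gene model file {path} is missing or empty")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise InputError(f"cannot parse gene models from {path}: {exc}") from exc

    def _gene_id(feature) -> str:
        for key in ("gene_id", "ID", "Name"):
            if key in feature.attributes:
                return feature.attributes[key][0]
        return feature.id

    def _gene_name(feature) -> str:
        for key in ("gene_name", "Name"):
            if key in feature.attributes:
                return feature.attributes[key][0]
        return _gene_id(feature)

    spans: dict[str, GeneModel] = {}
    features = list(db.features_of_type("gene"))
    if not features:
        # fall back to the union of transcript-level features per gene_id
        for ftype in ("mRNA", "transcript"):
            features.extend(db.features_of_type(ftype))
    if not features:
        raise InputError(f"no gene or transcript features found in {path}")

    for feat in features:
        gid = _gene_id(feat)
        start0, end0 = feat.start - 1, feat.end
        if gid in spans:
            prev = spans[gid]
            logger.warning("duplicate gene id %s merged to union span", gid)
            spans[gid] = GeneModel(
                gid, prev.gene_name, prev.chrom,
                min(prev.start, start0), max(prev.end, end0), prev.strand,
            )
        else:
            spans[gid] = GeneModel(
                gid, _gene_name(feat), feat.seqid, start0, end0,
                feat.strand if feat.strand in "+-" else "+",
            )
    return sorted(spans.values(), key=lambda g: (g.chrom, g.start))


def annotate_peaks(
    peaks: list[Peak],
    genes: list[GeneModel],
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
) -> pd.DataFrame:
    """Candidate target genes per peak, ranked by proximity.

    Candidates are genes overlapping the peak span plus genes with
    |midpoint - TSS| <= ``max_distance_bp``.  Candidate rank 1 is the
    smallest absolute distance, with overlapping genes ranked before
    non-overlapping ones.  Peaks without any candidate get an explicit
    ``none`` row.
    """
    trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        tss_by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for peak in peaks:
        mid = (peak.start + peak.end) // 2
        cands: dict[str, tuple[GeneModel, str]] = {}
        tree = trees.get(peak.chrom)
        if tree is not None:
            for iv in tree.overlap(peak.start, peak.end):
                cands[iv.data.gene_id] = (iv.data, "overlap")
        for g in tss_by_chrom.get(peak.chrom, []):
            if g.gene_id in cands:
                continue
            if abs(mid - g.tss) <= max_distance_bp:
                relation = "upstream" if g.tss > mid else "downstream"
                cands[g.gene_id] = (g, relation)

        if not cands:
            rows.append(
                {
                    "peak_id": peak.peak_id, "chrom": peak.chrom,
                    "peak_start": peak.start, "peak_end": peak.end,
                    "peak_rank": peak.rank, "rep_p": peak.rep_p,
                    "gene_id": "none", "gene_name": "none", "strand": ".",
                    "relation": "none", "distance_bp": pd.NA, "candidate_rank": pd.NA,
                }
            )
            continue

        entries = []
        for g, relation in cands.values():
            if relation == "overlap" and g.start <= mid < g.end:
                dist = 0
            else:
                dist = g.tss - mid
            entries.append((g, relation, dist))
        entries.sort(key=lambda t: (t[1] != "overlap", abs(t[2]), t[0].gene_id))
        for rank, (g, relation, dist) in enumerate(entries, start=1):
            rows.append(
                {
                    "peak_id": peak.peak_id, "chrom": peak.chrom,
                    "peak_start": peak.start, "peak_end": peak.end,
                    "peak_rank": peak.rank, "rep_p": peak.rep_p,
                    "gene_id": g.gene_id, "gene_name": g.gene_name,
                    "strand": g.strand, "relation": relation,
                    "distance_bp": dist, "candidate_rank": rank,
                }
            )
    return pd.DataFrame(rows)
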