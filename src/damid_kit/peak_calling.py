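"""Peak calling: merge runs of significant GATC regions under the gap rule.

Adjacent significant regions are likely products of the same binding
event, so significant (``Upreg``) regions are merged left to right: if
the genomic gap between the end of the open peak and the start of the
next significant region is strictly less than ``gap_bp`` (150 bp by
default, a value tuned for transcription-factor fusions), the region is
absorbed into the peak together with any intervening non-significant
sequence.  Each peak is represented by its lowest-p-value region, and
peaks are ranked by that representative p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GAP_BP = 150


@dataclass
class Peak:
    peak_id: str
    chrom: str
    start: int
    end: int
    n_regions: int
    rep_region_id: str
    rep_p: float
    rep_fdr: float
    max_logFC: float
    rank: int = 0


def call_peaks(results: pd.DataFrame, gap_bp: int = DEFAULT_GAP_BP) -> list[Peak]:
    """Merge Upreg regions into peaks; ``results`` is a region test table.

    Regions must carry chrom/start/end/p_value/fdr/logFC/meth_status.
    Scanning proceeds left to right per chromosome over Upreg regions
    only; a gap of exactly ``gap_bp`` splits (strict inequality merges).
    Peak coordinates are the union span including absorbed gaps.
    """
    sig = results[results["meth_status"] == "Upreg"].sort_values(
        ["chrom", "start"], kind="stable"
    )
    if len(sig) == 0:
        logger.warning("no significant regions; empty peak list")
        return []

    peaks: list[Peak] = []
    current: list[pd.Series] = []

    def close(run: list[pd.Series]) -> None:
        start = int(run[0]["start"])
        end = int(max(r["end"] for r in run))
        chrom = run[0]["chrom"]
        rep = min(run, key=lambda r: (r["p_value"], r["start"]))
        peaks.append(
            Peak(
                peak_id=f"peak_{chrom}_{start}_{end}",
                chrom=chrom,
                start=start,
                end=end,
                n_regions=len(run),
                rep_region_id=rep["region_id"],
                rep_p=float(rep["p_value"]),
                rep_fdr=float(rep["fdr"]),
                max_logFC=float(max(r["logFC"] for r in run)),
            )
        )

    for _, row in sig.iterrows():
        if current and row["chrom"] == current[0]["chrom"]:
            open_end = max(r["end"] for r in current)
            if row["start"] - open_end < gap_bp:
                current.append(row)
                continue
        if current:
            close(current)
        current = [row]
    if current:
        close(current)
    return rank_peaks(peaks)


def rank_peaks(peaks: list[Peak]) -> list[Peak]:
    """Assign 1-based ranks by ascending representative p-value.

    Ties break to the larger max logFC, then genomic order.  The input
    list order (genomic) is preserved; only ``rank`` is set.
    """
    order = sorted(
        range(len(peaks)),
        key=lambda i: (peaks[i].rep_p, -peaks[i].max_logFC, peaks[i].chrom, peaks[i].start),
    )
    for rank, i in enumerate(order, start=1):
        peaks[i].rank = rank
    return peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "peak_id": [p.peak_id for p in peaks],
            "rank": [p.rank for p in peaks],
            "strand": ["." for _ in peaks],
            "n_regions": [p.n_regions for p in peaks],
            "rep_region_id": [p.rep_region_id for p in peaks],
            "rep_p": [p.rep_p for p in peaks],
            "rep_fdr": [p.rep_fdr for p in peaks],
            "max_logFC": [p.max_logFC for p in peaks],
        }
    )


def write_peaks(peaks: list[Peak], path) -> None:
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t")
    return [
        Peak(
            peak_id=row.peak_id,
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            n_regions=int(row.n_regions),
            rep_region_id=str(row.rep_region_id),
            rep_p=float(row.rep_p),
            rep_fdr=float(row.rep_fdr),
            max_logFC=float(row.max_logFC),
            rank=int(row.rank),
        )
        for row in df.itertuples()
    ]
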