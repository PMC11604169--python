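"""Layered genome-track figures and QC plots.

Each plotting call first assembles a *plot manifest* — a dict of tidy
DataFrames, one per layer — and then renders it.  Tests (and users who
want the numbers) work from the manifest; the figure is a deterministic
SVG rendering of it.

Track stack for a window, top to bottom: per-sample region counts
(shared y-scale within each group), logFC bars colored by methylation
status, peak boxes, one tick per GATC motif boundary, strand-aware gene
glyphs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .counting import RegionCountMatrix
from .gatc_index import GatcRegion, InputError
from .gene_annotation import GeneModel
from .peak_calling import Peak

logger = logging.getLogger(__name__)

_STATUS_COLORS = {"Upreg": "#d62728", "No": "#7f7f7f", "Not_included": "#d9d9d9"}
_GROUP_COLORS = {"Dam": "#1f77b4", "Fusion": "#ff7f0e"}

# deterministic SVG output
matplotlib.rcParams["svg.hashsalt"] = "damid-kit"


def _clip(df: pd.DataFrame, start: int, end: int) -> pd.DataFrame:
    return df[(df["end"] > start) & (df["start"] < end)].reset_index(drop=True)


def region_manifest(
    chrom: str,
    start: int,
    end: int,
    matrix: RegionCountMatrix | None = None,
    dm_results: pd.DataFrame | None = None,
    peaks: list[Peak] | None = None,
    regions: list[GatcRegion] | None = None,
    genes: list[GeneModel] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tidy per-layer tables for a window; empty layers yield empty tables."""
    if end <= start:
        raise ValueError("window end must exceed start")
    seen_chroms: set[str] = set()
    manifest: dict[str, pd.DataFrame] = {}

    if matrix is not None:
        df = matrix.to_frame()
        seen_chroms.update(df["chrom"].unique())
        sub = _clip(df[df["chrom"] == chrom], start, end)
        long = sub.melt(
            id_vars=["region_id", "chrom", "start", "end", "width"],
            value_vars=matrix.sample_ids, var_name="sample_id", value_name="count",
        )
        groups = {s.sample_id: s.group for s in matrix.samples}
        long["group"] = long["sample_id"].map(groups)
        manifest["counts"] = long
    else:
        manifest["counts"] = pd.DataFrame(
            columns=["region_id", "chrom", "start", "end", "width", "sample_id", "count", "group"]
        )

    if dm_results is not None and len(dm_results):
        seen_chroms.update(dm_results["chrom"].unique())
        manifest["dm"] = _clip(dm_results[dm_results["chrom"] == chrom], start, end)
    else:
        manifest["dm"] = pd.DataFrame(columns=["region_id", "chrom", "start", "end",
                                               "logFC", "p_value", "meth_status"])

    peak_rows = [
        {"peak_id": p.peak_id, "chrom": p.chrom, "start": p.start, "end": p.end,
         "rank": p.rank, "rep_p": p.rep_p}
        for p in (peaks or [])
    ]
    pf = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end", "rank", "rep_p"])
    seen_chroms.update(pf["chrom"].unique())
    manifest["peaks"] = _clip(pf[pf["chrom"] == chrom], start, end) if len(pf) else pf

    ticks = []
    for r in regions or []:
        seen_chroms.add(r.chrom)
        if r.chrom == chrom and r.terminal_flag != "left_flank" and start <= r.start < end:
            ticks.append({"chrom": r.chrom, "pos": r.start})
    manifest["gatc"] = pd.DataFrame(ticks, columns=["chrom", "pos"])

    gene_rows = [
        {"gene_id": g.gene_id, "gene_name": g.gene_name, "chrom": g.chrom,
         "start": g.start, "end": g.end, "strand": g.strand, "tss": g.tss}
        for g in (genes or [])
    ]
    gf = pd.DataFrame(gene_rows, columns=["gene_id", "gene_name", "chrom", "start",
                                          "end", "strand", "tss"])
    seen_chroms.update(gf["chrom"].unique())
    manifest["genes"] = _clip(gf[gf["chrom"] == chrom], start, end) if len(gf) else gf

    if seen_chroms and chrom not in seen_chroms:
        raise InputError(f"window chromosome {chrom!r} absent from every input")
    return manifest


def plot_region(
    chrom: str,
    start: int,
    end: int,
    out_path: str | Path,
    matrix: RegionCountMatrix | None = None,
    dm_results: pd.DataFrame | None = None,
    peaks: list[Peak] | None = None,
    regions: list[GatcRegion] | None = None,
    genes: list[GeneModel] | None = None,
) -> dict[str, pd.DataFrame]:
    """Render the layered track figure; returns the plot manifest."""
    manifest = region_manifest(chrom, start, end, matrix, dm_results, peaks, regions, genes)
    counts = manifest["counts"]
    sample_ids = list(dict.fromkeys(counts["sample_id"])) if len(counts) else []
    n_count_tracks = max(len(sample_ids), 1)
    n_rows = n_count_tracks + 4
    heights = [1.0] * n_count_tracks + [1.0, 0.5, 0.3, 0.8]
    fig, axes = plt.subplots(
        n_rows, 1, sharex=True, figsize=(10, 1.1 * n_rows),
        gridspec_kw={"height_ratios": heights},
    )
    axes = np.atleast_1d(axes)

    ymax_by_group: dict[str, float] = {}
    if len(counts):
        for grp, sub in counts.groupby("group"):
            ymax_by_group[grp] = max(float(sub["count"].max()), 1.0)
    for i, sid in enumerate(sample_ids):
        ax = axes[i]
        sub = counts[counts["sample_id"] == sid]
        grp = sub["group"].iloc[0] if len(sub) else "Dam"
        ax.bar(
            sub["start"], sub["count"], width=sub["width"], align="edge",
            color=_GROUP_COLORS.get(grp, "#333333"), linewidth=0,
        )
        ax.set_ylim(0, ymax_by_group.get(grp, 1.0) * 1.05)
        ax.set_ylabel(sid, rotation=0, ha="right", va="center", fontsize=8)
    if not sample_ids:
        axes[0].set_ylabel("counts", fontsize=8)

    ax_dm = axes[n_count_tracks]
    dm = manifest["dm"]
    if len(dm):
        colors = [_STATUS_COLORS.get(s, "#7f7f7f") for s in dm["meth_status"]]
        ax_dm.bar(dm["start"], dm["logFC"].fillna(0.0), width=dm["end"] - dm["start"],
                  align="edge", color=colors, linewidth=0)
        ax_dm.axhline(0, color="black", linewidth=0.5)
    ax_dm.set_ylabel("logFC", rotation=0, ha="right", va="center", fontsize=8)

    ax_pk = axes[n_count_tracks + 1]
    for _, p in manifest["peaks"].iterrows():
        ax_pk.add_patch(plt.Rectangle((p["start"], 0.2), p["end"] - p["start"], 0.6,
                                      facecolor="#2ca02c", edgecolor="none"))
    ax_pk.set_ylim(0, 1)
    ax_pk.set_yticks([])
    ax_pk.set_ylabel("peaks", rotation=0, ha="right", va="center", fontsize=8)

    ax_gatc = axes[n_count_tracks + 2]
    for _, t in manifest["gatc"].iterrows():
        ax_gatc.axvline(t["pos"], color="black", linewidth=0.5)
    ax_gatc.set_yticks([])
    ax_gatc.set_ylabel("GATC", rotation=0, ha="right", va="center", fontsize=8)

    ax_gene = axes[n_count_tracks + 3]
    for k, (_, g) in enumerate(manifest["genes"].iterrows()):
        y = 0.25 + 0.5 * (k % 2)
        ax_gene.add_patch(plt.Rectangle((g["start"], y - 0.1), g["end"] - g["start"], 0.2,
                                        facecolor="#9467bd", edgecolor="none"))
        marker = ">" if g["strand"] == "+" else "<"
        ax_gene.plot([g["tss"]], [y], marker=marker, color="black", markersize=4)
        ax_gene.text(g["start"], y + 0.12, g["gene_name"], fontsize=7)
    ax_gene.set_ylim(0, 1)
    ax_gene.set_yticks([])
    ax_gene.set_ylabel("genes", rotation=0, ha="right", va="center", fontsize=8)
    ax_gene.set_xlabel(f"{chrom}:{start}-{end}")

    for ax in axes:
        ax.set_xlim(start, end)
    fig.align_ylabels()
    fig.savefig(str(out_path), metadata=_svg_metadata(out_path))
    plt.close(fig)
    return manifest


def qc_manifest(
    matrix: RegionCountMatrix,
    dm_results: pd.DataFrame,
    peaks: list[Peak],
) -> pd.DataFrame:
    """Partition each sample's total counts into in-peak / tested / not-tested.

    The three segments sum exactly to the sample total.
    """
    tested_ids = set(
        dm_results.loc[dm_results["meth_status"] != "Not_included", "region_id"]
    )
    peak_spans: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        peak_spans.setdefault(p.chrom, []).append((p.start, p.end))

    def in_peak(r: GatcRegion) -> bool:
        return any(r.start < e and r.end > s for s, e in peak_spans.get(r.chrom, []))

    in_peak_mask = np.array([in_peak(r) for r in matrix.regions])
    tested_mask = np.array([r.region_id in tested_ids for r in matrix.regions])

    rows = []
    for j, s in enumerate(matrix.samples):
        col = matrix.counts[:, j]
        pk = int(col[in_peak_mask & tested_mask].sum())
        tested = int(col[tested_mask & ~in_peak_mask].sum())
        untested = int(col[~tested_mask].sum())
        total = int(col.sum())
        assert pk + tested + untested == total
        rows.append(
            {"sample_id": s.sample_id, "group": s.group, "in_peak": pk,
             "tested_not_peak": tested, "not_tested": untested, "total": total}
        )
    return pd.DataFrame(rows)


def plot_qc(
    matrix: RegionCountMatrix,
    dm_results: pd.DataFrame,
    peaks: list[Peak],
    out_path: str | Path,
) -> pd.DataFrame:
    """Stacked per-sample depth bars split by testing/peak membership."""
    table = qc_manifest(matrix, dm_results, peaks)
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(table), 4))
    x = np.arange(len(table))
    bottom = np.zeros(len(table))
    for seg, color in [("in_peak", "#2ca02c"), ("tested_not_peak", "#1f77b4"),
                       ("not_tested", "#d9d9d9")]:
        ax.bar(x, table[seg], bottom=bottom, color=color, label=seg)
        bottom += table[seg].to_numpy(dtype=float)
    ax.set_xticks(x, table["sample_id"], rotation=45, ha="right")
    ax.set_ylabel("total counts")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(str(out_path), metadata=_svg_metadata(out_path))
    plt.close(fig)
    return table


def _svg_metadata(out_path: str | Path) -> dict | None:
    # strip the timestamp so identical inputs give byte-identical SVGs
    return {"Date": None} if str(out_path).endswith(".svg") else None
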