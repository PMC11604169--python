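"""Deterministic synthetic DamID-seq data for every pipeline stage.

The generator emulates the statistical structure of a transcription-factor
DamID experiment: a toy genome with GATC motifs injected at Poisson-spaced
positions (plus whatever incidental motifs the random background
produces — the post-injection rescan is the ground truth); region counts
drawn from a negative-binomial model whose baseline scales with region
width; a planted subset of enriched regions where Fusion means are
multiplied by 2^logFC; optional replicate-specific depth skew (mirroring
the large between-replicate depth differences seen in real DamID
libraries) and replicate-specific per-region effects for studying
replicate-aware designs; and BAM emission that round-trips exactly
through the counting stage.

It does not model fragment-length distributions, GC effects, or PCR
duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .counting import RegionCountMatrix, SampleInfo
from .gatc_index import GatcRegion, MotifSite, build_regions, scan_motifs_in_sequence

logger = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic experiment.

    Defaults mirror a small two-replicate transcription-factor DamID
    design: two Dam-only and two Fusion samples, a GATC density of about
    three injected motifs per kb (comparable to the ~1/256 background
    rate of a 4-mer in random sequence), NB dispersion 0.1, five percent
    of regions enriched four-fold.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 100_000
    motif_rate: float = 3.0  # expected injected GATC per kb
    n_dam: int = 2
    n_fusion: int = 2
    library_sizes: list[int] | None = None  # per sample, Dam first
    nb_dispersion: float = 0.1
    enriched_fraction: float = 0.05
    planted_logfc: float = 2.0
    replicate_depth_skew: float = 1.0  # depth multiplier applied per replicate index
    replicate_effect_sd: float = 0.0  # sd of per-region, per-replicate log-normal effects
    replicate_effect_fraction: float = 0.1  # fraction of regions carrying such effects
    read_length: int = 75

    def __post_init__(self) -> None:
        if not (0 <= self.enriched_fraction <= 1):
            raise ValueError("enriched_fraction must be in [0, 1]")
        if self.motif_rate < 0 or self.nb_dispersion <= 0:
            raise ValueError("motif_rate must be >= 0 and nb_dispersion > 0")
        if self.n_dam < 1 or self.n_fusion < 1:
            raise ValueError("need at least one Dam and one Fusion sample")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    truth_sites: list[MotifSite] = field(repr=False)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def make_genome(spec: SimulationSpec) -> SyntheticGenome:
    """Random genome with Poisson-spaced injected GATC motifs.

    The truth table is obtained by rescanning the final sequence, so it
    includes incidental motifs arising from the random background.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.chrom_length < 8:
        raise ValueError("chromosome too short to hold a motif")
    sequences = {}
    truth: list[MotifSite] = []
    bases = np.array(list("ACGT"))
    for c in range(spec.n_chrom):
        chrom = f"chr{c + 1}"
        seq = rng.choice(bases, size=spec.chrom_length)
        if spec.motif_rate > 0:
            mean_gap = 1000.0 / spec.motif_rate
            pos = 0
            positions = []
            while True:
                pos += max(4, int(rng.exponential(mean_gap)) + 1)
                if pos + 4 > spec.chrom_length:
                    break
                positions.append(pos)
            for p in positions:
                seq[p : p + 4] = list("GATC")
        seq_str = "".join(seq)
        sequences[chrom] = seq_str
        truth.extend(scan_motifs_in_sequence(seq_str, chrom))
    return SyntheticGenome(sequences=sequences, truth_sites=truth)


def make_regions(genome: SyntheticGenome) -> list[GatcRegion]:
    return build_regions(genome.truth_sites, genome.chrom_lengths)


def make_samples(spec: SimulationSpec, paired: bool = False) -> list[SampleInfo]:
    """Sample sheet: replicate ids pair Dam_i with Fusion_i."""
    samples = []
    for i in range(spec.n_dam):
        samples.append(SampleInfo(f"Dam_{i + 1}", "", "Dam", i + 1, paired=paired))
    for i in range(spec.n_fusion):
        samples.append(SampleInfo(f"Fusion_{i + 1}", "", "Fusion", i + 1, paired=paired))
    return samples


def simulate_counts(
    regions: list[GatcRegion],
    spec: SimulationSpec,
    samples: list[SampleInfo] | None = None,
) -> tuple[RegionCountMatrix, np.ndarray]:
    """NB counts with planted enrichment; returns the matrix and truth flags.

    Baseline region means are proportional to width times a gamma
    variability factor; Fusion samples multiply the mean by
    2^planted_logfc on enriched regions.  Per-sample depth combines the
    library size with the replicate depth skew.  When
    ``replicate_effect_sd > 0``, each (region, replicate) pair receives a
    shared log-normal effect — a replicate-confounded structure that a
    group-only design cannot model.
    """
    if len(regions) < 10:
        raise ValueError("need at least 10 regions to simulate counts")
    rng = np.random.default_rng(spec.seed + 1)
    samples = samples if samples is not None else make_samples(spec)
    G, n = len(regions), len(samples)

    widths = np.array([r.width for r in regions], dtype=float)
    base = widths / widths.mean() * rng.gamma(shape=2.0, scale=0.5, size=G)
    base = np.maximum(base, 1e-3)

    enriched = rng.random(G) < spec.enriched_fraction
    lib = (
        np.asarray(spec.library_sizes, dtype=float)
        if spec.library_sizes is not None
        else np.full(n, 40.0 * G)
    )
    if lib.shape != (n,):
        raise ValueError(f"library_sizes must have {n} entries")

    rel = base / base.sum()
    mu = np.tile(rel[:, None], (1, n))
    for j, s in enumerate(samples):
        if s.group == "Fusion":
            mu[enriched, j] *= 2.0 ** spec.planted_logfc
        depth = lib[j] * spec.replicate_depth_skew ** (s.replicate - 1)
        # fixed sequencing depth per library: enrichment displaces reads from
        # unenriched regions (the composition effect TMM is there to absorb)
        mu[:, j] *= depth / mu[:, j].sum()
    if spec.replicate_effect_sd > 0:
        # replicate-specific effects at a minority of regions (e.g. accessibility
        # or copy-number differences between biological replicates): shared by
        # the Dam and Fusion samples of a replicate, invisible to a group-only
        # design yet inflating its region-wise variance heterogeneity
        affected = rng.random(G) < spec.replicate_effect_fraction
        reps = sorted({s.replicate for s in samples})
        for rep in reps:
            eff = np.where(
                affected,
                rng.lognormal(mean=0.0, sigma=spec.replicate_effect_sd, size=G),
                1.0,
            )
            for j, s in enumerate(samples):
                if s.replicate == rep:
                    mu[:, j] *= eff

    r_nb = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    matrix = RegionCountMatrix(regions=list(regions), samples=samples, counts=counts)
    for j, s in enumerate(samples):
        s.library_size = int(counts[:, j].sum())
    return matrix, enriched


def emit_bam(
    matrix: RegionCountMatrix,
    genome: SyntheticGenome,
    outdir: str | Path,
    paired: bool = False,
    read_length: int = 75,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one sorted, indexed BAM per sample whose recount equals the matrix.

    Every read (or proper pair) is placed fully inside its region, so
    largest-overlap assignment is unambiguous and counting round-trips
    exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_lengths = genome.chrom_lengths
    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
        "CO": [f"synthetic DamID fixture, seed={seed}"],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    paths = {}
    for j, sample in enumerate(matrix.samples):
        unsorted = outdir / f"{sample.sample_id}.unsorted.bam"
        final = outdir / f"{sample.sample_id}.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            serial = 0
            for i, region in enumerate(matrix.regions):
                count = int(matrix.counts[i, j])
                if count == 0:
                    continue
                rlen = min(read_length, region.width)
                frag = min(2 * rlen, region.width) if paired else rlen
                slots = max(1, region.width - frag + 1)
                for k in range(count):
                    start = region.start + (k % slots)
                    serial += 1
                    name = f"{sample.sample_id}.{serial}"
                    if paired:
                        _write_pair(bam, name, tid[region.chrom], start, frag, rlen,
                                    genome.sequences[region.chrom])
                    else:
                        _write_single(bam, name, tid[region.chrom], start, rlen,
                                      genome.sequences[region.chrom])
        pysam.sort("-o", str(final), str(unsorted))
        unsorted.unlink()
        pysam.index(str(final))
        sample.bam_path = final
        paths[sample.sample_id] = final
    return paths


def _write_single(bam, name, tid, start, rlen, chrom_seq) -> None:
    a = pysam.AlignedSegment(bam.header)
    a.query_name = name
    a.reference_id = tid
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = f"{rlen}M"
    a.query_sequence = chrom_seq[start : start + rlen]
    a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
    a.flag = 0
    bam.write(a)


def _write_pair(bam, name, tid, start, frag, rlen, chrom_seq) -> None:
    rlen = min(rlen, frag)
    mate_start = start + frag - rlen
    for is_read1 in (True, False):
        a = pysam.AlignedSegment(bam.header)
        a.query_name = name
        a.reference_id = tid
        a.next_reference_id = tid
        a.mapping_quality = 60
        a.cigarstring = f"{rlen}M"
        if is_read1:
            a.reference_start = start
            a.next_reference_start = mate_start
            a.template_length = frag
            a.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
            a.query_sequence = chrom_seq[start : start + rlen]
        else:
            a.reference_start = mate_start
            a.next_reference_start = start
            a.template_length = -frag
            a.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
            a.query_sequence = chrom_seq[mate_start : mate_start + rlen]
        a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
        bam.write(a)


def make_genes(
    genome: SyntheticGenome, gene_length: int = 2000, spacing: int = 5000
) -> str:
    """Uniformly spaced toy gene models on alternating strands, as GFF3 text."""
    lines = ["##gff-version 3"]
    g = 0
    for chrom, length in genome.chrom_lengths.items():
        pos = spacing // 2
        while pos + gene_length < length:
            g += 1
            strand = "+" if g % 2 else "-"
            lines.append(
                f"{chrom}\tsynthetic\tgene\t{pos + 1}\t{pos + gene_length}\t.\t{strand}\t.\t"
                f"ID=g{g};Name=gene{g}"
            )
            pos += spacing
    return "\n".join(lines) + "\n"


def make_categories(
    gene_ids: list[str],
    n_terms: int = 20,
    mean_size: int = 15,
    seed: int = 0,
    bias: dict[str, int] | None = None,
    bias_strength: float = 0.0,
) -> dict[str, set[str]]:
    """Random GO-style categories; ``bias_strength`` skews membership toward
    high-bias genes (to emulate categories of GATC-dense genes)."""
    rng = np.random.default_rng(seed)
    if bias is not None and bias_strength != 0:
        b = np.array([bias.get(g, 0) for g in gene_ids], dtype=float)
        z = (b - b.mean()) / (b.std() + 1e-9)
    else:
        z = np.zeros(len(gene_ids))
    cats: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = max(3, int(rng.poisson(mean_size)))
        size = min(size, len(gene_ids))
        a = bias_strength * rng.uniform(-1, 1)
        p = np.exp(a * z)
        p /= p.sum()
        members = rng.choice(len(gene_ids), size=size, replace=False, p=p)
        cats[f"GO:{t + 1:07d}"] = {gene_ids[i] for i in members}
    return cats


def write_categories(cat_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(cat_map):
            for gene in sorted(cat_map[term]):
                fh.write(f"{term}\t{gene}\n")


def simulate_to_dir(spec: SimulationSpec, outdir: str | Path, paired: bool = False) -> dict:
    """Emit the full fixture set (FASTA, BED, BAMs, GFF3, go.tsv, truth.tsv)."""
    from .gatc_index import write_regions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(spec)
    genome.write_fasta(outdir / "genome.fa")
    regions = make_regions(genome)
    write_regions(regions, outdir / "regions.bed", "bed")
    samples = make_samples(spec, paired=paired)
    matrix, enriched = simulate_counts(regions, spec, samples)
    emit_bam(matrix, genome, outdir, paired=paired, read_length=spec.read_length,
             seed=spec.seed)
    (outdir / "genes.gff3").write_text(make_genes(genome))
    gene_ids = [f"g{i + 1}" for i in range(make_genes(genome).count("\tgene\t"))]
    write_categories(make_categories(gene_ids, seed=spec.seed), outdir / "go.tsv")
    truth = matrix.to_frame()[["region_id"]].copy()
    truth["enriched"] = enriched
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tbam\tgroup\treplicate\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.bam_path}\t{s.group}\t{s.replicate}\n")
    matrix.to_frame().to_csv(outdir / "counts.tsv", sep="\t", index=False)
    return {"genome": genome, "regions": regions, "matrix": matrix, "enriched": enriched,
            "samples": samples}
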