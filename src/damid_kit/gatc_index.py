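"""Genome partitioning into GATC-delimited regions.

Dam methylase acts on the adenine of GATC motifs, so the natural unit of
quantification for DamID-seq is the interval between two adjacent GATC
sites.  Because GATC is its own reverse complement, a single forward-strand
scan demarcates both strands simultaneously.

Coordinates are 0-based half-open throughout; conversion to 1-based
inclusive happens only at the SAF I/O boundary.  An internal region owns
the motif that starts it: it spans from the first base of its upstream
GATC to the base before the first base of the next GATC, so the regions of
a chromosome (together with the terminal flanks) tile it exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_VALID_MOTIF = re.compile(r"^[ACGT]+$")


class InputError(ValueError):
    """Unreadable or malformed input data."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class ConsistencyError(ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


@dataclass(frozen=True, order=True)
class MotifSite:
    """A forward-strand occurrence of the motif; ``pos`` is the 0-based start."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class GatcRegion:
    """A genomic interval delimited by adjacent GATC motifs.

    ``terminal_flag`` is ``"internal"`` for motif-to-motif intervals and
    ``"left_flank"`` / ``"right_flank"`` for the chromosome ends outside
    the outermost motifs.
    """

    chrom: str
    start: int
    end: int
    terminal_flag: str = "internal"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def region_id(self) -> str:
        return f"{self.chrom}-{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # lower median base for even widths
        return (self.start + self.end) // 2


def scan_motifs(fasta_path: str | Path, motif: str = "GATC") -> list[MotifSite]:
    """Scan a FASTA for forward-strand occurrences of ``motif``.

    The motif must be 4 bp over {A,C,G,T}.  Matching is case-insensitive
    and windows containing N never match.  No reverse-strand scan is
    performed: for palindromic motifs such as GATC it would be redundant.
    """
    motif = motif.upper()
    if len(motif) != 4:
        raise ConfigError(f"motif must be 4 bp, got {motif!r}")
    if not _VALID_MOTIF.match(motif):
        raise ConfigError(f"motif must contain only A/C/G/T, got {motif!r}")

    try:
        fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    except Exception as exc:  # pyfaidx raises several error types
        raise InputError(f"cannot read FASTA {fasta_path}: {exc}") from exc
    if len(fasta.keys()) == 0:
        raise InputError(f"FASTA {fasta_path} contains no sequences")

    sites: list[MotifSite] = []
    for chrom in fasta.keys():
        seq = str(fasta[chrom][:])
        start = 0
        while True:
            hit = seq.find(motif, start)
            if hit < 0:
                break
            sites.append(MotifSite(chrom=chrom, pos=hit))
            start = hit + 1  # overlapping self-hits impossible for GATC but be general
    return sites


def scan_motifs_in_sequence(seq: str, chrom: str, motif: str = "GATC") -> list[MotifSite]:
    """Scan an in-memory sequence string (used by the simulator's rescan)."""
    seq = seq.upper()
    motif = motif.upper()
    sites = []
    start = 0
    while True:
        hit = seq.find(motif, start)
        if hit < 0:
            break
        sites.append(MotifSite(chrom=chrom, pos=hit))
        start = hit + 1
    return sites


def build_regions(
    sites: Iterable[MotifSite], chrom_lengths: dict[str, int]
) -> list[GatcRegion]:
    """Partition chromosomes into GATC regions from sorted motif sites.

    For a chromosome with k >= 2 sites at positions p_1 < ... < p_k this
    emits k-1 internal regions [p_i, p_{i+1}), plus the nonempty terminal
    flanks [0, p_1) and [p_k, length).  Chromosomes with fewer than two
    sites yield flanks only, with a warning.  The emitted regions tile
    [0, length) exactly.
    """
    by_chrom: dict[str, list[int]] = {}
    for site in sites:
        if site.chrom not in chrom_lengths:
            raise ConsistencyError(f"site chromosome {site.chrom!r} not in chrom_lengths")
        length = chrom_lengths[site.chrom]
        if site.pos + 4 > length:
            raise ConsistencyError(
                f"motif at {site.chrom}:{site.pos} extends past chromosome end ({length})"
            )
        positions = by_chrom.setdefault(site.chrom, [])
        if positions and site.pos <= positions[-1]:
            raise ConsistencyError(f"sites not strictly increasing on {site.chrom}")
        positions.append(site.pos)

    regions: list[GatcRegion] = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        positions = by_chrom.get(chrom, [])
        if len(positions) < 2:
            logger.warning(
                "chromosome %s has %d GATC site(s); emitting flanks only",
                chrom,
                len(positions),
            )
            if not positions:
                if length > 0:
                    regions.append(GatcRegion(chrom, 0, length, "left_flank"))
                continue
            p = positions[0]
            if p > 0:
                regions.append(GatcRegion(chrom, 0, p, "left_flank"))
            if p < length:
                regions.append(GatcRegion(chrom, p, length, "right_flank"))
            continue
        if positions[0] > 0:
            regions.append(GatcRegion(chrom, 0, positions[0], "left_flank"))
        for left, right in zip(positions, positions[1:]):
            regions.append(GatcRegion(chrom, left, right, "internal"))
        if positions[-1] < length:
            regions.append(GatcRegion(chrom, positions[-1], length, "right_flank"))
    return regions


def write_regions(
    regions: Iterable[GatcRegion], path: str | Path, format: str = "bed"
) -> None:
    """Write regions as BED6 (0-based half-open) or SAF (1-based inclusive).

    BED columns: chrom, start, end, region_id, width, ".".  The flag column
    is appended as a 7th field so that a BED round trip preserves the
    terminal annotation.  SAF columns: GeneID, Chr, Start, End, Strand.
    """
    fmt = format.lower()
    if fmt not in {"bed", "saf"}:
        raise ConfigError(f"unknown region format {format!r}")
    with open(path, "w") as fh:
        if fmt == "saf":
            fh.write("GeneID\tChr\tStart\tEnd\tStrand\n")
        for r in regions:
            if fmt == "bed":
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.width}\t.\t{r.terminal_flag}\n"
                )
            else:
                fh.write(f"{r.region_id}\t{r.chrom}\t{r.start + 1}\t{r.end}\t+\n")


def read_regions(path: str | Path) -> list[GatcRegion]:
    """Read regions written by :func:`write_regions` (BED or SAF, autodetected)."""
    regions: list[GatcRegion] = []
    with open(path) as fh:
        first = fh.readline()
        if not first:
            return regions
        is_saf = first.startswith("GeneID\t")
        lines = [] if is_saf else [first]
        lines.extend(fh)
        for lineno, line in enumerate(lines, start=2 if is_saf else 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if is_saf:
                    _, chrom, start1, end1, _ = fields[:5]
                    start, end = int(start1) - 1, int(end1)
                    flag = "internal"
                else:
                    chrom, start_s, end_s = fields[0], fields[1], fields[2]
                    start, end = int(start_s), int(end_s)
                    flag = fields[6] if len(fields) > 6 else "internal"
                if start >= end:
                    raise ValueError("start >= end")
                regions.append(GatcRegion(chrom, start, end, flag))
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: parse error at line {lineno}: {exc}") from exc
    return regions
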