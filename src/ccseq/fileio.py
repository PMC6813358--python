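"""Readers and writers for the standard formats used across the pipeline.

Internal coordinates are 1-based inclusive; BED and bedGraph files are
0-based half-open, and the conversion happens only here, at the file
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pysam

from ccseq.breakmap import BreakMap, WATSON, CRICK
from ccseq.calibration import NormalizedTrack
from ccseq.signal_analysis import Locus
from ccseq.terminal_mapping import AlignedSegment

_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S"}


@dataclass
class SamRecord:
    """A minimal SAM line used by the simulator's writer."""

    qname: str
    flag: int
    rname: str
    pos: int       # 1-based leftmost
    mapq: int
    cigar: str
    rnext: str = "="
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    md: str | None = None

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual if self.qual != "*" or self.seq == "*" else "I" * len(self.seq),
        ]
        if self.md is not None:
            fields.append(f"MD:Z:{self.md}")
        return "\t".join(fields)


def write_sam(
    records: list[SamRecord], contig_lengths: dict[str, int], path: str | Path
) -> None:
    """Write records as plain-text SAM with @SQ header lines."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in sorted(contig_lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{contig_lengths[name]}\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def _convert(rec: pysam.AlignedSegment) -> AlignedSegment:
    cigar = []
    for op, length in rec.cigartuples or []:
        sym = _PYSAM_OPS.get(op)
        if sym is None:
            # hard clips etc. never occur in the supported flag pairs; keep
            # the op visible so downstream filters reject loudly
            sym = "?"
        cigar.append((length, sym))
    md = None
    if rec.has_tag("MD"):
        md = rec.get_tag("MD")
    return AlignedSegment(
        query_name=rec.query_name,
        sam_flag=rec.flag,
        ref_name=rec.reference_name or "*",
        leftmost=(rec.reference_start + 1) if rec.reference_start is not None and rec.reference_start >= 0 else 1,
        mapq=rec.mapping_quality,
        cigar=cigar,
        md_tag=md,
    )


def read_alignments(
    path: str | Path, buffer_limit: int = 1_000_000
) -> Iterator[tuple[AlignedSegment, AlignedSegment]]:
    """Stream mate pairs from a SAM/BAM file, grouped by query name.

    Pairing is order-independent: records are buffered by query name
    until both mates arrive, so both name-sorted and coordinate-sorted
    inputs yield the same pairs.  Secondary and supplementary alignments
    are skipped.  An orphan mate left at end of file is a hard error.
    """
    pending: dict[str, AlignedSegment] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            seg = _convert(rec)
            mate = pending.pop(seg.query_name, None)
            if mate is None:
                if len(pending) >= buffer_limit:
                    raise RuntimeError("pairing buffer overflow; is the file paired?")
                pending[seg.query_name] = seg
            else:
                yield (mate, seg)
    if pending:
        names = ", ".join(sorted(pending)[:5])
        raise ValueError(f"{len(pending)} unpaired records at end of file (e.g. {names})")


# ---------------------------------------------------------------------------
# bedGraph / TSV tracks

def write_bedgraph(
    track: NormalizedTrack | BreakMap, path: str | Path, strand: str
) -> None:
    """One 4-column bedGraph line per nonzero coordinate (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{strand}"\n')
        if isinstance(track, BreakMap):
            items = [
                (c, p, n)
                for c, s, p, n in track.iter_sites()
                if s == strand
            ]
        else:
            items = [
                (c, p, v)
                for (c, s), d in sorted(track.values.items())
                if s == strand
                for p, v in sorted(d.items())
            ]
        for contig, pos, value in items:
            fh.write(f"{contig}\t{pos - 1}\t{pos}\t{value:g}\n")


def read_bedgraph(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a single-base bedGraph back into 1-based sparse values."""
    out: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            contig, start, end, value = line.split()[:4]
            start, end = int(start), int(end)
            v = float(value)
            for pos0 in range(start, end):
                out.setdefault(contig, {})[pos0 + 1] = v
    return out


def write_two_strand_tsv(track: BreakMap | NormalizedTrack, path: str | Path) -> None:
    """Compact per-position table: contig, 1-based pos, watson, crick."""
    if isinstance(track, BreakMap):
        get = lambda c, s: dict(track.counts.get((c, s), {}))
        contigs = track.contigs
        total = track.total_mapped_pairs
    else:
        get = lambda c, s: track.values.get((c, s), {})
        contigs = track.contigs
        total = track.total_mapped_pairs
    with open(path, "w") as fh:
        fh.write(f"# total_mapped_pairs={total}\n")
        fh.write("contig\tpos\twatson\tcrick\n")
        for contig in contigs:
            w = get(contig, WATSON)
            c = get(contig, CRICK)
            for pos in sorted(set(w) | set(c)):
                fh.write(f"{contig}\t{pos}\t{w.get(pos, 0):g}\t{c.get(pos, 0):g}\n")


def read_two_strand_tsv(path: str | Path) -> BreakMap:
    """Read the two-strand TSV back into a BreakMap (counts rounded)."""
    bmap = BreakMap()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "total_mapped_pairs=" in line:
                    bmap.total_mapped_pairs = int(
                        float(line.split("total_mapped_pairs=")[1])
                    )
                continue
            if line.startswith("contig"):
                continue
            contig, pos, w, c = line.split()
            pos = int(pos)
            if float(w) > 0:
                bmap.add(contig, WATSON, pos, int(round(float(w))))
            if float(c) > 0:
                bmap.add(contig, CRICK, pos, int(round(float(c))))
    if bmap.total_mapped_pairs == 0:
        bmap.total_mapped_pairs = bmap.total_count()
    return bmap


# ---------------------------------------------------------------------------
# BED / loci / FASTA

def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """BED intervals converted to 1-based half-open (start+1, end+1)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            parts = line.split()
            out.append((parts[0], int(parts[1]) + 1, int(parts[2]) + 1))
    return out


def read_loci_bed(path: str | Path) -> list[Locus]:
    """BED6 loci; position is the interval midpoint, score is the covariate."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            parts = line.split()
            start, end = int(parts[1]), int(parts[2])
            pos = (start + end + 1) // 2  # 1-based midpoint
            name = parts[3] if len(parts) > 3 else ""
            cov = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            loci.append(Locus(parts[0], pos, strand, cov, name))
    return loci


def read_genes_tsv(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Gene table: contig, start(1-based), end, strand[, id]."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            genes.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return genes


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain dict-of-strings FASTA reader for small genomes."""
    contigs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        contigs[name] = "".join(chunks)
    return contigs
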