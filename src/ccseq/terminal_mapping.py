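"""Call protein-linked 5' DNA termini from paired-end alignments.

Covalent-complex libraries ligate a distinguishable adapter to the
protein-linked DNA end, so Read-1's 5' terminus is the cleavage
coordinate.  Only fully aligned, properly paired reads are informative:
flag pair (99, 147) is a Watson-strand break, (83, 163) a Crick-strand
break; everything else is rejected.  For a plus-strand read the 5' end is
the SAM leftmost coordinate; for a minus-strand read the leftmost base is
the 3' end, and the 5' coordinate is obtained by walking the CIGAR over
the reference (M and D advance, I and S do not):

    five_prime = leftmost + reference_span(cigar) - 1

Reads whose 5' terminus carries a run of >= 2 mismatched or absent bases
(read from the MD:Z tag, plus any 5' soft clip) are positionally ambiguous
and the whole pair is discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

from ccseq.breakmap import BreakMap, MappingStats, WATSON, CRICK

# Reference-consumption weight per CIGAR op: insertions in the read and
# soft clips occupy no reference bases and must not shift the called end.
_REF_WEIGHT = {"M": 1, "D": 1, "I": 0, "S": 0}

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")

FLAG_READ1 = 0x40
FLAG_REVERSE = 0x10

WATSON_PAIR_FLAGS = frozenset({99, 147})
CRICK_PAIR_FLAGS = frozenset({83, 163})


@dataclass
class AlignedSegment:
    """One mate of a paired-end alignment, 1-based leftmost coordinate."""

    query_name: str
    sam_flag: int
    ref_name: str
    leftmost: int
    mapq: int
    cigar: list[tuple[int, str]]
    md_tag: str | None = None

    @property
    def is_read1(self) -> bool:
        return bool(self.sam_flag & FLAG_READ1)

    @property
    def is_reverse(self) -> bool:
        return bool(self.sam_flag & FLAG_REVERSE)


class PairClass(Enum):
    WATSON_PAIR = "watson"
    CRICK_PAIR = "crick"
    REJECT = "reject"


def classify_pair(flag_read1: int, flag_read2: int) -> PairClass:
    """Classify a read pair by its SAM flag combination.

    (99, 147) is a proper pair with Read-1 on Watson; (83, 163) with
    Read-1 on Crick.  Any other combination (unmapped, discordant,
    secondary, ...) is rejected.  Symmetric in argument order.
    """
    flags = {flag_read1, flag_read2}
    if flags == WATSON_PAIR_FLAGS:
        return PairClass.WATSON_PAIR
    if flags == CRICK_PAIR_FLAGS:
        return PairClass.CRICK_PAIR
    return PairClass.REJECT


def reference_span(cigar: Iterable[tuple[int, str]]) -> int:
    """Number of reference bases covered by an alignment.

    M and D consume the reference; I and S do not, so an inserted or
    clipped read base never shifts the called coordinate.
    """
    span = 0
    for length, op in cigar:
        try:
            span += length * _REF_WEIGHT[op]
        except KeyError:
            raise ValueError(f"unsupported CIGAR op {op!r}") from None
    return span


def call_five_prime(segment: AlignedSegment) -> tuple[int, str]:
    """5' terminus coordinate and strand of one aligned read.

    Plus-strand reads start at their 5' end, so the leftmost coordinate is
    returned directly.  Minus-strand reads start at their 3' end; the 5'
    coordinate is leftmost + reference_span - 1 (the -1 because the
    leftmost base is itself part of the span).
    """
    if segment.is_reverse:
        return segment.leftmost + reference_span(segment.cigar) - 1, CRICK
    return segment.leftmost, WATSON


def _md_walk(md_tag: str) -> list[bool]:
    """Expand an MD:Z tag into per-reference-position mismatch flags.

    Returns one boolean per aligned reference position, reference
    left-to-right: False for a matching base, True for a substitution or a
    base deleted from the read (``^`` runs).  Insertions do not appear in
    MD and are invisible here.
    """
    walk: list[bool] = []
    pos = 0
    for m in _MD_TOKEN.finditer(md_tag):
        if m.start() != pos:
            raise ValueError(f"malformed MD:Z tag near {md_tag[pos:]!r}")
        pos = m.end()
        num, deletion, sub = m.groups()
        if num is not None:
            walk.extend([False] * int(num))
        elif deletion is not None:
            walk.extend([True] * len(deletion))
        else:
            walk.append(True)
    if pos != len(md_tag):
        raise ValueError(f"malformed MD:Z tag near {md_tag[pos:]!r}")
    return walk


def five_prime_mismatch_run(
    md_tag: str | None,
    cigar: Iterable[tuple[int, str]] = (),
    is_reverse: bool = False,
) -> int:
    """Length of the mismatched/absent run at a read's 5' terminus.

    The MD walk runs reference left-to-right, which is the read 5'->3'
    direction for plus-strand reads but 3'->5' for minus-strand reads; the
    run is therefore measured from the right end of the walk for minus
    reads.  Soft-clipped bases at the 5' end are positionally
    uninformative and count toward the run.
    """
    cigar = list(cigar)
    run = 0
    if cigar:
        clip = cigar[-1] if is_reverse else cigar[0]
        if clip[1] == "S":
            run += clip[0]
    walk = _md_walk(md_tag) if md_tag is not None else []
    if is_reverse:
        walk = walk[::-1]
    for mismatched in walk:
        if not mismatched:
            break
        run += 1
    return run


def _orient_pair(
    a: AlignedSegment, b: AlignedSegment
) -> tuple[AlignedSegment, AlignedSegment]:
    if a.is_read1 and not b.is_read1:
        return a, b
    if b.is_read1 and not a.is_read1:
        return b, a
    # Both or neither claim Read-1: unresolvable, let the flag filter reject.
    return a, b


def map_read_pairs(
    records: Iterable[tuple[AlignedSegment, AlignedSegment]],
    library_mode: str = "single",
    mapq_min: int = 0,
    max_end_mismatch: int = 1,
    genome_id: str = "",
    sample_id: str = "",
) -> tuple[BreakMap, MappingStats]:
    """Build a strand-specific break map from a stream of read pairs.

    Each accepted pair contributes exactly one count at Read-1's 5'
    coordinate on its strand.  A pair is rejected when its flags are not a
    proper (99,147)/(83,163) combination or its mates map to different
    contigs; when either mate's MAPQ falls below ``mapq_min``; or when the
    5'-terminal mismatch run exceeds ``max_end_mismatch`` on Read-1
    ("single" libraries) or on either read ("double" libraries, where both
    ends are adapter-defined).  MAPQ defaults follow the organism: 0 for
    yeast-sized genomes, 10 for human.
    """
    mode = library_mode.lower()
    if mode not in ("single", "double"):
        raise ValueError(f"library_mode must be 'single' or 'double', got {library_mode!r}")
    bmap = BreakMap(genome_id=genome_id, sample_id=sample_id)
    stats = MappingStats()
    for a, b in records:
        stats.pairs_seen += 1
        r1, r2 = _orient_pair(a, b)
        cls = classify_pair(r1.sam_flag, r2.sam_flag)
        if cls is PairClass.REJECT or r1.ref_name != r2.ref_name:
            stats.pairs_flag_rejected += 1
            continue
        if r1.mapq < mapq_min or r2.mapq < mapq_min:
            stats.pairs_mapq_rejected += 1
            continue
        ambiguous = five_prime_mismatch_run(r1.md_tag, r1.cigar, r1.is_reverse) > max_end_mismatch
        if not ambiguous and mode == "double":
            ambiguous = five_prime_mismatch_run(r2.md_tag, r2.cigar, r2.is_reverse) > max_end_mismatch
        if ambiguous:
            stats.pairs_ambiguous_end += 1
            continue
        pos, strand = call_five_prime(r1)
        bmap.add(r1.ref_name, strand, pos)
        stats.pairs_counted += 1
    bmap.total_mapped_pairs = stats.pairs_counted
    stats.check()
    return bmap, stats


def apply_region_mask(
    bmap: BreakMap,
    mask: Iterable[tuple[str, int, int]],
    mode: str = "exclude",
) -> BreakMap:
    """Drop (or keep only) counts inside a set of half-open intervals.

    Intervals are (contig, start, end), half-open in the map's own 1-based
    coordinate space: position p is inside iff start <= p < end.  Used to
    exclude repetitive regions (rDNA, LTRs, telomeres) or restrict to a
    region of interest.  ``total_mapped_pairs`` is deliberately left
    unchanged so depth normalisation still refers to the full library.
    """
    if mode not in ("exclude", "include"):
        raise ValueError(f"mode must be 'exclude' or 'include', got {mode!r}")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in mask:
        if end < start:
            raise ValueError(f"malformed interval {contig}:{start}-{end} (end < start)")
        by_contig.setdefault(contig, []).append((start, end))
    for ivs in by_contig.values():
        ivs.sort()

    def inside(contig: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in by_contig.get(contig, ()))

    out = BreakMap(
        total_mapped_pairs=bmap.total_mapped_pairs,
        genome_id=bmap.genome_id,
        sample_id=bmap.sample_id,
    )
    for contig, strand, pos, n in bmap.iter_sites():
        keep = not inside(contig, pos) if mode == "exclude" else inside(contig, pos)
        if keep:
            out.add(contig, strand, pos, n)
    return out
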