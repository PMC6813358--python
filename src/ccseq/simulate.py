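"""Ground-truth simulation of cleavage sites and paired-end reads.

The generator emulates the physical structure of a covalent-complex
library: a protein-linked 5' terminus at each cleavage site (the
adapter-defined Read-1 end), a sonication-derived random mate position on
the other side of the fragment, 5' overhangs of configurable length
(2 nt Spo11-like, 4 nt Top2-like), a mixture of double-strand and
strand-biased single-strand cleavage, gamma-distributed site intensities,
optional terminal mismatches and internal indels to exercise the
ambiguous-end filter, spike-in genome mixing at a set molar ratio, and an
optional planted base preference at the scissile position.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ccseq.breakmap import BreakMap, WATSON, CRICK
from ccseq.calibration import SpikeInfo
from ccseq.fileio import SamRecord
from ccseq.seqbias import dyad_axis, offset_coordinate

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALT = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    """Random i.i.d. genome at a target GC fraction."""

    contigs: dict[str, str]
    gc_fraction: float
    seed: int

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]


def make_genome(
    length: int, gc: float = 0.40, seed: int = 0, name: str = "chrS"
) -> SyntheticGenome:
    """I.i.d. random genome of ``length`` bases at GC fraction ``gc``."""
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return SyntheticGenome(contigs={name: seq}, gc_fraction=gc, seed=seed)


@dataclass
class CleavageSite:
    """One cleavage site: Watson-linked 5' base at ``pos`` (1-based)."""

    contig: str
    pos: int
    lam: float          # expected event count at depth 1
    ssb_w_prob: float = 0.0
    ssb_c_prob: float = 0.0

    @property
    def dsb_prob(self) -> float:
        return 1.0 - self.ssb_w_prob - self.ssb_c_prob


@dataclass
class CleavageModel:
    """Ground-truth description of where and how the genome is cleaved.

    ``overhang`` is the 5'-overhang length (4 for Top2-like, 2 for
    Spo11-like); a DSB places a Watson terminus at pos and a Crick
    terminus at pos + overhang - 1.  ``planted_preference`` is an optional
    (base, dyad_offset, strength) triple for a sequence bias planted at
    every site.
    """

    sites: list[CleavageSite]
    overhang: int = 4
    planted_preference: tuple[str, int, float] | None = None

    def __post_init__(self) -> None:
        if self.overhang < 1:
            raise ValueError("overhang must be >= 1")
        for s in self.sites:
            if s.lam <= 0:
                raise ValueError("site intensity must be positive")
            if s.ssb_w_prob + s.ssb_c_prob > 1 + 1e-9:
                raise ValueError("ssb probabilities must sum to <= 1")


def random_cleavage_model(
    genome: SyntheticGenome,
    n_sites: int,
    overhang: int = 4,
    ssb_w_prob: float = 0.0,
    ssb_c_prob: float = 0.0,
    gamma_shape: float = 1.5,
    gamma_scale: float = 10.0,
    lam_min: float = 0.1,
    min_spacing: int = 200,
    margin: int = 500,
    seed: int = 0,
    planted_preference: tuple[str, int, float] | None = None,
) -> CleavageModel:
    """Draw ``n_sites`` sites with gamma-distributed intensities.

    Positions are uniform with a minimum spacing (default 200 bp) so
    neighbouring sites do not overlap within analysis windows; lambda ~
    Gamma(shape 1.5, scale 10) gives a realistic skewed dynamic range of
    site strengths.
    """
    rng = np.random.default_rng(seed)
    contig = next(iter(genome.contigs))
    lo, hi = margin, genome.length(contig) - margin
    if hi - lo < n_sites * min_spacing:
        raise ValueError("genome too short for requested sites at this spacing")
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_sites:
        attempts += 1
        if attempts > 100 * n_sites:
            raise RuntimeError("could not place sites; reduce n_sites or spacing")
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= min_spacing for q in positions):
            positions.append(p)
    positions.sort()
    lams = rng.gamma(gamma_shape, gamma_scale, size=n_sites)
    lams = np.maximum(lams, lam_min)
    sites = [
        CleavageSite(contig, p, float(l), ssb_w_prob, ssb_c_prob)
        for p, l in zip(positions, lams)
    ]
    return CleavageModel(sites=sites, overhang=overhang, planted_preference=planted_preference)


def plant_preference(
    genome: SyntheticGenome, model: CleavageModel, seed: int = 0
) -> SyntheticGenome:
    """Plant the model's base preference into the genome at every site.

    At each site, the base at the stated dyad offset is replaced by the
    preferred base with probability ``strength``; for sites that can form
    DSBs the complementary base is planted at the mirrored offset, keeping
    the motif rotationally symmetric about the dyad.  Overlapping sites:
    the later site wins (logged).
    """
    if model.planted_preference is None:
        raise ValueError("model has no planted_preference")
    base, offset, strength = model.planted_preference
    if base not in "ACGT" or not 0.0 <= strength <= 1.0:
        raise ValueError("planted_preference must be (ACGT base, offset, strength in [0,1])")
    rng = np.random.default_rng(seed)
    seqs = {c: list(s) for c, s in genome.contigs.items()}
    touched: set[tuple[str, int]] = set()
    n_overlap = 0
    for site in model.sites:
        dyad = dyad_axis(site.pos, model.overhang)
        targets = [(offset_coordinate(dyad, offset), base)]
        if site.dsb_prob > 0:
            targets.append(
                (offset_coordinate(dyad, -offset), base.translate(_COMPLEMENT))
            )
        for coord, b in targets:
            if not 1 <= coord <= len(seqs[site.contig]):
                continue
            if (site.contig, coord) in touched:
                n_overlap += 1
            touched.add((site.contig, coord))
            if rng.random() < strength:
                seqs[site.contig][coord - 1] = b
    if n_overlap:
        log.info("plant_preference: %d overlapping plant positions (later site wins)", n_overlap)
    return SyntheticGenome(
        contigs={c: "".join(s) for c, s in seqs.items()},
        gc_fraction=genome.gc_fraction,
        seed=genome.seed,
    )


def simulate_break_map(
    model: CleavageModel, depth: float = 1.0, seed: int = 0
) -> BreakMap:
    """Sample the ground-truth break map from a cleavage model.

    Each site receives Poisson(lambda * depth) events; each event is a DSB
    (one Watson terminus at pos, one Crick terminus at
    pos + overhang - 1), an SSB on the Watson strand only, or an SSB on
    the Crick strand only, per the site's probabilities.  Sonication
    converts a 5'-linked SSB into a mappable end, so SSB events yield a
    normal read pair on a single strand.
    """
    rng = np.random.default_rng(seed)
    bmap = BreakMap(genome_id="synthetic", sample_id="truth")
    off = model.overhang - 1
    for site in model.sites:
        n = rng.poisson(site.lam * depth)
        if n == 0:
            continue
        dsb, ssb_w, ssb_c = rng.multinomial(
            n, [site.dsb_prob, site.ssb_w_prob, site.ssb_c_prob]
        )
        if dsb + ssb_w:
            bmap.add(site.contig, WATSON, site.pos, int(dsb + ssb_w))
        if dsb + ssb_c:
            bmap.add(site.contig, CRICK, site.pos + off, int(dsb + ssb_c))
    bmap.total_mapped_pairs = bmap.total_count()
    return bmap


@dataclass
class ReadSimConfig:
    """Read-pair generation parameters (sonication-style fragments)."""

    read_length: int = 75
    frag_mean: float = 350.0
    frag_sd: float = 50.0
    frag_min: int = 100
    terminal_mismatch_prob: float = 0.0
    indel_prob: float = 0.0
    mapq: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.terminal_mismatch_prob, self.indel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def simulate_read_pairs(
    truth: BreakMap, genome: SyntheticGenome, config: ReadSimConfig
) -> list[SamRecord]:
    """Emit one paired-end alignment per break, coordinate-sorted.

    Read-1's 5' terminus sits exactly at the break coordinate on the break
    strand (the adapter-defined protein-linked end); the mate is placed at
    the far end of a fragment drawn from a truncated normal length
    distribution, extending away from the protein-linked terminus, on the
    opposite strand.  Flags are 99/147 for Watson breaks and 83/163 for
    Crick breaks.  Optional terminal mismatches (2 bp at the Read-1 5'
    end) and internal 1-bp deletions are reflected in SEQ, CIGAR and MD.
    Fragments that would leave the contig are resampled a bounded number
    of times, then dropped with a log message.
    """
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    records: list[SamRecord] = []
    n_dropped = 0
    serial = 0
    for contig, strand, pos, count in truth.iter_sites():
        seq_ref = genome.contigs[contig]
        clen = len(seq_ref)
        for _ in range(count):
            serial += 1
            qname = f"sim:{contig}:{strand}:{pos}:{serial}"
            frag = None
            for _try in range(20):
                f = int(round(rng.normal(config.frag_mean, config.frag_sd)))
                f = max(f, config.frag_min, L)
                if strand == WATSON and pos + f - 1 <= clen:
                    frag = f
                    break
                if strand == CRICK and pos - f + 1 >= 1:
                    frag = f
                    break
            if frag is None:
                n_dropped += 1
                continue
            if strand == WATSON:
                mates = ((pos, False, 99, True), (pos + frag - 1, True, 147, False))
            else:
                mates = ((pos, True, 83, True), (pos - frag + 1, False, 163, False))
            pair = []
            for five_prime, rev, flag, is_r1 in mates:
                has_del = bool(
                    is_r1 and config.indel_prob > 0 and rng.random() < config.indel_prob
                )
                span = L + 1 if has_del else L
                # leftmost so the read's 5' terminus lands exactly at five_prime
                left = five_prime - span + 1 if rev else five_prime
                if left < 1 or left + span - 1 > clen:
                    pair = []
                    break
                if has_del:
                    # 1-bp internal deletion: read skips one reference base
                    k = int(rng.integers(10, L - 10))
                    read_ref = (
                        seq_ref[left - 1 : left - 1 + k] + seq_ref[left + k : left + span - 1]
                    )
                    cigar = f"{k}M1D{L - k}M"
                    md = f"{k}^{seq_ref[left - 1 + k]}{L - k}"
                else:
                    read_ref = seq_ref[left - 1 : left + L - 1]
                    cigar, md = f"{L}M", str(L)
                seq = list(read_ref)
                if (
                    is_r1
                    and not has_del
                    and config.terminal_mismatch_prob > 0
                    and rng.random() < config.terminal_mismatch_prob
                ):
                    # 2-bp mismatch at the read's 5' terminus
                    idxs = (0, 1) if not rev else (L - 1, L - 2)
                    for i in idxs:
                        seq[i] = _mutate(seq[i], rng)
                    if not rev:
                        md = f"0{read_ref[0]}0{read_ref[1]}{L - 2}"
                    else:
                        md = f"{L - 2}{read_ref[L - 2]}0{read_ref[L - 1]}0"
                out_seq = "".join(seq)
                if rev:
                    out_seq = _revcomp(out_seq)
                pair.append(
                    SamRecord(
                        qname=qname,
                        flag=flag,
                        rname=contig,
                        pos=left,
                        mapq=config.mapq,
                        cigar=cigar,
                        rnext="=",
                        pnext=0,
                        tlen=0,
                        seq=out_seq,
                        md=md,
                    )
                )
            if not pair:
                n_dropped += 1
                continue
            r1, r2 = pair
            r1.pnext, r2.pnext = r2.pos, r1.pos
            tlen = frag
            if r1.pos <= r2.pos:
                r1.tlen, r2.tlen = tlen, -tlen
            else:
                r1.tlen, r2.tlen = -tlen, tlen
            records.extend(pair)
    if n_dropped:
        log.info("simulate_read_pairs: dropped %d breaks (fragment out of bounds)", n_dropped)
    records.sort(key=lambda r: (r.rname, r.pos, r.qname, r.flag))
    return records


def mix_spike(
    records_primary: list[SamRecord],
    records_spike: list[SamRecord],
    fraction: float,
    seed: int = 0,
) -> tuple[list[SamRecord], SpikeInfo]:
    """Mix spike-genome read pairs into a primary library at a set fraction.

    Spike pairs are subsampled so they make up ``fraction`` of the output
    pairs (e.g. 1/101 for a 1:100 molar design); the realised counts are
    reported in the returned :class:`SpikeInfo`.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)

    def pairs(records: list[SamRecord]) -> dict[str, list[SamRecord]]:
        by_name: dict[str, list[SamRecord]] = {}
        for r in records:
            by_name.setdefault(r.qname, []).append(r)
        return by_name

    primary_pairs = pairs(records_primary)
    spike_pairs = pairs(records_spike)
    n_primary = len(primary_pairs)
    n_target = int(round(fraction / (1.0 - fraction) * n_primary))
    names = sorted(spike_pairs)
    if n_target < len(names):
        keep = rng.choice(len(names), size=n_target, replace=False)
        names = [names[i] for i in sorted(keep)]
    combined = list(records_primary)
    for name in names:
        combined.extend(spike_pairs[name])
    combined.sort(key=lambda r: (r.rname, r.pos, r.qname, r.flag))
    return combined, SpikeInfo(reads_primary=n_primary, reads_spike=len(names))
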