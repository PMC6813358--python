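"""Binning, smoothing, aggregation and correlation of break-density tracks.

All coordinates are 1-based; a position p falls in bin floor((p-1)/width).
The strand cross-correlation recovers cleavage-overhang geometry: a
homodimeric enzyme cutting both strands with an n-nucleotide 5' overhang
places the Crick 5' terminus n-1 bases rightward of the Watson terminus,
so the Pearson correlation between strand-specific count vectors peaks at
offset n-1 (3 bp for Top2-like 4-nt overhangs, 1 bp for Spo11-like 2-nt
overhangs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ccseq.breakmap import BreakMap, WATSON, CRICK, STRANDS
from ccseq.calibration import NormalizedTrack

log = logging.getLogger(__name__)


@dataclass
class Locus:
    """A genomic anchor point (TSS, motif centre, ...) with optional covariate."""

    contig: str
    position: int
    strand: str = "."
    covariate: float | None = None
    name: str = ""


@dataclass
class AggregateProfile:
    """Mean signal per offset around a set of loci, in HpM per locus."""

    offsets: np.ndarray
    watson_mean: np.ndarray
    crick_mean: np.ndarray
    n_loci: int
    n_dropped: int = 0

    @property
    def total_mean(self) -> np.ndarray:
        return self.watson_mean + self.crick_mean


@dataclass
class OffsetCorrelation:
    """Watson-vs-Crick correlation as a function of strand offset."""

    offsets: np.ndarray
    r: np.ndarray              # Pearson r per offset, NaN where undefined
    n_sites: np.ndarray
    read_fraction: np.ndarray  # normalised over offsets where defined

    def argmax_offsets(self) -> list[int]:
        """Offset(s) with maximal correlation; ties all reported."""
        if np.all(np.isnan(self.r)):
            return []
        best = np.nanmax(self.r)
        return [int(o) for o, v in zip(self.offsets, self.r) if v == best]


# ---------------------------------------------------------------------------
# binning and smoothing

def bin_positions(
    pos_to_val: dict[int, float], bin_width: int, n_bins: int | None = None
) -> np.ndarray:
    """Sum sparse 1-based position values into fixed-width bins.

    Bin i covers positions i*width+1 .. (i+1)*width.  Total signal is
    conserved.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if n_bins is None:
        n_bins = (max(pos_to_val) - 1) // bin_width + 1 if pos_to_val else 1
    out = np.zeros(n_bins)
    for pos, v in pos_to_val.items():
        idx = (pos - 1) // bin_width
        if 0 <= idx < n_bins:
            out[idx] += v
    return out


def bin_genome(
    track: NormalizedTrack | BreakMap,
    bin_width: int,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Strand-summed bins per contig for a track or raw break map."""
    if isinstance(track, BreakMap):
        combined: dict[str, dict[int, float]] = {}
        for contig, _strand, pos, n in track.iter_sites():
            combined.setdefault(contig, {})
            combined[contig][pos] = combined[contig].get(pos, 0.0) + n
    else:
        combined = {c: track.combined(c) for c in track.contigs}
    out = {}
    for contig, vals in combined.items():
        n_bins = None
        if contig_lengths and contig in contig_lengths:
            n_bins = (contig_lengths[contig] - 1) // bin_width + 1
        out[contig] = bin_positions(vals, bin_width, n_bins)
    return out


def hann_window(window_bins: int) -> np.ndarray:
    """Unit-sum Hann (raised-cosine) kernel with ``window_bins`` nonzero taps."""
    if window_bins < 1:
        raise ValueError(f"window_bins must be >= 1, got {window_bins}")
    w = np.hanning(window_bins + 2)[1:-1]  # drop the structural zeros
    return w / w.sum()


def hann_smooth(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Convolve with a unit-sum Hann kernel, renormalising at the edges.

    Edge bins see a truncated kernel which is renormalised to unit sum, so
    a constant input is returned unchanged everywhere.
    """
    values = np.asarray(values, dtype=float)
    if window_bins <= 1 or values.size == 0:
        return values.copy()
    kern = hann_window(window_bins)
    num = np.convolve(values, kern, mode="same")
    den = np.convolve(np.ones_like(values), kern, mode="same")
    return num / den


def density_smooth(
    pos_to_val: dict[int, float],
    b0: float = 5.0,
    density_window: int = 50,
    grid: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Variable-bandwidth Gaussian smoothing of a sparse track.

    Each hit is spread with a Gaussian whose bandwidth shrinks with the
    local hit density (bandwidth = b0 / (1 + density in a
    ``density_window``-bp window)), so isolated hits are smoothed broadly
    while dense clusters stay sharp.  The kernel for each hit is
    renormalised on the output grid, so total mass is conserved exactly.
    This bandwidth rule is a pragmatic in-house choice, not a normative
    algorithm.  Returns (grid positions, smoothed values).
    """
    if not pos_to_val:
        raise ValueError("cannot density-smooth an empty track")
    positions = np.array(sorted(pos_to_val))
    weights = np.array([pos_to_val[p] for p in positions], dtype=float)
    if grid is None:
        pad = int(4 * b0) + 1
        grid = (int(positions.min()) - pad, int(positions.max()) + pad)
    xs = np.arange(grid[0], grid[1] + 1)
    out = np.zeros_like(xs, dtype=float)
    half = density_window / 2
    for p, w in zip(positions, weights):
        local = weights[(positions >= p - half) & (positions <= p + half)].sum()
        bw = b0 / (1.0 + local / density_window)
        kern = np.exp(-0.5 * ((xs - p) / bw) ** 2)
        total = kern.sum()
        if total > 0:
            out += w * kern / total
    return xs, out


# ---------------------------------------------------------------------------
# locus-centred aggregation and stratification

def aggregate(
    track: NormalizedTrack,
    loci: list[Locus],
    flank: int,
    orient: bool = True,
    bin_width: int = 1,
) -> AggregateProfile:
    """Mean strand-specific signal per offset around a set of loci.

    Offsets run -flank..+flank relative to each locus.  With
    ``orient=True``, minus-strand loci contribute with offsets negated and
    strands swapped, so the profile reads in the loci's own 5'->3' frame.
    Loci whose window would run past a contig end (position - flank < 1)
    are dropped and counted.
    """
    if not loci:
        raise ValueError("no loci to aggregate over")
    offsets = np.arange(-flank, flank + 1)
    width = offsets.size
    w_sum = np.zeros(width)
    c_sum = np.zeros(width)
    n_used = 0
    n_dropped = 0
    for locus in loci:
        if locus.position - flank < 1:
            n_dropped += 1
            continue
        flip = orient and locus.strand == "-"
        for strand, acc in ((WATSON, w_sum), (CRICK, c_sum)):
            vals = track.values.get((locus.contig, strand), {})
            for off in range(-flank, flank + 1):
                v = vals.get(locus.position + off)
                if v:
                    if flip:
                        # mirrored offset, opposite strand accumulator
                        tgt = c_sum if strand == WATSON else w_sum
                        tgt[flank - off] += v
                    else:
                        acc[flank + off] += v
        n_used += 1
    if n_dropped:
        log.info("aggregate: dropped %d loci with out-of-bounds windows", n_dropped)
    if n_used == 0:
        raise ValueError("all loci dropped (windows out of bounds)")
    if bin_width > 1:
        n_bins = width // bin_width
        offsets = offsets[: n_bins * bin_width : bin_width]
        w_sum = w_sum[: n_bins * bin_width].reshape(n_bins, bin_width).sum(axis=1)
        c_sum = c_sum[: n_bins * bin_width].reshape(n_bins, bin_width).sum(axis=1)
    return AggregateProfile(
        offsets=offsets,
        watson_mean=w_sum / n_used,
        crick_mean=c_sum / n_used,
        n_loci=n_used,
        n_dropped=n_dropped,
    )


def stratify(loci: list[Locus], k: int) -> list[list[Locus]]:
    """Split loci into k covariate quantile groups, lowest first.

    Ties are broken by stable input order; group sizes differ by at most
    one.  Loci without a covariate are dropped and logged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    usable = [l for l in loci if l.covariate is not None]
    dropped = len(loci) - len(usable)
    if dropped:
        log.info("stratify: dropped %d loci with missing covariates", dropped)
    order = sorted(range(len(usable)), key=lambda i: (usable[i].covariate, i))
    groups = np.array_split(np.array(order), k)
    return [[usable[i] for i in g] for g in groups]


# ---------------------------------------------------------------------------
# correlation structure

def autocorrelate(
    binned: np.ndarray | dict[str, np.ndarray], max_separation_bins: int
) -> np.ndarray:
    """Pearson autocorrelation of a binned track at increasing bin separations.

    r(s) correlates bin pairs (b_i, b_{i+s}); pairs never span contig
    boundaries.  Zero-variance series give NaN.
    """
    series = [np.asarray(binned, dtype=float)] if isinstance(binned, np.ndarray) else [
        np.asarray(v, dtype=float) for v in binned.values()
    ]
    out = np.full(max_separation_bins + 1, np.nan)
    for s in range(max_separation_bins + 1):
        xs, ys = [], []
        for arr in series:
            if arr.size > s:
                xs.append(arr[: arr.size - s] if s else arr)
                ys.append(arr[s:])
        if not xs:
            continue
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            continue
        out[s] = float(np.corrcoef(x, y)[0, 1])
    return out


def strand_cross_correlation(
    bmap: BreakMap | NormalizedTrack,
    offset_range: tuple[int, int] = (-100, 100),
    min_threshold: float = 0.0,
) -> OffsetCorrelation:
    """Correlate Watson and Crick signal as the Crick strand is offset.

    For each offset d, Watson position w is paired with Crick position
    w + d; only sites where both strands exceed ``min_threshold`` enter
    the Pearson correlation (positive d means the Crick terminus lies d
    bases rightward of the Watson terminus, the 5'-overhang geometry).
    The read fraction per offset is the share of reads falling in the
    paired sites, normalised over the offset range.
    """
    if isinstance(bmap, BreakMap):
        get = lambda c, s: dict(bmap.counts.get((c, s), {}))
        contigs = bmap.contigs
    else:
        get = lambda c, s: bmap.values.get((c, s), {})
        contigs = bmap.contigs
    lo, hi = offset_range
    offsets = np.arange(lo, hi + 1)
    r = np.full(offsets.size, np.nan)
    n_sites = np.zeros(offsets.size, dtype=int)
    reads = np.zeros(offsets.size)
    per_contig = [(get(c, WATSON), get(c, CRICK)) for c in contigs]
    for i, d in enumerate(offsets):
        ws, cs = [], []
        for wvals, cvals in per_contig:
            for w, wv in wvals.items():
                cv = cvals.get(w + d, 0)
                if wv > min_threshold and cv > min_threshold:
                    ws.append(wv)
                    cs.append(cv)
        n_sites[i] = len(ws)
        if ws:
            reads[i] = float(np.sum(ws) + np.sum(cs))
        if len(ws) >= 3:
            wa, ca = np.array(ws, dtype=float), np.array(cs, dtype=float)
            if wa.std() > 0 and ca.std() > 0:
                r[i] = float(np.corrcoef(wa, ca)[0, 1])
    total_reads = reads[~np.isnan(r)].sum()
    frac = np.where(~np.isnan(r), reads / total_reads, np.nan) if total_reads > 0 else np.full_like(reads, np.nan)
    return OffsetCorrelation(offsets=offsets, r=r, n_sites=n_sites, read_fraction=frac)


# ---------------------------------------------------------------------------
# genomic regions

@dataclass
class RegionClass:
    contig: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    label: str   # intragenic | IGR_divergent | IGR_tandem | IGR_convergent

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _merge_genes(
    genes: list[tuple[int, int, str]]
) -> list[tuple[int, int, str, str]]:
    """Union overlapping gene extents; keep boundary strands for gap labels."""
    merged: list[list] = []
    for start, end, strand in sorted(genes):
        if merged and start <= merged[-1][1] + 1:
            if end > merged[-1][1]:
                merged[-1][1] = end
                merged[-1][3] = strand  # strand of the rightmost boundary gene
        else:
            merged.append([start, end, strand, strand])
    return [tuple(m) for m in merged]


def classify_igrs(
    genes: list[tuple[str, int, int, str]]
) -> list[RegionClass]:
    """Partition each contig into intragenic extents and labelled IGRs.

    Gene intervals are 1-based inclusive.  Overlapping genes are unioned;
    each gap between successive merged extents is labelled by the strands
    of its flanking genes: (-, +) divergent (both point away), (+, +) or
    (-, -) tandem, (+, -) convergent (both point toward the gap).  The
    regions before the first and after the last gene are left unlabelled.
    """
    out: list[RegionClass] = []
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for contig, start, end, strand in genes:
        by_contig.setdefault(contig, []).append((start, end, strand))
    for contig in sorted(by_contig):
        merged = _merge_genes(by_contig[contig])
        if len(merged) < 2:
            log.info("classify_igrs: contig %s has < 2 merged genes; gaps unlabelled", contig)
        for start, end, _ls, _rs in merged:
            out.append(RegionClass(contig, start, end, "intragenic"))
        for (s1, e1, _l1, right_strand), (s2, e2, left_strand, _r2) in zip(merged, merged[1:]):
            if s2 - e1 <= 1:
                continue  # abutting extents leave no gap
            if right_strand == "-" and left_strand == "+":
                label = "IGR_divergent"
            elif right_strand == "+" and left_strand == "-":
                label = "IGR_convergent"
            else:
                label = "IGR_tandem"
            out.append(RegionClass(contig, e1 + 1, s2 - 1, label))
    return out


def region_density(
    track: NormalizedTrack,
    regions: list[RegionClass],
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Signal density per region plus Tukey box-and-whisker summaries.

    Density is total strand-summed HpM in the region divided by region
    length.  Summaries per label report quartiles and whiskers at the most
    extreme points within 1.5 x IQR of the quartiles.
    """
    rows = []
    combined = {c: None for c in {r.contig for r in regions}}
    for region in regions:
        if region.length <= 0:
            raise ValueError(f"zero-length region {region}")
        if combined[region.contig] is None:
            combined[region.contig] = track.combined(region.contig)
        vals = combined[region.contig]
        total = sum(
            v for p, v in vals.items() if region.start <= p <= region.end
        )
        rows.append(
            {
                "contig": region.contig,
                "start": region.start,
                "end": region.end,
                "label": region.label,
                "density": total / region.length,
            }
        )
    table = pd.DataFrame(rows)
    summary: dict[str, dict[str, float]] = {}
    for label, grp in table.groupby("label"):
        d = grp["density"].to_numpy()
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        in_lo = d[d >= q1 - 1.5 * iqr]
        in_hi = d[d <= q3 + 1.5 * iqr]
        summary[label] = {
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "whisker_low": float(in_lo.min()) if in_lo.size else float(q1),
            "whisker_high": float(in_hi.max()) if in_hi.size else float(q3),
            "n": int(d.size),
        }
    return table, summary


def call_peaks(
    track: NormalizedTrack, threshold: float = 0.05
) -> list[tuple[str, int, float]]:
    """Positions whose strand-summed signal is >= threshold (inclusive).

    The default 0.05 HpM cutoff defines peak coordinates on pooled data;
    the comparison is inclusive so boundary sites are retained.
    """
    peaks = []
    for contig in track.contigs:
        for pos, v in sorted(track.combined(contig).items()):
            if v >= threshold:
                peaks.append((contig, pos, v))
    return peaks


def quantify_vs_covariate(
    track: NormalizedTrack,
    loci: list[Locus],
    window: tuple[int, int],
    log_transform: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Correlate per-locus signal with a covariate (e.g. transcription rate).

    Signal is tallied over ``window`` = (upstream_offset, downstream_offset)
    relative to each locus, oriented by locus strand.  Returns Pearson r
    against the (optionally log-transformed) covariate and Spearman r_s
    against the raw covariate, plus the per-locus table.  Loci with
    nonpositive covariates are dropped when log-transforming.
    """
    rows = []
    n_dropped = 0
    for locus in loci:
        if locus.covariate is None:
            n_dropped += 1
            continue
        if log_transform and locus.covariate <= 0:
            n_dropped += 1
            continue
        lo, hi = window
        if locus.strand == "-":
            lo, hi = -hi, -lo
        start = locus.position + lo
        end = locus.position + hi
        total = 0.0
        for strand in STRANDS:
            vals = track.values.get((locus.contig, strand), {})
            total += sum(v for p, v in vals.items() if start <= p <= end)
        rows.append({"name": locus.name, "signal": total, "covariate": locus.covariate})
    if n_dropped:
        log.info("quantify_vs_covariate: dropped %d loci", n_dropped)
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 usable loci for correlation")
    x = np.log(table["covariate"]) if log_transform else table["covariate"]
    pearson = float(sstats.pearsonr(table["signal"], x)[0])
    spearman = float(sstats.spearmanr(table["signal"], table["covariate"])[0])
    return pearson, spearman, table
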