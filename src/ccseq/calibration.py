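"""Depth normalisation, spike-in calibration and background-noise estimation.

Break counts are reported in HpM — hits per million mapped read pairs per
base pair — so that libraries of different depth are comparable.  Absolute
calibration between samples uses a spike-in genome mixed at a known molar
ratio: every value is multiplied by the reciprocal of the fraction of
spike reads recovered in that sample.  The background-noise ratio between
a treated and an untreated sample is estimated NCIS-style from the
subpopulation of large genomic bins with the lowest signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ccseq.breakmap import BreakMap, STRANDS


@dataclass
class NormalizedTrack:
    """Sparse per-(contig, strand) track of HpM values."""

    values: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    total_mapped_pairs: int = 0
    calibration_factor: float = 1.0
    genome_id: str = ""
    sample_id: str = ""

    def strand_values(self, contig: str, strand: str) -> dict[int, float]:
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        return self.values.setdefault((contig, strand), {})

    @property
    def contigs(self) -> list[str]:
        return sorted({c for (c, _s) in self.values})

    def combined(self, contig: str) -> dict[int, float]:
        """Strand-summed values for one contig."""
        out: dict[int, float] = {}
        for strand in STRANDS:
            for pos, v in self.values.get((contig, strand), {}).items():
                out[pos] = out.get(pos, 0.0) + v
        return out

    def total_signal(self) -> float:
        return sum(sum(d.values()) for d in self.values.values())

    def scaled(self, factor: float) -> "NormalizedTrack":
        return NormalizedTrack(
            values={
                k: {p: v * factor for p, v in d.items()}
                for k, d in self.values.items()
            },
            total_mapped_pairs=self.total_mapped_pairs,
            calibration_factor=self.calibration_factor * factor,
            genome_id=self.genome_id,
            sample_id=self.sample_id,
        )


@dataclass
class SpikeInfo:
    """Read counts from the two alignment passes of a spiked library."""

    reads_primary: int
    reads_spike: int

    @property
    def fraction_spike(self) -> float:
        return self.reads_spike / (self.reads_primary + self.reads_spike)


@dataclass
class NoiseEstimate:
    """Noise densities of a treated/control pair and their ratio r.

    r = d_treated / d_control scales the control so its background matches
    the treated sample's.
    """

    d_treated: float
    d_control: float
    bin_width: int
    low_fraction: float

    @property
    def ratio(self) -> float:
        return self.d_treated / self.d_control


def to_hpm(bmap: BreakMap) -> NormalizedTrack:
    """Convert raw counts to hits per million mapped read pairs."""
    if bmap.total_mapped_pairs <= 0:
        raise ValueError("cannot normalise a map with zero mapped pairs")
    scale = 1e6 / bmap.total_mapped_pairs
    track = NormalizedTrack(
        total_mapped_pairs=bmap.total_mapped_pairs,
        genome_id=bmap.genome_id,
        sample_id=bmap.sample_id,
    )
    for contig, strand, pos, n in bmap.iter_sites():
        track.strand_values(contig, strand)[pos] = n * scale
    return track


def spike_calibrate(track: NormalizedTrack, spike: SpikeInfo) -> NormalizedTrack:
    """Calibrate by the reciprocal fraction of spike-genome reads.

    With a fixed molar spike ratio, the fraction of reads aligning to the
    spike genome measures recovery efficiency; dividing by it puts samples
    on a common absolute scale.
    """
    f = spike.fraction_spike
    if not 0.0 < f < 1.0:
        raise ValueError(f"spike fraction must be in (0, 1), got {f}")
    return track.scaled(1.0 / f)


def _binned_totals(
    track: NormalizedTrack,
    bin_width: int,
    contig_lengths: dict[str, int],
) -> np.ndarray:
    """Strand-summed bin totals over the whole genome, zeros included."""
    chunks = []
    for contig in sorted(contig_lengths):
        n_bins = int(np.ceil(contig_lengths[contig] / bin_width))
        vals = np.zeros(max(n_bins, 1))
        for pos, v in track.combined(contig).items():
            vals[(pos - 1) // bin_width] += v
        chunks.append(vals)
    return np.concatenate(chunks) if chunks else np.zeros(0)


def _infer_contig_lengths(*tracks: NormalizedTrack) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for track in tracks:
        for (contig, _strand), d in track.values.items():
            if d:
                lengths[contig] = max(lengths.get(contig, 0), max(d))
    return lengths


def estimate_noise_ratio(
    track_treated: NormalizedTrack,
    track_control: NormalizedTrack,
    bin_width: int = 10_000,
    low_fraction: float = 0.5,
    contig_lengths: dict[str, int] | None = None,
) -> NoiseEstimate:
    """Estimate the treated/control background ratio from low-signal bins.

    Both tracks are binned at ``bin_width`` over the same genome.  In each
    sample independently, the ``low_fraction`` of bins with the lowest
    signal is taken as background; the mean density over that
    subpopulation is the sample's noise density d, and r = d_treated /
    d_control.  Low-signal bins are dominated by untemplated background,
    so r measures how much background the treated library carries relative
    to the control.
    """
    if not 0.0 < low_fraction <= 1.0:
        raise ValueError(f"low_fraction must be in (0, 1], got {low_fraction}")
    if contig_lengths is None:
        contig_lengths = _infer_contig_lengths(track_treated, track_control)
    densities = []
    for track in (track_treated, track_control):
        bins = _binned_totals(track, bin_width, contig_lengths)
        if bins.size == 0:
            raise ValueError("empty track: no bins to estimate noise from")
        n_low = max(1, int(np.floor(low_fraction * bins.size)))
        low = np.sort(bins)[:n_low]
        densities.append(float(low.mean()))
    d_treated, d_control = densities
    if d_control == 0.0:
        raise ValueError("control noise density is zero; ratio undefined")
    return NoiseEstimate(
        d_treated=d_treated,
        d_control=d_control,
        bin_width=bin_width,
        low_fraction=low_fraction,
    )


def prepare_broadscale(
    track: NormalizedTrack,
    bin_width: int = 10_000,
    noise: NoiseEstimate | None = None,
    window_bins: int = 10,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Bin, smooth and median-subtract a track for broad-scale comparison.

    Pipeline: optional scaling by the noise ratio r (applied when ``noise``
    is given, e.g. to put a control on the treated sample's background
    scale) -> binning at ``bin_width`` -> Hann smoothing over
    ``window_bins`` bins -> subtraction of the genome-wide median of the
    smoothed bins.  Returns one array of bin values per contig.
    """
    from ccseq.signal_analysis import hann_smooth

    if contig_lengths is None:
        contig_lengths = _infer_contig_lengths(track)
    scale = noise.ratio if noise is not None else 1.0
    binned: dict[str, np.ndarray] = {}
    for contig in sorted(contig_lengths):
        n_bins = int(np.ceil(contig_lengths[contig] / bin_width))
        vals = np.zeros(max(n_bins, 1))
        for pos, v in track.combined(contig).items():
            vals[(pos - 1) // bin_width] += v * scale
        binned[contig] = hann_smooth(vals, window_bins)
    all_bins = np.concatenate(list(binned.values()))
    med = float(np.median(all_bins))
    return {c: v - med for c, v in binned.items()}
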