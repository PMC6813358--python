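# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that are not forced by the science.

## Terminal mapping

Covalent-complex libraries attach distinguishable adapters to the two ends
of each sonication fragment; the protein-linked (cleaved) end always
becomes Read-1.  The mapper therefore emits exactly one count per accepted
pair, at Read-1's 5′ coordinate on Read-1's strand, and never uses Read-2
as a break coordinate (Read-2's 5′ end is the random sonication point).

A pair is accepted only when its flags are (99, 147) or (83, 163) —
properly paired, both mates fully aligned, Read-1 defining the strand.
All other combinations (unmapped, discordant, secondary, mates on
different contigs) are rejected; classification is symmetric in mate
order.  Mapping-quality filtering applies to both mates before anything
else is examined; the default threshold is 0, with 10 recommended for
repeat-rich mammalian genomes.

**Coordinate calling.**  Coordinates are 1-based inclusive on the
reference top strand everywhere inside the package; the 0-based half-open
convention of BED/bedGraph applies only at file boundaries.  For a
minus-strand read the 5′ coordinate is leftmost + span − 1 where span sums
CIGAR ops with weights M = 1, D = 1, I = 0, S = 0: insertions and soft
clips occupy no reference bases, so they must not shift the call.  This
rule is tested against a literal base-by-base reference walk on 10,000
random CIGARs.

**Ambiguous ends.**  The MD:Z tag is expanded into per-reference-position
match/mismatch flags (deleted bases count as mismatched).  The run of
consecutive non-matching positions at the read's 5′ terminus is measured
from the left end of the MD walk for plus-strand reads and from the right
end for minus-strand reads, since MD always runs reference-left→right,
which is read 3′→5′ on the minus strand.  Runs of ≥ 2 (parameter
`max_end_mismatch`, default 1) disqualify the pair: two independent
terminal mismatches are far more likely to be an end-repair or alignment
artefact than two sequencing errors, and the terminus is exactly the
quantity being mapped.  Soft-clipped 5′ bases count toward the run for the
same reason — a clipped terminus is positionally uninformative.  In
`single` mode only Read-1 is checked; in `double` mode (both ends
adapter-defined) either read's 5′ end can disqualify the pair.  Duplicate
pairs are retained: cleavage hotspots legitimately produce identical
fragments, so deduplication would clip real dynamic range.

**Region masks** are half-open `[start, end)` intervals in the internal
1-based coordinate space (BED input is shifted by +1 on read).  Masking
removes counts but deliberately leaves `total_mapped_pairs` unchanged, so
HpM normalisation still refers to the sequenced library, not to the
surviving subset.

## Normalisation, calibration, noise

HpM = count × 10⁶ / total mapped pairs.  Spike-in calibration multiplies
every value by the reciprocal of the realised spike-read fraction; with a
fixed molar spike ratio this cancels recovery-efficiency differences
between samples, and the factor is recorded on the track.

The background-noise ratio between a treated and an untreated sample is
estimated from 10-kb bins (parameter).  In each sample independently, the
lowest-signal fraction of bins (parameter `low_fraction`, default 0.5) is
taken as background and its mean density is that sample's noise density
*d*; the ratio r = d_treated / d_control scales the control onto the
treated sample's background level.  The low fraction is a free parameter
because this family of estimators is stable over a broad low quantile; it
is recorded in the result so runs are reproducible.  Bins are selected
per-sample, not as an intersection — the procedure is the per-sample
definition of "lowest-signal subpopulation".  Note the estimator assumes
the two samples' background distributions differ by a scale factor; if
their shapes differ (e.g. very different depths and strong Poisson
truncation), the lower-half mean introduces a small bias.

Broad-scale preparation: optional scaling of the control by r → binning →
smoothing with a 10-bin Hann (raised-cosine) window → subtraction of the
genome-wide median of the smoothed bins.  The Hann kernel is normalised to
unit sum, and edges are renormalised over the truncated kernel so a
constant track maps to itself.  The kernel is built as `hanning(n + 2)`
with the structural zero endpoints dropped, so `window_bins` counts
nonzero taps and a 1-bin window is the identity.

## Signal analysis

Bin assignment: 1-based position p → bin ⌊(p − 1)/width⌋; binning
conserves total signal exactly.

Locus aggregation sums strand-specific signal at offsets −flank..+flank
around each locus and divides by the number of usable loci; for
minus-strand loci (orientation on) offsets are negated and strands
swapped, so profiles read in the locus's own 5′→3′ frame.  Out-of-bounds
loci are dropped and counted.  Covariate stratification sorts stably and
splits into quantile groups differing by at most one locus.

Strand cross-correlation: for each offset d ∈ [−100, 100], Watson
position w is paired with Crick position w + d; only sites with hits on
both strands (above an optional threshold) enter the Pearson correlation.
Positive d means the Crick terminus lies rightward, the 5′-overhang
geometry, so the argmax recovers overhang − 1.  The read fraction per
offset is normalised after site-threshold filtering, over the offset
range.  Ties in the argmax are all reported.

The fine-scale variable-bandwidth smoother (`density_smooth`) is an
in-house rule — Gaussian kernels with bandwidth b₀ / (1 + local hit
density in a 50-bp window), each kernel renormalised on the grid so mass
is conserved — documented as nonnormative: it reproduces the qualitative
behaviour (isolated hits smoothed broadly, dense clusters kept sharp)
without claiming to match any specific published smoother.

Intergenic classification: overlapping gene extents are unioned; each gap
between successive merged extents is labelled by its flanking strands —
(−, +) divergent, (+, +)/(−, −) tandem, (+, −) convergent — with the
boundary gene's strand used when a merged cluster mixes strands.  The
spans before the first and after the last gene are left unlabelled.
Region densities are Σ signal / length with Tukey box-and-whisker
summaries (whiskers at the most extreme points within 1.5 × IQR).

Peak calling keeps positions with strand-summed signal ≥ threshold
(default 0.05 HpM); the comparison is inclusive so boundary-valued sites
are retained.

## Cognate fractionation

Pairing at a fixed offset is bijective (w ↔ w + offset), so no position
contributes twice on a strand; sites with signal on only one strand take
zero on the other — they are precisely the candidate SSB signatures, so
excluding them would bias the test.  λ for the cognate simulation is
computed on raw counts, not HpM, keeping the Poisson model on the count
scale.

The disparity test conditions on the site total n: under equal rates with
equal exposure, W | n ~ Binomial(n, ½).  The two-sided p-value uses the
minimum-likelihood rule (sum of all outcome probabilities no larger than
the observed one); for this symmetric null it coincides with doubled
tails capped at 1, but the rule is fixed for reproducibility.  The
implementation is verified against an exact-rational enumeration oracle
for all totals ≤ 30 and against `scipy.stats.binomtest`.  Defaults follow
the standard analysis: minimum total 8 (below which the test has
essentially no power), α = 0.05 for noncognate, p > 0.95 for highly
cognate.  No multiple-testing correction is applied; the per-site α is the
classification boundary by design, and the 100 %-cognate simulation
quantifies the resulting false-positive rate empirically.

Amplitude shuffling permutes the count multiset among the *occupied*
positions of each (contig, strand) — not over all genomic positions — so
both marginal amplitude distributions are preserved while Watson–Crick
pairing is destroyed.

## Sequence bias

Weight normalisation rescales each site to a common total (default 100)
preserving the strand ratio, so that coverage differences between loci do
not dominate the composition average while strand disparity still controls
how much each strand's sequence is sampled.

The dyad axis is w + (overhang − 1)/2, a half-integer for even overhangs;
single-strand-only sites use an inferred dyad at the same relative
position (for Crick-only sites the mirror convention gives the same
coordinate, since the pairing offset is fixed).  Position labels are
signed integers with no zero; −1/+1 are the two central overhang bases,
and the base 5′ of the Watson scissile phosphate is −3 for a 4-nt
overhang.  The window default is ±20 bp.

Watson-weighted accumulation reads the top strand 5′→3′; Crick-weighted
accumulation reads the bottom strand 5′→3′, which in the top-strand frame
is the complement at the mirrored offset.  Reported fractions are
top-strand-equivalent, so rotationally symmetric cleavage chemistry
yields a profile with fraction(b, +k) = fraction(complement(b), −k).
Ambiguous bases are masked from numerator and denominator, not counted as
a fifth symbol.

χ² goodness-of-fit uses effective weights as counts with 3 degrees of
freedom per position.  Log₂ deviations are taken against the per-base mean
fraction over the whole window (a whole-window local average, rather than
a sliding one, keeps the reference independent of position); zero
fractions are floored at a pseudo-fraction (default 10⁻³) and logged.

## Simulator

The generator emulates: i.i.d. genomes at a target GC; cleavage sites with
minimum spacing and Gamma(shape 1.5, scale 10) intensities (skewed
dynamic range with mean 15 events per site at depth 1 — hotspot-like);
DSB events placing Watson and Crick termini at the overhang offset;
strand-biased SSB events placing a terminus on one strand only (sonication
converts a 5′-linked SSB into a mappable end, so SSBs yield normal
one-strand pairs); truncated-normal fragment lengths (mean 350 bp,
sd 50 bp, matching sonication to 300–400 bp) with the mate on the opposite
strand extending away from the protein-linked terminus; optional 2-bp
terminal mismatches and internal 1-bp deletions with CIGAR/MD kept
consistent (deletion-carrying minus-strand reads get compensated leftmost
coordinates so the 5′ call is unaffected); spike-genome mixing at a target
fraction; and planted base preferences applied symmetrically
(complemented at the mirrored offset) at DSB-capable sites.

It does **not** emulate: base-quality variation, PCR duplicates,
alignment errors or multi-mapping (reads are emitted as truthful
alignments, so MAPQ filtering is exercised only synthetically),
non-uniform sonication breakpoints, or enrichment-efficiency variation
between sites.  Consequently, passing round-trip tests shows the mapper
inverts the simulator's read model exactly; it does not certify behaviour
on aligner-specific quirks (e.g. unusual CIGAR/MD combinations) beyond
those generated.  One structural difference from real libraries: a
simulated DSB event emits both of its ends, so Watson and Crick counts at
a pure DSB site are equal by construction rather than independently
Poisson; the exact test is therefore conservative on simulator output, and
the 100 %-cognate resampling (which redraws both strands independently) is
the right null for calibrating noncognate rates.

## Problem sizes and determinism

Tests and the acceptance script run on desk-scale problems chosen to make
the statistics decisive while keeping runs fast: 100–400-kb genomes,
200–1,000 sites, ~10⁵ sites for the type-I-error bound, 250-site
λ ≥ 10 libraries for the geometry recovery (at which depth the
cross-correlation argmax is deterministic across seeds).  All generators
take explicit seeds and are bit-reproducible for a fixed seed and package
version; the pipeline runner writes data artifacts byte-identically across
reruns of the same config (the JSON run log carries wall-clock timestamps
and is exempt from that guarantee).

## Known limitations

- The noise-ratio estimator inherits the scale-family assumption noted
  above.
- `DOUBLE` library mode changes only the ambiguity filtering; Read-2
  termini are never emitted as a second break map.
- The variable-bandwidth smoother is a declared stand-in, suitable for
  display, not inference.
- Chimeric/supplementary alignments are rejected rather than resolved.
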