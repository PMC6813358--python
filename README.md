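# ccseqtools

Nucleotide-resolution, strand-specific mapping and analysis of covalent
protein-linked DNA break termini from paired-end sequencing.

Type II topoisomerases (Top2) and the meiotic DSB enzyme Spo11 cleave DNA
while covalently attached, via a phosphotyrosyl bond, to the 5′ terminus
they create.  Enrichment protocols for these covalent complexes ligate a
distinguishable adapter to the protein-linked end, so that after paired-end
sequencing and alignment, **Read-1's 5′ terminus is the cleavage
coordinate, at single-base and single-strand resolution**.  This package
turns such alignments into strand-specific break maps and implements the
downstream statistics used to characterise them.  It is aimed at
researchers analysing Top2/Spo11 covalent-complex sequencing libraries (or
any protocol with an adapter-defined informative read end), and at anyone
who wants a fully simulated, ground-truth-tested version of that pipeline.

## What it computes

**Terminal mapping.** Only proper pairs with SAM flags (99, 147)
(Watson-strand break) or (83, 163) (Crick-strand break) are informative.
For a plus-strand read the 5′ end is the SAM leftmost coordinate; for a
minus-strand read the CIGAR is scored over the reference (M = 1, D = 1,
I = 0, S = 0) and

&nbsp;&nbsp;&nbsp;&nbsp;5′ = leftmost + Σ(ref-consuming ops) − 1,

so a read at leftmost 10200 with CIGAR `35M2D10M3I30M` is called at
10200 + 35 + 2 + 10 + 30 − 1 = **10276**.  Pairs whose informative 5′ end
carries ≥ 2 bp of mismatched/absent bases (from the MD:Z tag, plus any 5′
soft clip) are positionally ambiguous and discarded.

**Calibration and noise.** Counts are reported in HpM (hits per million
mapped read pairs).  Spike-in calibration multiplies by the reciprocal
fraction of spike-genome reads.  The treated/control background ratio
*r* = *d*₊ / *d*₋ is estimated NCIS-style from the mean density of the
lowest-signal half of 10-kb bins in each sample.

**Overhang geometry.** Double-strand cleavage with an *n*-nt 5′ overhang
places the Crick terminus *n* − 1 bp rightward of the Watson terminus, so
the Pearson correlation between strand-specific count vectors peaks at
offset 3 for Top2 (4-nt overhang) and 1 for Spo11 (2-nt overhang).

**Cognate fractionation.** Watson/Crick positions are paired at the
overhang offset and each site's strand disparity is tested with the exact
conditional Poisson test: given total *n* = W + C, W ~ Binomial(*n*, ½)
under equal rates; two-sided *p* by the minimum-likelihood rule.  Sites
with *n* < 8 are excluded; *p* ≤ 0.05 → noncognate (SSB-like),
*p* > 0.05 → cognate (DSB-like), *p* > 0.95 → highly cognate.  Reference
datasets: a 100 %-cognate Poisson resampling (λ = site strand mean) and an
amplitude-shuffled randomisation.

**Sequence bias.** Per-site signal is normalised to a common total
(W30:C10 → W75:C25) without changing the strand ratio, and nucleotide
composition is accumulated 5′→3′ on both strands around the dyad axis
(midpoint of the central overhang bases), weighted by the normalised
values, with χ² goodness-of-fit tests and log₂-deviation matrices.

**Simulation.** A generator produces genomes, gamma-distributed cleavage
sites with configurable overhang and DSB/SSB mixtures, sonication-style
read pairs (SAM), terminal mismatches/indels for the ambiguity filter,
spike-in mixing, and planted base preferences — every stage of the
pipeline is testable against known ground truth.

## Worked example

```sh
python examples/02_overhang_geometry.py
```

prints

```
Top2-like (overhang 4 nt): argmax offset = 3 bp, r = 1.000, inferred overhang = 4 nt
Spo11-like (overhang 2 nt): argmax offset = 1 bp, r = 1.000, inferred overhang = 2 nt
```

i.e. the strand cross-correlation of a simulated 250-site library peaks at
exactly overhang − 1, recovering the cleavage geometry from the mapped
reads alone.  `examples/03_cognate_fractionation.py` runs the disparity
analysis on a library with 30 % Watson-biased SSBs:

```
          dataset  n_tested  noncognate  cognate  highly_cognate
         observed       295         8.1     91.9             5.8
simulated_cognate       295         4.1     95.9            21.4
       randomized       300        49.7     50.3             6.0
```

The observed library sits between the 100 %-cognate simulation (upper
bound; its noncognates are exact-test false positives) and the shuffled
randomisation (lower bound; pairing destroyed).  The other examples cover
mapping round trips, planted-motif recovery and calibration.

A thin CLI wraps the same functions
(`ccseq map|simulate|normalize|calibrate|correlate-strands|autocorrelate|aggregate|regions|peaks|cognate|seqbias|run`);
see `ccseq --help`.

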