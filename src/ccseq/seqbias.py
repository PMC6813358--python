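"""Dyad-centred, signal-weighted DNA sequence composition.

The dyad axis is the twofold symmetry centre of a cleavage site: the
midpoint of the central two base pairs of the 5' overhang, a half-integer
reference coordinate.  Positions are labelled by signed integer offsets
with no zero; -1/+1 are the two bases flanking the dyad, and for a 4-nt
overhang the base 5' of the Watson scissile phosphate sits at -3.

To stop locus-to-locus coverage differences (chromatin accessibility,
copy number) from dominating the average, each site's Watson+Crick signal
is first normalised to a common total while preserving the strand ratio;
sequences are then accumulated 5'->3' on each strand with these weights,
Crick reads entering mirror-complemented so the profile is reported in the
top-strand frame.  A rotationally symmetric cleavage chemistry then shows
up as a profile symmetric about the dyad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_site_weights(
    sites: pd.DataFrame, common_total: float = 100.0
) -> pd.DataFrame:
    """Equalise per-site totals without changing the Watson:Crick ratio.

    (w, c) -> common_total * (w, c) / (w + c); e.g. W30:C10 -> W75:C25.
    Requires columns ``w`` and ``c``; adds ``w_weight`` and ``c_weight``.
    """
    w = sites["w"].to_numpy(dtype=float)
    c = sites["c"].to_numpy(dtype=float)
    total = w + c
    if np.any(total <= 0):
        raise ValueError("every site needs w + c > 0 to normalise")
    out = sites.copy()
    out["w_weight"] = common_total * w / total
    out["c_weight"] = common_total * c / total
    return out


def dyad_axis(watson_pos: int, overhang: int = 4) -> float:
    """Dyad-axis coordinate for a site anchored at Watson position w.

    For a pair (w, c = w + overhang - 1) the dyad is the midpoint
    w + (overhang - 1) / 2 — a half-integer for even overhangs.  Sites
    detected on one strand only use an inferred dyad at the same relative
    position (the mirror convention makes Watson-only and Crick-only
    sites coincide because crick_pos - watson_pos is fixed).
    """
    if overhang < 1:
        raise ValueError(f"overhang must be >= 1, got {overhang}")
    return watson_pos + (overhang - 1) / 2.0


def offset_coordinate(dyad: float, k: int) -> int:
    """Reference coordinate of dyad-offset label k (no zero label).

    k = -1/+1 are the central two bases; coordinates step outward by one.
    """
    if k == 0:
        raise ValueError("offset labels have no zero")
    return int(round(dyad + k + 0.5)) if k < 0 else int(round(dyad + k - 0.5))


@dataclass
class CompositionProfile:
    """Per-position base fractions around the dyad, signal-weighted.

    ``fractions`` is indexed by the signed offset labels with columns
    A/C/G/T summing to 1 where weight is nonzero; ``weights`` is the
    effective accumulated weight per position.  Values are top-strand.
    """

    fractions: pd.DataFrame
    weights: pd.Series
    n_sites: int
    n_dropped: int = 0

    @property
    def positions(self) -> np.ndarray:
        return self.fractions.index.to_numpy()


def _fetch(genome, contig: str, start1: int, end1: int) -> str:
    """Sequence for 1-based inclusive [start1, end1], uppercase."""
    if isinstance(genome, dict):
        return genome[contig][start1 - 1 : end1].upper()
    # pyfaidx.Fasta and similar mappings with slice access
    return str(genome[contig][start1 - 1 : end1]).upper()


def weighted_composition(
    sites: pd.DataFrame,
    genome,
    flank: int = 20,
    overhang: int = 4,
) -> CompositionProfile:
    """Signal-weighted nucleotide composition around site dyads.

    ``sites`` needs columns contig, watson_pos, w_weight, c_weight (from
    :func:`normalize_site_weights`).  For each site the top-strand window
    is accumulated with the Watson weight, and the bottom-strand 5'->3'
    read-out (mirror-complemented back onto the top-strand frame) with the
    Crick weight — so sequence around a site is sampled in proportion to
    the strand disparity of its signal.  Ambiguous bases are masked from
    both numerator and denominator; sites too close to a contig end are
    dropped and logged.
    """
    labels = np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])
    counts = pd.DataFrame(0.0, index=labels, columns=list(BASES))
    weights = pd.Series(0.0, index=labels)
    n_used = 0
    n_dropped = 0
    contig_len_cache: dict[str, int] = {}
    for row in sites.itertuples(index=False):
        dyad = dyad_axis(int(row.watson_pos), overhang)
        lo = offset_coordinate(dyad, -flank)
        hi = offset_coordinate(dyad, flank)
        contig = row.contig
        if contig not in contig_len_cache:
            contig_len_cache[contig] = (
                len(genome[contig]) if not isinstance(genome, dict) else len(genome[contig])
            )
        if lo < 1 or hi > contig_len_cache[contig]:
            n_dropped += 1
            continue
        window = _fetch(genome, contig, lo, hi)  # labels -flank..+flank in order
        for i, k in enumerate(labels):
            base = window[i]
            if base in BASES:
                counts.at[k, base] += row.w_weight
                weights[k] += row.w_weight
            # Crick read-out at label k is the complement of the base at -k
            mirror = window[len(labels) - 1 - i]
            mbase = mirror.translate(_COMPLEMENT)
            if mbase in BASES:
                counts.at[k, mbase] += row.c_weight
                weights[k] += row.c_weight
        n_used += 1
    if n_dropped:
        log.info("weighted_composition: dropped %d sites near contig ends", n_dropped)
    fractions = counts.div(weights.replace(0.0, np.nan), axis=0)
    return CompositionProfile(
        fractions=fractions, weights=weights, n_sites=n_used, n_dropped=n_dropped
    )


def chi_squared_bias(
    profile: CompositionProfile,
    background: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Goodness-of-fit of each position's composition against a background.

    Effective weights serve as counts; the statistic is the usual
    sum((O - E)^2 / E) with 3 degrees of freedom per position.  Default
    background is uniform (0.25 each).
    """
    if background is None:
        background = {b: 0.25 for b in BASES}
    rows = []
    for k in profile.positions:
        weight = profile.weights[k]
        if weight <= 0:
            continue
        obs = profile.fractions.loc[k, list(BASES)].to_numpy() * weight
        exp = np.array([background[b] for b in BASES]) * weight
        if np.any((exp == 0) & (obs > 0)):
            raise ValueError(f"zero background with nonzero observed at position {k}")
        stat = float(np.sum((obs - exp) ** 2 / np.where(exp > 0, exp, 1.0)))
        rows.append({"position": k, "statistic": stat, "dof": 3, "p": float(chi2.sf(stat, 3))})
    return pd.DataFrame(rows).set_index("position")


@dataclass
class BiasMatrices:
    """Log2 deviations from the local average composition.

    ``deviation_*`` are base x position log2(fraction / window-mean
    fraction of that base); ``sum_abs_*`` collapse them per position; the
    difference matrix is |cognate - noncognate| per cell, also summed per
    position.
    """

    deviation_cognate: pd.DataFrame
    deviation_noncognate: pd.DataFrame
    sum_abs_cognate: pd.Series
    sum_abs_noncognate: pd.Series
    difference: pd.DataFrame
    sum_abs_difference: pd.Series


def _log2_deviation(profile: CompositionProfile, pseudo_fraction: float) -> pd.DataFrame:
    frac = profile.fractions[list(BASES)]
    local_avg = frac.mean(axis=0)  # per-base mean over the whole window
    clipped = frac.clip(lower=pseudo_fraction)
    if (frac < pseudo_fraction).any().any():
        log.info("deviation floored at pseudo-fraction %g", pseudo_fraction)
    return np.log2(clipped.div(local_avg, axis=1))


def deviation_matrices(
    profile_cognate: CompositionProfile,
    profile_noncognate: CompositionProfile,
    pseudo_fraction: float = 1e-3,
) -> BiasMatrices:
    """Log2-deviation matrices and the cognate-vs-noncognate difference."""
    if not np.array_equal(profile_cognate.positions, profile_noncognate.positions):
        raise ValueError("profiles must share the same position labels")
    dev_c = _log2_deviation(profile_cognate, pseudo_fraction)
    dev_n = _log2_deviation(profile_noncognate, pseudo_fraction)
    diff = (dev_c - dev_n).abs()
    return BiasMatrices(
        deviation_cognate=dev_c,
        deviation_noncognate=dev_n,
        sum_abs_cognate=dev_c.abs().sum(axis=1),
        sum_abs_noncognate=dev_n.abs().sum(axis=1),
        difference=diff,
        sum_abs_difference=diff.sum(axis=1),
    )
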