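"""Cognate/noncognate fractionation of strand-paired cleavage sites.

A homodimeric type-II topoisomerase cleaving both strands leaves a Watson
and a Crick 5' terminus at a fixed offset (3 bp for a 4-nt overhang).
At a genuine double-strand cleavage site the two strand counts are draws
from the same underlying rate, so strand disparity is evidence of
single-strand cleavage.  Each offset-paired site is tested with the exact
two-sample Poisson test: conditional on the total, the Watson count is
Binomial(total, 1/2) under equal rates, and the two-sided p-value follows
the minimum-likelihood rule.  Sites with p <= alpha are noncognate,
p > alpha cognate, p > hi highly cognate; totals below ``min_total`` lack
power and are excluded.  No multiple-testing correction is applied: the
per-site alpha is the classification boundary by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from ccseq.breakmap import BreakMap, WATSON, CRICK


def pair_offset_sites(bmap: BreakMap, offset: int = 3) -> pd.DataFrame:
    """Pair Watson and Crick positions at a fixed strand offset.

    Every Watson position w and/or Crick position w + offset with a
    nonzero count yields one site; the absent strand contributes zero.
    The pairing is bijective (w <-> w + offset), so no position is used
    twice on the same strand.  Columns: contig, watson_pos, crick_pos,
    w, c, total.
    """
    if offset < 0:
        raise ValueError(f"offset must be >= 0, got {offset}")
    rows = []
    for contig in bmap.contigs:
        wc = bmap.counts.get((contig, WATSON), {})
        cc = bmap.counts.get((contig, CRICK), {})
        anchors = set(wc) | {p - offset for p in cc}
        for w_pos in sorted(anchors):
            w = wc.get(w_pos, 0)
            c = cc.get(w_pos + offset, 0)
            rows.append(
                {
                    "contig": contig,
                    "watson_pos": w_pos,
                    "crick_pos": w_pos + offset,
                    "w": w,
                    "c": c,
                    "total": w + c,
                }
            )
    return pd.DataFrame(
        rows, columns=["contig", "watson_pos", "crick_pos", "w", "c", "total"]
    )


def poisson_exact_test(w_count: int, c_count: int) -> float:
    """Exact two-sided test of equal Poisson rates for two counts.

    Conditional on the total n = w + c, the Watson count is
    Binomial(n, 1/2) under the null of equal rates with equal exposure.
    The two-sided p-value sums the probability of every outcome no more
    likely than the observed one (minimum-likelihood rule); for this
    symmetric null that equals the doubled tail capped at 1.
    """
    n = w_count + c_count
    if n < 1:
        raise ValueError("total count must be >= 1")
    if w_count < 0 or c_count < 0:
        raise ValueError("counts must be non-negative")
    pmf = binom.pmf(np.arange(n + 1), n, 0.5)
    observed = pmf[w_count]
    return float(min(1.0, pmf[pmf <= observed * (1 + 1e-12)].sum()))


def _p_values(w: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised minimum-likelihood binomial p-values, grouped by total."""
    w = np.asarray(w, dtype=int)
    total = w + np.asarray(c, dtype=int)
    out = np.empty(w.shape, dtype=float)
    for n in np.unique(total):
        sel = total == n
        if n < 1:
            raise ValueError("total count must be >= 1")
        pmf = binom.pmf(np.arange(n + 1), n, 0.5)
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        sorted_pmf = pmf[order]
        # p(k) = cumulative probability of outcomes with pmf <= pmf[k] (ties included)
        rank = np.searchsorted(sorted_pmf, pmf * (1 + 1e-12), side="right") - 1
        out[sel] = np.minimum(1.0, csum[rank[w[sel]]])
    return out


CLASSES = ("excluded", "noncognate", "cognate", "highly_cognate")


@dataclass
class FractionationResult:
    """Per-site classes and class percentages among tested sites."""

    sites: pd.DataFrame
    offset: int
    alpha: float
    hi: float
    min_total: int
    percentages: dict[str, float] = field(default_factory=dict)

    @property
    def n_tested(self) -> int:
        return int((self.sites["class"] != "excluded").sum())

    def params(self) -> tuple:
        return (self.offset, self.alpha, self.hi, self.min_total)


def fractionate(
    sites: pd.DataFrame,
    alpha: float = 0.05,
    hi: float = 0.95,
    min_total: int = 8,
    offset: int = 3,
) -> FractionationResult:
    """Classify offset-paired sites as cognate or noncognate.

    Sites with fewer than ``min_total`` hits (Watson + Crick) are excluded
    for lack of power.  Among tested sites, p <= alpha marks a noncognate
    (significantly strand-disparate) site, p > alpha a cognate one and
    p > hi a highly cognate subset.  Percentages are over tested sites,
    with cognate and noncognate summing to 100.
    """
    df = sites.copy()
    df["p"] = np.nan
    df["class"] = "excluded"
    tested = df["total"] >= min_total
    if tested.any():
        pvals = _p_values(df.loc[tested, "w"].to_numpy(), df.loc[tested, "c"].to_numpy())
        df.loc[tested, "p"] = pvals
        df.loc[tested, "class"] = np.where(pvals <= alpha, "noncognate", "cognate")
        df.loc[tested & (df["p"] > hi), "class"] = "highly_cognate"
    n_tested = int(tested.sum())
    pct = {}
    if n_tested:
        noncog = int((df["class"] == "noncognate").sum())
        hicog = int((df["class"] == "highly_cognate").sum())
        pct = {
            "noncognate": 100.0 * noncog / n_tested,
            "cognate": 100.0 * (n_tested - noncog) / n_tested,
            "highly_cognate": 100.0 * hicog / n_tested,
        }
    return FractionationResult(
        sites=df, offset=offset, alpha=alpha, hi=hi, min_total=min_total, percentages=pct
    )


def fractionate_map(
    bmap: BreakMap,
    offset: int = 3,
    alpha: float = 0.05,
    hi: float = 0.95,
    min_total: int = 8,
) -> FractionationResult:
    """Convenience: pair a break map at ``offset`` and fractionate."""
    return fractionate(
        pair_offset_sites(bmap, offset), alpha=alpha, hi=hi, min_total=min_total, offset=offset
    )


def shuffle_amplitudes(bmap: BreakMap, seed: int) -> BreakMap:
    """Permute per-position counts among each strand's occupied positions.

    Positions stay fixed; the multiset of counts on each (contig, strand)
    is shuffled uniformly.  This destroys Watson-Crick pairing while
    preserving both marginal amplitude distributions, giving the null
    expectation for cognate fractions under strand independence.
    """
    rng = np.random.default_rng(seed)
    out = bmap.copy()
    for key in sorted(out.counts):
        ctr = out.counts[key]
        positions = sorted(ctr)
        values = np.array([ctr[p] for p in positions])
        rng.shuffle(values)
        for p, v in zip(positions, values):
            ctr[p] = int(v)
    return out


@dataclass
class CognateSimulation:
    """A 100%-cognate resampling of an observed dataset.

    Per site, lambda is the Watson/Crick mean of the observed counts and
    both strands are redrawn independently from Poisson(lambda), so every
    disparity beyond Poisson noise is erased.
    """

    sites: pd.DataFrame  # contig, watson_pos, crick_pos, lam, w, c, total
    seed: int

    @property
    def lam(self) -> np.ndarray:
        return self.sites["lam"].to_numpy()


def simulate_fully_cognate(
    bmap: BreakMap, offset: int = 3, seed: int = 0
) -> CognateSimulation:
    """Resample an observed map as if every site were a pure DSB site."""
    paired = pair_offset_sites(bmap, offset)
    if paired.empty:
        raise ValueError("break map yields no offset sites")
    lam = (paired["w"] + paired["c"]).to_numpy() / 2.0
    rng = np.random.default_rng(seed)
    w = rng.poisson(lam)
    c = rng.poisson(lam)
    df = paired[["contig", "watson_pos", "crick_pos"]].copy()
    df["lam"] = lam
    df["w"] = w
    df["c"] = c
    df["total"] = w + c
    return CognateSimulation(sites=df, seed=seed)


def summarize_fractions(
    observed: FractionationResult,
    simulated: FractionationResult,
    randomized: FractionationResult,
) -> pd.DataFrame:
    """Class percentages of observed, fully-cognate and shuffled datasets.

    All three must have been fractionated with identical parameters.
    """
    results = {
        "observed": observed,
        "simulated_cognate": simulated,
        "randomized": randomized,
    }
    params = {name: r.params() for name, r in results.items()}
    if len(set(params.values())) != 1:
        raise ValueError(f"fractionation parameters differ: {params}")
    rows = []
    for name, r in results.items():
        if not r.percentages:
            raise ValueError(f"{name} dataset has no tested sites")
        rows.append({"dataset": name, "n_tested": r.n_tested, **r.percentages})
    return pd.DataFrame(rows)
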