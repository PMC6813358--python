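"""Recover a planted cleavage-site base preference from weighted composition.

Plants a cytosine at dyad offset -3 (the base 5' of the Watson scissile
phosphate for a 4-nt overhang) with probability 0.8 at 1,000 simulated
sites, then computes the dyad-centred, signal-weighted nucleotide
composition and its log2 deviation from the window average.
"""

from ccseq import (
    make_genome,
    normalize_site_weights,
    plant_preference,
    random_cleavage_model,
    simulate_break_map,
    weighted_composition,
)
from ccseq.cognate import pair_offset_sites
from ccseq.seqbias import _log2_deviation

genome = make_genome(400_000, 0.40, seed=30)
model = random_cleavage_model(
    genome, 1000, overhang=4, min_spacing=200, seed=31,
    planted_preference=("C", -3, 0.8),
)
genome = plant_preference(genome, model, seed=32)
truth = simulate_break_map(model, depth=1.0, seed=33)

sites = pair_offset_sites(truth, offset=3)
sites = sites[sites["total"] > 0]
profile = weighted_composition(normalize_site_weights(sites), genome.contigs, flank=20)
dev = _log2_deviation(profile, pseudo_fraction=1e-3)

print(f"sites used: {profile.n_sites}")
print(f"C fraction at -3: {profile.fractions.loc[-3, 'C']:.3f} "
      f"(genome background ~0.20)")
print(f"argmax of C log2 deviation: position {dev['C'].idxmax()}")
print(f"G fraction at +3: {profile.fractions.loc[3, 'G']:.3f}")
# The planted preference appears as a strong C enrichment at -3 and, by
# the rotational symmetry of double-strand cleavage, a matching G at +3.
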