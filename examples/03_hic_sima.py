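"""Hi-C normalization, TAD calling, and SIMA enhancer-pair enrichment.

Simulates contact matrices with a planted 5x contact boost between
same-class enhancer pairs, ICE-normalizes them, recovers TAD boundaries
from the insulation score, and measures enhancer-enhancer interaction
strength against randomly placed control regions — including the 10-kb
shifted negative control.
"""

import numpy as np

from chromdyn.hic import ice_normalize, insulation_tads, shifted_control, sima
from chromdyn.intervals import ScoredInterval
from chromdyn.simulate import SyntheticConfig, plant_truth, simulate_annotation, simulate_hic

config = SyntheticConfig(
    n_chroms=1, chrom_length=10_000_000, n_tads=20, n_genes=200,
    n_enhancers=300, pair_boost=5.0, seed=3,
)
annotation = simulate_annotation(config)
truth = plant_truth(annotation, config)
raw = simulate_hic(annotation, truth, config)["SS"]["chr1"]

norm = ice_normalize(raw)
boundaries, called_tads = insulation_tads(norm, window_bins=10)
true_bounds = [t.end for t in annotation.tads[:-1]]
recovered = sum(1 for b in true_bounds if min(abs(np.array(boundaries) - b)) <= config.bin_size)
print(f"ICE bias range        : {norm.bias.min():.2f} - {norm.bias.max():.2f}")
print(f"insulation boundaries : {len(boundaries)} called, "
      f"{recovered}/{len(true_bounds)} true boundaries within 1 bin")

diff_tads = [t for t, c in zip(annotation.tads, truth.tad_class) if c != "neutral"]
n_prom = len(annotation.promoters)
dar_enhancers = [
    ScoredInterval(iv, 0.0, cls)
    for iv, cls in zip(annotation.enhancers, truth.element_class[n_prom:])
    if cls != "null"
]
res = sima(diff_tads, dar_enhancers, {"chr1": norm}, n_rand=500, seed=0)
print(f"SIMA domains          : {len(res.strengths)}")
print(f"median strength       : {res.median_strength:.2f} (1 = random expectation)")
print(f"signed-rank p         : {res.signed_rank_p:.2e}")

shifted, dropped = shifted_control(dar_enhancers, diff_tads, offset=10_000)
res_shift = sima(diff_tads, shifted, {"chr1": norm}, n_rand=500, seed=0)
print(f"shifted control       : strength {res_shift.median_strength:.2f} "
      f"({dropped} regions dropped at boundaries)")
# Strength well above 1 at the true enhancer coordinates but near 1 after a
# 10-kb shift shows the enrichment is anchored at the enhancers themselves.
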