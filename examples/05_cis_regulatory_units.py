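"""Cis-regulatory units: does acetylation change track looping change?

Builds promoter-centred cis-regulatory units (CRUs) — a promoter plus its
significant DAR-containing promoter-interacting regions — and tests each
unit's Spearman correlation between per-fragment H3K27ac fold change and
interaction-frequency fold change against a connectivity-scrambling
permutation null. Run twice: with invariant architecture (default) and
with 10% of units rewired so looping tracks acetylation.
"""

import numpy as np

from chromdyn.cru import build_crus, permutation_test, pir_stats
from chromdyn.diffcount import (
    call_differential_genes,
    estimate_dispersion,
    estimate_size_factors,
    merge_windows_to_dars,
    test_regions,
)
from chromdyn.simulate import SyntheticConfig, simulate_all
from chromdyn.summaries import cru_significance_summary


def analyse(rewired_fraction, seed):
    data = simulate_all(SyntheticConfig(rewired_fraction=rewired_fraction, seed=seed))
    ann, chip = data["annotation"], data["chip"]
    sf = estimate_size_factors(chip)
    dars = merge_windows_to_dars(test_regions(chip, sf, estimate_dispersion(chip, sf)))
    genes = call_differential_genes(data["rna"])
    diff_names = {ann.genes[i].name for i in range(len(ann.genes)) if genes[i].direction != "none"}
    interactions = [r for r in data["pchic"] if r.gene in diff_names]
    stats = pir_stats(data["pchic"])
    crus = build_crus(interactions, dars, chip, sf, min_fragments=5)
    crus, significant = permutation_test(crus, n_perm=10_000, fdr=0.05, seed=seed)
    return data["truth"], stats, crus, significant


truth, stats, crus, significant = analyse(rewired_fraction=0.0, seed=5)
s = cru_significance_summary(len(significant), len(crus))
print(f"[invariant architecture] median PIRs per promoter: {stats['median_pirs']:.0f}")
print(f"[invariant architecture] CRUs tested {s['n_tested']}, "
      f"significant {s['n_significant']} ({s['significant_pct']:.1f}%)")

truth, stats, crus, significant = analyse(rewired_fraction=0.10, seed=5)
s = cru_significance_summary(len(significant), len(crus))
n_planted = sum(c.gene in truth.rewired_genes for c in significant)
print(f"[rewired 10%]            CRUs tested {s['n_tested']}, "
      f"significant {s['n_significant']} ({s['significant_pct']:.1f}%), "
      f"{n_planted} of them planted")
# With shared contact intensity between conditions almost no unit shows a
# significant acetylation-looping correlation; planting coupled units makes
# the detected set concentrate on exactly those promoters.
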