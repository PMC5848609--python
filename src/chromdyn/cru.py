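"""Promoter-centric cis-regulatory units (CRUs).

A CRU is a promoter together with all its significant promoter-interacting
regions (PIRs) that contain a differentially acetylated region (DAR). For
each member fragment we carry two log2 fold changes — H3K27ac and
interaction frequency — and ask, per CRU, whether acetylation dynamics
track looping dynamics (Spearman correlation against a
connectivity-scrambling permutation null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, overlap_pairs

__all__ = [
    "CisRegulatoryUnit",
    "pir_stats",
    "fragment_acetylation_lfc",
    "build_crus",
    "cru_correlation",
    "permutation_test",
]

LFC_PSEUDOCOUNT = 0.5


@dataclass
class CisRegulatoryUnit:
    gene: str
    bait: GenomicInterval
    member_fragments: list           # GenomicInterval per member
    acetyl_lfc: np.ndarray           # H3K27ac log2 FC (TPO/SS) per member
    interaction_lfc: np.ndarray      # contact-frequency log2 FC per member
    spearman_r: float = float("nan")
    pvalue: float = float("nan")
    qvalue: float = float("nan")

    @property
    def n_members(self) -> int:
        return len(self.member_fragments)


def pir_stats(interactions, diff_genes=None, min_score: float = 5.0) -> dict:
    """Per-promoter PIR counts and bait-to-PIR distance distributions.

    A PIR is a distinct other-end fragment with score >= ``min_score`` in
    either condition. ``diff_genes`` optionally maps gene name ->
    direction ("gain"/"loss"/"none") to stratify by gene class.
    """
    per_gene: dict[str, dict] = {}
    for rec in interactions:
        if max(rec.score_ss, rec.score_tpo) < min_score:
            continue
        entry = per_gene.setdefault(rec.gene, {"fragments": {}, "bait": rec.bait})
        key = (rec.other_end.chrom, rec.other_end.start, rec.other_end.end)
        entry["fragments"].setdefault(key, rec)
    counts, distances, gene_names = [], [], []
    for gene, entry in per_gene.items():
        frs = entry["fragments"].values()
        counts.append(len(frs))
        gene_names.append(gene)
        distances.append([r.distance for r in frs if r.distance is not None])
    result = {
        "genes": gene_names,
        "pir_counts": np.array(counts),
        "distances": distances,
        "median_pirs": float(np.median(counts)) if counts else float("nan"),
    }
    if diff_genes is not None:
        by_class: dict[str, list[int]] = {}
        for g, c in zip(gene_names, counts):
            by_class.setdefault(diff_genes.get(g, "none"), []).append(c)
        result["pir_counts_by_class"] = {k: np.array(v) for k, v in by_class.items()}
    return result


def fragment_acetylation_lfc(
    fragments, window_counts, size_factors, restrict_to=None
) -> np.ndarray:
    """Per-fragment H3K27ac log2 fold change (TPO/SS).

    Normalized window counts are summed over windows overlapping each
    fragment, averaged within condition, and compared with a pseudocount.
    With ``restrict_to`` (e.g. the DAR set), only windows also overlapping
    one of those intervals contribute — the fold change at the target
    DARs, undiluted by unrelated signal elsewhere in the fragment.
    """
    y = window_counts.counts / np.asarray(size_factors)
    cols_ss = window_counts.condition_columns("SS")
    cols_tpo = window_counts.condition_columns("TPO")
    use_window = np.ones(len(window_counts.regions), dtype=bool)
    if restrict_to is not None:
        use_window[:] = False
        for wi, _ in overlap_pairs(window_counts.regions, restrict_to):
            use_window[wi] = True
    sums = np.zeros((len(fragments), y.shape[1]))
    for fi, wi in overlap_pairs(fragments, window_counts.regions):
        if use_window[wi]:
            sums[fi] += y[wi]
    ss = sums[:, cols_ss].mean(axis=1)
    tpo = sums[:, cols_tpo].mean(axis=1)
    return np.log2(tpo + LFC_PSEUDOCOUNT) - np.log2(ss + LFC_PSEUDOCOUNT)


def build_crus(
    interactions,
    dars,
    window_counts,
    size_factors,
    min_fragments: int = 5,
    min_score: float = 5.0,
) -> list[CisRegulatoryUnit]:
    """Assemble CRUs: promoters with >= ``min_fragments`` DAR-containing PIRs.

    Member fragments are the distinct significant PIRs (score >=
    ``min_score`` in either condition) overlapping at least one DAR. The
    per-member acetylation LFC comes from normalized fragment-summed
    H3K27ac windows, the interaction LFC from the record's per-condition
    normalized frequencies.
    """
    per_gene: dict[str, dict] = {}
    for rec in interactions:
        if max(rec.score_ss, rec.score_tpo) < min_score:
            continue
        entry = per_gene.setdefault(rec.gene, {"bait": rec.bait, "frags": {}})
        key = (rec.other_end.chrom, rec.other_end.start, rec.other_end.end)
        entry["frags"].setdefault(key, rec)

    all_frags: list[GenomicInterval] = []
    frag_owner: list[tuple[str, tuple]] = []
    for gene, entry in per_gene.items():
        for key, rec in entry["frags"].items():
            all_frags.append(rec.other_end)
            frag_owner.append((gene, key))
    dar_regions = [d.region for d in dars]
    has_dar = np.zeros(len(all_frags), dtype=bool)
    for fi, _ in overlap_pairs(all_frags, dar_regions):
        has_dar[fi] = True
    acetyl = fragment_acetylation_lfc(
        all_frags, window_counts, size_factors, restrict_to=dar_regions
    )

    members: dict[str, list[int]] = {}
    for i, ((gene, _), ok) in enumerate(zip(frag_owner, has_dar)):
        if ok:
            members.setdefault(gene, []).append(i)
    crus = []
    for gene, idx in members.items():
        if len(idx) < min_fragments:
            continue
        recs = [per_gene[gene]["frags"][frag_owner[i][1]] for i in idx]
        ilfc = np.array([
            np.log2(r.freq_tpo + LFC_PSEUDOCOUNT) - np.log2(r.freq_ss + LFC_PSEUDOCOUNT)
            for r in recs
        ])
        crus.append(
            CisRegulatoryUnit(
                gene=gene,
                bait=per_gene[gene]["bait"],
                member_fragments=[all_frags[i] for i in idx],
                acetyl_lfc=acetyl[idx],
                interaction_lfc=ilfc,
            )
        )
    return crus


def cru_correlation(cru: CisRegulatoryUnit) -> float:
    """Spearman r between member acetylation and interaction fold changes.

    NaN (excluded from testing) when either vector has zero variance.
    """
    if np.ptp(cru.acetyl_lfc) == 0 or np.ptp(cru.interaction_lfc) == 0:
        return float("nan")
    return float(stats.spearmanr(cru.acetyl_lfc, cru.interaction_lfc).statistic)


def permutation_test(
    crus,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
    within_chromosome: bool = False,
):
    """Connectivity-scrambling permutation test of CRU correlations.

    Each round permutes the interaction-LFC values across all members
    genome-wide (or within chromosome), keeping every CRU's acetylation
    vector and size fixed, and recomputes each CRU's Spearman r on its own
    members. ``p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm)``; BH at
    ``fdr``. Fills r/p/q on the CRUs and returns ``(crus, significant)``.
    """
    if len(crus) < 2:
        raise ValueError("need >= 2 CRUs")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    for cru in crus:
        cru.spearman_r = cru_correlation(cru)
    testable = [c for c in crus if np.isfinite(c.spearman_r)]
    pool = np.concatenate([c.interaction_lfc for c in testable])
    sizes = [c.n_members for c in testable]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    n_pool = len(pool)
    obs = np.array([abs(c.spearman_r) for c in testable])
    if within_chromosome:
        chroms = np.concatenate([
            np.array([f.chrom for f in c.member_fragments]) for c in testable
        ])
    centered_a = [
        (lambda ra: ra - ra.mean())(stats.rankdata(c.acetyl_lfc) - 1.0)
        for c in testable
    ]
    exceed = np.zeros(len(testable))
    batch = 2000
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        # global scrambles: each row permutes the member pool
        if within_chromosome:
            perms = np.tile(np.arange(n_pool), (nb, 1))
            for ch in np.unique(chroms):
                sel = np.flatnonzero(chroms == ch)
                sub = np.argsort(rng.random((nb, len(sel))), axis=1)
                perms[:, sel] = sel[sub]
        else:
            perms = np.argsort(rng.random((nb, n_pool)), axis=1)
        scrambled = pool[perms]
        for k, c in enumerate(testable):
            chunk = scrambled[:, bounds[k] : bounds[k + 1]]
            m = chunk.shape[1]
            ca = centered_a[k]
            # Spearman = Pearson on ranks; scrambled values are distinct, so
            # their ranks are a permutation of 0..m-1 with closed-form moments
            denom = m * (m * m - 1) / 12.0
            if denom == 0 or np.ptp(ca) == 0:
                continue
            rb = np.argsort(np.argsort(chunk, axis=1), axis=1).astype(float)
            r_null = (rb - (m - 1) / 2.0) @ ca / denom
            exceed[k] += np.count_nonzero(np.abs(r_null) >= obs[k] - 1e-12)
        done += nb
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    significant = []
    for c, p, q in zip(testable, pvals, qvals):
        c.pvalue, c.qvalue = float(p), float(q)
        if q <= fdr:
            significant.append(c)
    return crus, significant
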