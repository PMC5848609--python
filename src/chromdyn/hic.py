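"""Contact-matrix normalization, domain structure, and SIMA.

The structured interaction matrix analysis (SIMA) measures whether a set
of regions (here: differentially acetylated enhancers) interact more
strongly with each other than length-matched regions sampled at random
from the same chromatin domains. The per-domain interaction strength is
observed pooled contact divided by the null mean; strengths are tested
against 1 with a Wilcoxon signed-rank test and compared between
conditions with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as scipy_signal
from scipy import stats

from .intervals import GenomicInterval, ScoredInterval
from .io import ContactMatrix

__all__ = [
    "ice_normalize",
    "expected_by_distance",
    "observed_over_expected",
    "insulation_score",
    "insulation_tads",
    "compartment_eigenvector",
    "SimaResult",
    "sima",
    "sima_compare_conditions",
    "shifted_control",
    "contact_concordance",
]


# ---------------------------------------------------------------------------
# normalization

def ice_normalize(matrix: ContactMatrix, tol: float = 1e-4, max_iter: int = 200) -> ContactMatrix:
    """Iterative correction (matrix balancing) of a raw contact matrix.

    Bins with zero marginal are masked and stay zero; iteration stops when
    the coefficient of variation of unmasked row sums drops below ``tol``.
    The result is scaled so the mean unmasked row sum equals the input's,
    preserving total mass up to that global scalar. The recovered
    multiplicative per-bin bias is stored on the result.
    """
    W = matrix.counts.copy().astype(float)
    marginal = W.sum(axis=1)
    mask = marginal > 0
    if not mask.any():
        raise ValueError("no bins with nonzero marginal")
    target = marginal[mask].mean()
    bias = np.ones(W.shape[0])
    for _ in range(max_iter):
        s = W.sum(axis=1)
        cv = s[mask].std() / s[mask].mean()
        if cv < tol:
            break
        b = np.ones(W.shape[0])
        b[mask] = s[mask] / s[mask].mean()
        W = W / np.outer(b, b)
        bias *= b
    # rescale so unmasked row sums match the input mean marginal
    s = W.sum(axis=1)
    scale = s[mask].mean() / target
    W = W / scale
    return ContactMatrix(matrix.chrom, matrix.bin_size, W, normalized=True, bias=bias)


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean count per |i - j| over unmasked bin pairs."""
    W = matrix.counts
    n = W.shape[0]
    mask = W.sum(axis=1) > 0
    exp = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(W, d)
        pair_ok = mask[: n - d] & mask[d:]
        exp[d] = diag[pair_ok].mean() if pair_ok.any() else 0.0
    return exp


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    """O/E matrix; cells with zero expected value map to 0."""
    W = matrix.counts
    n = W.shape[0]
    exp = expected_by_distance(matrix)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    E = exp[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(E > 0, W / E, 0.0)
    return oe


# ---------------------------------------------------------------------------
# domains & compartments

def insulation_score(matrix: ContactMatrix, window_bins: int = 10) -> np.ndarray:
    """Mean contact of the ``window_bins`` square crossing each bin (log2,
    relative to the chromosome mean; NaN where undefined)."""
    n = matrix.n_bins
    if n <= 2 * window_bins:
        raise ValueError("matrix smaller than insulation window")
    W = matrix.counts
    raw = np.full(n, np.nan)
    for i in range(window_bins, n - window_bins):
        block = W[i - window_bins : i, i + 1 : i + 1 + window_bins]
        raw[i] = block.mean()
    ok = np.isfinite(raw) & (raw > 0)
    if not ok.any():
        return raw
    score = np.full(n, np.nan)
    score[ok] = np.log2(raw[ok] / np.exp(np.mean(np.log(raw[ok]))))
    return score


def insulation_tads(
    matrix: ContactMatrix, window_bins: int = 10, prominence: float = 0.1
):
    """TAD boundaries at prominent local minima of the insulation score.

    Returns ``(boundaries_bp, tads)`` where TADs are the inter-boundary
    intervals covering the chromosome.
    """
    score = insulation_score(matrix, window_bins)
    filled = np.where(np.isfinite(score), score, np.nanmax(score) if np.isfinite(score).any() else 0.0)
    minima, _ = scipy_signal.find_peaks(-filled, prominence=prominence)
    boundaries = [int(b * matrix.bin_size) for b in minima]
    edges = [0] + boundaries + [matrix.n_bins * matrix.bin_size]
    tads = [
        GenomicInterval(matrix.chrom, a, b)
        for a, b in zip(edges[:-1], edges[1:])
        if b > a
    ]
    return boundaries, tads


def compartment_eigenvector(matrix: ContactMatrix, orientation_covariate=None) -> np.ndarray:
    """A/B compartment signal: leading eigenvector of the O/E correlation.

    Masked bins get 0. If an ``orientation_covariate`` (per-bin, e.g.
    enhancer density) is given, the vector is flipped so that positive
    entries (A) have the higher mean covariate.
    """
    oe = observed_over_expected(matrix)
    mask = matrix.counts.sum(axis=1) > 0
    sub = oe[np.ix_(mask, mask)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if not np.isfinite(corr).all():
        raise ValueError("degenerate correlation matrix (constant O/E rows)")
    vals, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1]
    ev = np.zeros(matrix.n_bins)
    ev[mask] = lead / np.linalg.norm(lead)
    if orientation_covariate is not None:
        cov = np.asarray(orientation_covariate, dtype=float)
        pos, neg = ev > 0, ev < 0
        if pos.any() and neg.any() and cov[pos].mean() < cov[neg].mean():
            ev = -ev
    return ev


# ---------------------------------------------------------------------------
# SIMA

@dataclass
class SimaResult:
    """Per-domain interaction strengths and tests for one region set."""

    domain_ids: list
    strengths: np.ndarray          # observed / null-mean, one per domain
    observed: np.ndarray
    null_means: np.ndarray
    null_strengths: list           # per-domain arrays of null/null-mean draws
    signed_rank_p: float           # strengths vs 1
    n_skipped: int = 0

    @property
    def median_strength(self) -> float:
        return float(np.median(self.strengths)) if len(self.strengths) else float("nan")


def _pooled_pair_contact(matrix: ContactMatrix, bins_a, bins_b=None) -> float:
    """Mean normalized contact over unordered bin pairs (distinct bins)."""
    vals = []
    if bins_b is None:
        bins = list(bins_a)
        for x in range(len(bins)):
            for y in range(x + 1, len(bins)):
                vals.append(matrix.counts[bins[x], bins[y]])
    else:
        for i in bins_a:
            for j in bins_b:
                if i != j:
                    vals.append(matrix.counts[i, j])
    return float(np.mean(vals)) if vals else float("nan")


def _sample_bins(rng, domain: GenomicInterval, lengths, bin_size: int) -> list[int]:
    out = []
    for L in lengths:
        span = len(domain) - L
        if span <= 0:
            start = domain.start
        else:
            start = domain.start + int(rng.integers(0, span))
        out.append((start + L // 2) // bin_size)
    return out


def sima(
    domains,
    regions,
    matrices: dict,
    mode: str = "intra",
    block_span: int = 20_000_000,
    n_rand: int = 1000,
    seed: int = 0,
    domain_labels=None,
) -> SimaResult:
    """Structured interaction matrix analysis of a region set.

    intra mode: per domain, pooled mean normalized contact over all
    unordered pairs of regions inside it, against ``n_rand`` draws of
    equally many length-matched intervals placed uniformly within the
    same domain. inter mode: region pairs spanning two same-class domains
    within ``block_span`` (class from ``domain_labels``), with nulls
    sampled within each member domain.

    ``matrices`` maps chromosome to a normalized ContactMatrix; regions
    and domains are GenomicIntervals (regions may be ScoredIntervals).
    """
    rng = np.random.default_rng(seed)
    regs = [r.interval if isinstance(r, ScoredInterval) else r for r in regions]
    units = []  # (domain_id, [(domain, region_indices)])
    if mode == "intra":
        for di, dom in enumerate(domains):
            members = [
                i for i, r in enumerate(regs)
                if r.chrom == dom.chrom and dom.start <= r.midpoint < dom.end
            ]
            if len(members) >= 2:
                units.append((di, [(dom, members)]))
    elif mode == "inter":
        labels = domain_labels if domain_labels is not None else [""] * len(domains)
        members_of = [
            [i for i, r in enumerate(regs)
             if r.chrom == d.chrom and d.start <= r.midpoint < d.end]
            for d in domains
        ]
        for a in range(len(domains)):
            for b in range(a + 1, len(domains)):
                da, db = domains[a], domains[b]
                if da.chrom != db.chrom or labels[a] != labels[b]:
                    continue
                if abs(da.midpoint - db.midpoint) > block_span:
                    continue
                if members_of[a] and members_of[b]:
                    units.append(((a, b), [(da, members_of[a]), (db, members_of[b])]))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    domain_ids, strengths, observed_list, null_mean_list, null_strength_list = [], [], [], [], []
    n_skipped = 0
    for uid, parts in units:
        chrom = parts[0][0].chrom
        if chrom not in matrices:
            n_skipped += 1
            continue
        mat = matrices[chrom]
        bs = mat.bin_size
        part_lengths = [[len(regs[i]) for i in members] for _, members in parts]
        skip = False
        for (dom, _), lens in zip(parts, part_lengths):
            if len(dom) < sum(lens):
                warnings.warn(f"domain {dom.chrom}:{dom.start}-{dom.end} shorter than region total; skipped")
                skip = True
        if skip:
            n_skipped += 1
            continue
        part_bins = [
            [regs[i].midpoint // bs for i in members] for _, members in parts
        ]
        if len(parts) == 1:
            obs = _pooled_pair_contact(mat, part_bins[0])
        else:
            obs = _pooled_pair_contact(mat, part_bins[0], part_bins[1])
        if not np.isfinite(obs):
            n_skipped += 1
            continue
        nulls = np.empty(n_rand)
        for r in range(n_rand):
            sampled = [
                _sample_bins(rng, dom, lens, bs)
                for (dom, _), lens in zip(parts, part_lengths)
            ]
            if len(parts) == 1:
                nulls[r] = _pooled_pair_contact(mat, sampled[0])
            else:
                nulls[r] = _pooled_pair_contact(mat, sampled[0], sampled[1])
        null_mean = float(np.nanmean(nulls))
        if not np.isfinite(null_mean) or null_mean <= 0:
            n_skipped += 1
            continue
        domain_ids.append(uid)
        observed_list.append(obs)
        null_mean_list.append(null_mean)
        strengths.append(obs / null_mean)
        null_strength_list.append(nulls / null_mean)

    strengths_arr = np.array(strengths)
    if len(strengths_arr) >= 2 and np.any(strengths_arr != 1):
        # one-sided: enrichment over the resampling null
        p = float(stats.wilcoxon(strengths_arr - 1.0, zero_method="wilcox",
                                 alternative="greater").pvalue)
    else:
        p = 1.0
    return SimaResult(
        domain_ids, strengths_arr, np.array(observed_list), np.array(null_mean_list),
        null_strength_list, p, n_skipped,
    )


def sima_compare_conditions(result_a: SimaResult, result_b: SimaResult) -> float:
    """Between-condition Wilcoxon rank-sum p on per-domain strengths."""
    if len(result_a.strengths) == 0 or len(result_b.strengths) == 0:
        return 1.0
    return float(stats.ranksums(result_a.strengths, result_b.strengths).pvalue)


def shifted_control(regions, domains, offset: int = 10_000):
    """Shift every region by ``+offset``; drop regions that leave their domain.

    Returns ``(shifted_regions, n_dropped)``. Regions not inside any
    domain are shifted unconditionally.
    """
    def domain_of(iv: GenomicInterval):
        for di, d in enumerate(domains):
            if d.chrom == iv.chrom and d.start <= iv.midpoint < d.end:
                return di
        return None

    out = []
    dropped = 0
    for r in regions:
        iv = r.interval if isinstance(r, ScoredInterval) else r
        before = domain_of(iv)
        shifted = iv.shift(offset)
        if before is not None and domain_of(shifted) != before:
            dropped += 1
            continue
        out.append(shifted)
    return out, dropped


# ---------------------------------------------------------------------------
# contact concordance between conditions

def contact_concordance(
    elements,
    matrices_ss: dict,
    matrices_tpo: dict,
    anchored_min_length: int = 20_000,
    anchored: bool | None = None,
):
    """Per-element normalized contact per kb in each condition.

    For each element: the pooled mean contact among its covered bins per
    kb of element, or — when ``anchored`` (default: elements longer than
    ``anchored_min_length`` analysed as anchors) — the row-sum of its bins.
    Returns a dict with per-element values, Spearman r between conditions
    and the per-element log2 fold-change distribution.
    """
    vals_ss, vals_tpo, kept = [], [], []
    for ei, el in enumerate(elements):
        iv = el.interval if isinstance(el, ScoredInterval) else el
        if iv.chrom not in matrices_ss:
            continue
        m_ss, m_tpo = matrices_ss[iv.chrom], matrices_tpo[iv.chrom]
        bs = m_ss.bin_size
        b0, b1 = iv.start // bs, (iv.end - 1) // bs + 1
        if b1 - b0 < 1 or len(iv) < bs:
            continue  # element smaller than one bin
        bins = list(range(b0, min(b1, m_ss.n_bins)))
        use_anchor = anchored if anchored is not None else len(iv) > anchored_min_length
        kb = len(iv) / 1000.0

        def value(m):
            if use_anchor:
                return float(m.counts[bins, :].sum()) / kb
            if len(bins) == 1:
                return float(m.counts[bins[0], bins[0]]) / kb
            sub = m.counts[np.ix_(bins, bins)]
            return float(np.triu(sub).sum()) / kb

        vals_ss.append(value(m_ss))
        vals_tpo.append(value(m_tpo))
        kept.append(ei)
    vals_ss, vals_tpo = np.array(vals_ss), np.array(vals_tpo)
    if len(kept) >= 3:
        r = float(stats.spearmanr(vals_ss, vals_tpo).statistic)
    else:
        r = float("nan")
    lfc = np.log2(vals_tpo + 0.5) - np.log2(vals_ss + 0.5)
    return {
        "element_indices": kept,
        "ss": vals_ss,
        "tpo": vals_tpo,
        "spearman_r": r,
        "log2_fold_change": lfc,
    }
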