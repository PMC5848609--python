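"""Feature extraction and statistical learning for cis-regulatory response.

Classifies activated vs repressed cis-regulatory elements (DHS summits
+/- flank within DARs) from sequence and chromatin features: DNA k-mers
(2 <= k <= 4, reverse-complement collapsed), DNA shape summaries, PWM
motif hits, binary TF ChIP peak overlap, and normalized Hi-C anchored
contact strength. Learning uses L1-penalized (lasso) logistic regression
with cross-validated penalty (1-SE rule), bootstrap stability selection,
and a random-forest cross-check; performance is always reported on
held-out test elements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PWM",
    "FeatureMatrix",
    "kmer_features",
    "shape_features",
    "scan_pwms",
    "motif_density_profile",
    "tf_and_hic_features",
    "train_eval_lasso",
    "bootstrap_stability",
    "train_eval_forest",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class PWM:
    """Position probability matrix with background frequencies."""

    name: str
    matrix: np.ndarray                      # (width, 4) probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")

    @classmethod
    def from_counts(cls, name, counts, background=None, pseudocount: float = 0.5):
        counts = np.asarray(counts, dtype=float) + pseudocount
        mat = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(name, mat, bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, self.pseudocount)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def null_score_quantile(self, q: float, grid: float = 0.05) -> float:
        """Quantile of the per-window score under the i.i.d. background,
        by dynamic programming over discretised position distributions."""
        lo = self.log_odds
        dist = {0.0: 1.0}
        for pos in range(self.width):
            new: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = round((s + lo[pos, b]) / grid) * grid
                    new[key] = new.get(key, 0.0) + p * self.background[b]
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        cdf = np.cumsum(probs)
        idx = np.searchsorted(cdf, q, side="left")
        # discretisation can shift mass by up to grid/2 per position; back
        # the threshold off by that bound so true top scores are never lost
        return float(scores[min(idx, len(scores) - 1)]) - grid * self.width / 2


@dataclass
class FeatureMatrix:
    """Standardised feature matrix with labels and per-family grouping."""

    values: np.ndarray
    feature_names: list
    families: list             # family per feature (kmer/shape/motif/tf_chip/hic)
    labels: np.ndarray         # 1 = activated (gain), 0 = repressed (loss)
    region_names: list

    def family_columns(self, family: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.families) == family)


# ---------------------------------------------------------------------------
# sequence features

def _canonical_kmers(k: int) -> list[str]:
    seen = set()
    out = []
    for tup in itertools.product(_BASES, repeat=k):
        kmer = "".join(tup)
        canon = min(kmer, revcomp(kmer))
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


def kmer_features(sequences, k_min: int = 2, k_max: int = 4):
    """Reverse-complement-collapsed k-mer frequencies, length-normalized.

    Each feature is occurrences of the collapsed k-mer divided by
    ``L - k + 1``; windows containing N are skipped. Returns
    ``(matrix, feature_names)``.
    """
    names = []
    for k in range(k_min, k_max + 1):
        names += [f"kmer_{km}" for km in _canonical_kmers(k)]
    index = {n[5:]: i for i, n in enumerate(names)}
    mat = np.zeros((len(sequences), len(names)))
    for si, seq in enumerate(sequences):
        seq = seq.upper()
        for k in range(k_min, k_max + 1):
            n_windows = len(seq) - k + 1
            if n_windows <= 0:
                continue
            counts: dict[str, int] = {}
            for i in range(n_windows):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                canon = min(kmer, revcomp(kmer))
                counts[canon] = counts.get(canon, 0) + 1
            for km, c in counts.items():
                mat[si, index[km]] = c / n_windows
    return mat, names


def shape_features(sequences, pentamer_table: dict):
    """Mean/min/max of each DNA shape parameter from a pentamer lookup.

    ``pentamer_table`` maps parameter name -> {pentamer: value}. A 5-mer
    absent from the table raises, naming it. Returns ``(matrix, names)``.
    """
    params = list(pentamer_table)
    names = [f"shape_{p}_{s}" for p in params for s in ("mean", "min", "max")]
    mat = np.zeros((len(sequences), len(names)))
    for si, seq in enumerate(sequences):
        seq = seq.upper()
        for pi, param in enumerate(params):
            table = pentamer_table[param]
            vals = []
            for i in range(len(seq) - 4):
                pent = seq[i : i + 5]
                if "N" in pent:
                    continue
                if pent not in table:
                    raise KeyError(f"pentamer {pent} missing from shape table {param!r}")
                vals.append(table[pent])
            if vals:
                v = np.array(vals)
                mat[si, 3 * pi : 3 * pi + 3] = [v.mean(), v.min(), v.max()]
    return mat, names


def _scan_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Per-offset log-odds scores on the forward strand (NaN at Ns)."""
    lo = pwm.log_odds
    w = pwm.width
    L = len(seq)
    if L < w:
        return np.empty(0)
    idx = np.array([_BASE_IDX.get(b, -1) for b in seq])
    scores = np.zeros(L - w + 1)
    valid = np.ones(L - w + 1, dtype=bool)
    for p in range(w):
        sub = idx[p : p + L - w + 1]
        ok = sub >= 0
        valid &= ok
        scores += np.where(ok, lo[p, np.clip(sub, 0, 3)], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_pwms(sequences, pwms, score_threshold_quantile: float = 0.999):
    """Log-odds motif scan on both strands with analytic null thresholds.

    A hit is an (offset, strand) whose score reaches the
    ``score_threshold_quantile`` quantile of the PWM's null score
    distribution under the background model. Returns ``(hit_counts,
    names, hit_positions)`` where ``hit_positions[pwm][seq]`` lists motif
    start offsets (forward-strand coordinates).
    """
    names = [f"motif_{p.name}" for p in pwms]
    counts = np.zeros((len(sequences), len(pwms)))
    positions: dict[str, list] = {p.name: [[] for _ in sequences] for p in pwms}
    thresholds = [p.null_score_quantile(score_threshold_quantile) for p in pwms]
    for si, seq in enumerate(sequences):
        seq = seq.upper()
        rc = revcomp(seq)
        L = len(seq)
        for pi, pwm in enumerate(pwms):
            thr = thresholds[pi]
            fwd = _scan_scores(seq, pwm)
            rev = _scan_scores(rc, pwm)
            hits_f = np.flatnonzero(fwd >= thr)
            hits_r = np.flatnonzero(rev >= thr)
            counts[si, pi] = len(hits_f) + len(hits_r)
            pos = list(hits_f) + [L - pwm.width - h for h in hits_r]
            positions[pwm.name][si] = sorted(int(x) for x in pos)
    return counts, names, positions


def motif_density_profile(hit_positions, seq_length: int, n_bins: int = 20) -> np.ndarray:
    """Binned density of motif hits around the summit (sequence centre)."""
    centre = seq_length // 2
    edges = np.linspace(-centre, centre, n_bins + 1)
    acc = np.zeros(n_bins)
    n_seq = 0
    for per_seq in hit_positions:
        n_seq += 1
        for p in per_seq:
            rel = p - centre
            b = np.searchsorted(edges, rel, side="right") - 1
            if 0 <= b < n_bins:
                acc[b] += 1
    return acc / max(n_seq, 1)


# ---------------------------------------------------------------------------
# chromatin features

def tf_and_hic_features(regions, peak_sets: dict, matrices_by_condition: dict | None = None):
    """Binary TF peak overlap and anchored Hi-C contact per region.

    ``peak_sets`` maps TF name -> interval list (1 iff >= 1 bp overlap);
    ``matrices_by_condition`` maps condition -> {chrom: normalized
    ContactMatrix}, contributing each region's bin row-sum per condition.
    Returns ``(matrix, names, families)``.
    """
    from .intervals import overlap_pairs

    ivs = [getattr(r, "interval", r) for r in regions]
    cols, names, families = [], [], []
    for tf, peaks in peak_sets.items():
        pk = [getattr(p, "interval", p) for p in peaks]
        col = np.zeros(len(ivs))
        for i, _ in overlap_pairs(ivs, pk):
            col[i] = 1.0
        cols.append(col)
        names.append(f"tf_{tf}")
        families.append("tf_chip")
    for cond, mats in (matrices_by_condition or {}).items():
        col = np.zeros(len(ivs))
        for i, iv in enumerate(ivs):
            m = mats.get(iv.chrom)
            if m is None:
                continue
            b = min(iv.midpoint // m.bin_size, m.n_bins - 1)
            col[i] = m.counts[b, :].sum()
        cols.append(col)
        names.append(f"hic_{cond}")
        families.append("hic")
    return np.column_stack(cols) if cols else np.empty((len(ivs), 0)), names, families


# ---------------------------------------------------------------------------
# learning

def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _cv_choose_c(X, y, c_grid, n_folds: int, rng) -> float:
    """Pick the strongest penalty within 1 SE of the best CV log-loss."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    losses = np.zeros((len(c_grid), n_folds))
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, Xva = _standardize(X[tr], X[va])
        for ci, C in enumerate(c_grid):
            model = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", class_weight="balanced", max_iter=2000, random_state=0
            )
            model.fit(Xtr, y[tr])
            p = np.clip(model.predict_proba(Xva)[:, 1], 1e-12, 1 - 1e-12)
            losses[ci, fold] = -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
    mean = losses.mean(axis=1)
    se = losses.std(axis=1) / np.sqrt(n_folds)
    best = np.argmin(mean)
    limit = mean[best] + se[best]
    # strongest penalty (smallest C) whose mean loss is within 1 SE
    for ci in range(len(c_grid)):
        if mean[ci] <= limit:
            return float(c_grid[ci])
    return float(c_grid[best])


_C_GRID = np.logspace(-2.5, 1.5, 9)


def train_eval_lasso(
    features: np.ndarray,
    labels: np.ndarray,
    test_frac: float = 0.2,
    n_folds: int = 10,
    n_models: int = 10,
    seed: int = 0,
):
    """Lasso logistic classification with held-out evaluation.

    ``n_models`` repetitions of: stratified train/test split, penalty by
    stratified ``n_folds``-fold CV with the 1-SE rule, ROC/AUC on the
    held-out split only. Returns a dict with per-model AUCs, mean/min/max,
    ROC curves, and the penalty chosen in the first repetition (reused by
    bootstrap stability selection).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score, roc_curve
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    rng = np.random.default_rng(seed)
    aucs, rocs, chosen_c = [], [], None
    for m in range(n_models):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_frac, stratify=y,
            random_state=int(rng.integers(2**31)),
        )
        if min(np.bincount(ytr)) < 20:
            raise ValueError("need >= 20 training elements per class")
        C = _cv_choose_c(Xtr, ytr, _C_GRID, n_folds, rng)
        if chosen_c is None:
            chosen_c = C
        Xtr_s, Xte_s = _standardize(Xtr, Xte)
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", class_weight="balanced", max_iter=2000, random_state=0
        )
        model.fit(Xtr_s, ytr)
        p = model.predict_proba(Xte_s)[:, 1]
        aucs.append(roc_auc_score(yte, p))
        fpr, tpr, _ = roc_curve(yte, p)
        rocs.append(np.column_stack([fpr, tpr]))
    aucs = np.array(aucs)
    return {
        "aucs": aucs,
        "auc_mean": float(aucs.mean()),
        "auc_min": float(aucs.min()),
        "auc_max": float(aucs.max()),
        "rocs": rocs,
        "C": chosen_c,
    }


def bootstrap_stability(
    features: np.ndarray,
    labels: np.ndarray,
    C: float,
    n_boot: int = 100,
    seed: int = 0,
):
    """Bootstrap-lasso stability selection at a fixed penalty.

    Stability of a feature = fraction of bootstrap resamples in which its
    lasso coefficient is nonzero; sign = majority sign among those fits.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    n = len(y)
    nonzero = np.zeros(X.shape[1])
    sign_sum = np.zeros(X.shape[1])
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        Xb, _ = _standardize(X[idx], X[idx])
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", class_weight="balanced", max_iter=2000, random_state=0
        )
        model.fit(Xb, y[idx])
        coef = model.coef_.ravel()
        nonzero += coef != 0
        sign_sum += np.sign(coef)
        done += 1
    stability = nonzero / n_boot
    sign = np.sign(sign_sum)
    return {"stability": stability, "sign": sign}


def train_eval_forest(
    features: np.ndarray,
    labels: np.ndarray,
    test_frac: float = 0.2,
    n_models: int = 10,
    seed: int = 0,
):
    """Random-forest cross-check under the same split protocol."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    rng = np.random.default_rng(seed)
    aucs = []
    for m in range(n_models):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_frac, stratify=y,
            random_state=int(rng.integers(2**31)),
        )
        model = RandomForestClassifier(
            class_weight="balanced", random_state=int(rng.integers(2**31))
        )
        model.fit(Xtr, ytr)
        p = model.predict_proba(Xte)[:, 1]
        aucs.append(roc_auc_score(yte, p))
    aucs = np.array(aucs)
    return {"aucs": aucs, "auc_mean": float(aucs.mean()),
            "auc_min": float(aucs.min()), "auc_max": float(aucs.max())}
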