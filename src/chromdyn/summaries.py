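"""Headline summary statistics reported by the pipeline's summary stage.

These small routines turn stage outputs into the counts and percentages
the run report prints: total DAR counts by class, the responsive and
repressed fractions of super-enhancers, the significant fraction of
cis-regulatory units, and the intrachromosomal fraction of Hi-C di-tags.
"""

from __future__ import annotations

__all__ = [
    "percentage",
    "dar_class_summary",
    "se_response_summary",
    "cru_significance_summary",
    "intra_chromosomal_summary",
]


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round(100.0 * numerator / denominator, ndigits)


def dar_class_summary(n_gain: int, n_loss: int) -> dict:
    """Total DARs and the per-class share of all differential calls."""
    total = n_gain + n_loss
    return {
        "n_gain": n_gain,
        "n_loss": n_loss,
        "n_total": total,
        "gain_pct": percentage(n_gain, total) if total else 0.0,
        "loss_pct": percentage(n_loss, total) if total else 0.0,
    }


def se_response_summary(n_induced: int, n_repressed: int, n_total: int) -> dict:
    """Responsive fraction of all SEs and repressed fraction of responsive."""
    n_responsive = n_induced + n_repressed
    return {
        "n_induced": n_induced,
        "n_repressed": n_repressed,
        "n_responsive": n_responsive,
        "n_total": n_total,
        "responsive_pct": percentage(n_responsive, n_total, 0) if n_total else 0.0,
        "repressed_of_responsive_pct": (
            percentage(n_repressed, n_responsive, 0) if n_responsive else 0.0
        ),
    }


def cru_significance_summary(n_significant: int, n_tested: int) -> dict:
    """Fraction of cis-regulatory units with significant correlation."""
    return {
        "n_significant": n_significant,
        "n_tested": n_tested,
        "significant_pct": percentage(n_significant, n_tested) if n_tested else 0.0,
    }


def intra_chromosomal_summary(n_intra: int, n_total: int) -> dict:
    """Intrachromosomal fraction of valid di-tags / interactions."""
    return {
        "n_intra": n_intra,
        "n_total": n_total,
        "intra_pct": percentage(n_intra, n_total) if n_total else 0.0,
    }
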