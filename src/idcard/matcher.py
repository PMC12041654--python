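"""Matching samples against identity cards and the matching-credibility (MC)
statistic.

MC is a pure tolerance-count statistic:

    MC = 100% × (number of matched ion pairs) / (number of card ions)

where the numerator counts (card ion, sample ion) pairs within the tolerance
window.  Because one card ion can match several sample ions (e.g. an [M+H]+
and an [M+2H]+ feature both falling inside the Δm/z window), MC can exceed
100%; such multi-matches are flagged in the result rather than suppressed.
An alternative numerator that counts each card ion at most once is available
for sensitivity analysis (``numerator_mode="unique"``), but the pair count is
the default and the definition used throughout.
"""

from __future__ import annotations

import warnings

from . import _join
from .errors import EmptyCardError, PreprocessingMismatchWarning
from .feature_model import FeatureTable, IdentityCard, MatchResult, ToleranceSpec

__all__ = ["count_matched_pairs", "matching_credibility", "match_profile"]


def count_matched_pairs(
    card: IdentityCard,
    sample: FeatureTable,
    tol: ToleranceSpec,
) -> tuple[int, list[tuple[int, int]]]:
    """Count all (card ion, sample ion) pairs within tolerance.

    Each card ion contributes the number of sample ions it matches; the pair
    detail lists every (card index, sample index) pair.  An empty sample
    yields zero pairs; an empty card is an error.
    """
    if card.size == 0:
        raise EmptyCardError(f"card {card.label!r} has no ions")
    _check_fingerprint(card, sample)
    if sample.n_ions == 0:
        return 0, []
    rt, mz, _ = card.arrays()
    idx = _join.SortedIndex(sample.rt, sample.mz)
    detail = _join.pair_indices(rt, mz, idx, tol.delta_rt, tol.delta_mz)
    return len(detail), detail


def matching_credibility(matched_pairs: int, card_size: int) -> float:
    """MC percentage: 100 × matched_pairs / card_size.

    Values above 100 are legal (multi-match); report to two decimals via
    ``round(mc, 2)`` or :attr:`MatchResult.mc_display`.
    """
    if card_size < 1:
        raise ValueError("card_size must be >= 1")
    if matched_pairs < 0:
        raise ValueError("matched_pairs must be nonnegative")
    return 100.0 * matched_pairs / card_size


def match_profile(
    sample: FeatureTable,
    cards: dict[str, IdentityCard],
    tol: ToleranceSpec,
    numerator_mode: str = "pairs",
) -> list[MatchResult]:
    """Match one sample against every card; results sorted by MC descending.

    Ties in MC are broken by card label so the ordering is deterministic
    regardless of dict order or evaluation order.  ``numerator_mode="unique"``
    counts each card ion at most once (sensitivity-analysis variant).
    """
    if not cards:
        raise ValueError("match_profile needs at least one card")
    if numerator_mode not in ("pairs", "unique"):
        raise ValueError(f"unknown numerator_mode {numerator_mode!r}")
    results = []
    for label in sorted(cards):
        card = cards[label]
        pairs, detail = count_matched_pairs(card, sample, tol)
        if numerator_mode == "unique":
            pairs = len({c for c, _ in detail})
        results.append(
            MatchResult(
                card_label=card.label,
                matched_pairs=pairs,
                card_size=card.size,
                pair_detail=detail,
            )
        )
    results.sort(key=lambda r: (-r.mc, r.card_label))
    return results


def _check_fingerprint(card: IdentityCard, sample: FeatureTable) -> None:
    """Warn when a sample looks unpreprocessed relative to the card's build.

    Cards record the Rt window used at build time; a sample carrying ions
    outside that window was evidently not preprocessed the same way.
    """
    fp = card.metadata.get("preprocessing")
    if not fp or sample.n_ions == 0:
        return
    window = fp.get("rt_window")
    if window and (sample.rt.min() < window[0] or sample.rt.max() > window[1]):
        warnings.warn(
            f"sample {sample.sample_id!r} has ions outside the card's build Rt window "
            f"{window}; preprocess it with the same settings before matching",
            PreprocessingMismatchWarning,
            stacklevel=3,
        )
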