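"""End-to-end decision procedures: origin traceability and adulteration
screening.

*Traceability* matches a sample against the identity cards of all candidate
origins and assigns the argmax-MC origin; ties are reported as ambiguous
rather than silently broken, and an all-zero profile is "unclassifiable".

*Adulteration screening* matches a sample against a two-class pair of cards
(authentic material vs adulterant material, built with the stricter
shared-vs-raw screening) and flags adulteration when the MC against the
adulterant card strictly exceeds a threshold (default 50%).  Both MCs are
always reported, since the authentic-card MC falling is itself informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .card_builder import build_cards
from .errors import ConfigurationError
from .feature_model import FeatureTable, IdentityCard, MatchResult, ToleranceSpec
from .matcher import match_profile

__all__ = [
    "TraceDecision",
    "AdulterationDecision",
    "trace_origin",
    "detect_adulteration",
    "mixture_series_experiment",
]


@dataclass
class TraceDecision:
    """Outcome of origin traceability for one sample.

    ``status`` is ``assigned`` (unique argmax), ``ambiguous`` (tied maxima,
    listed in ``tied_labels``) or ``unclassifiable`` (all MCs zero).
    ``margin`` is best MC / runner-up MC (inf when the runner-up is 0).
    """

    sample_id: str
    assigned_origin: str | None
    status: str
    mc_table: dict[str, float]
    margin: float
    tied_labels: list[str] = field(default_factory=list)
    results: list[MatchResult] = field(default_factory=list)


@dataclass
class AdulterationDecision:
    """Outcome of adulteration screening for one sample."""

    sample_id: str
    mc_vs_adulterant_card: float
    mc_vs_authentic_card: float
    threshold: float
    detected: bool


def trace_origin(
    sample: FeatureTable,
    origin_cards: dict[str, IdentityCard],
    tol: ToleranceSpec,
) -> TraceDecision:
    """Assign a sample to the origin whose card it matches best."""
    if len(origin_cards) < 2:
        raise ConfigurationError("traceability needs at least 2 origin cards")
    results = match_profile(sample, origin_cards, tol)
    mc_table = {r.card_label: r.mc for r in results}
    best = results[0]
    if best.mc == 0.0:
        return TraceDecision(sample.sample_id, None, "unclassifiable", mc_table, 1.0,
                             results=results)
    tied = [r.card_label for r in results if r.mc == best.mc]
    runner_up = max((r.mc for r in results if r.card_label != best.card_label), default=0.0)
    margin = float("inf") if runner_up == 0.0 else best.mc / runner_up
    if len(tied) > 1:
        return TraceDecision(sample.sample_id, None, "ambiguous", mc_table, 1.0,
                             tied_labels=tied, results=results)
    return TraceDecision(sample.sample_id, best.card_label, "assigned", mc_table,
                         margin, results=results)


def detect_adulteration(
    sample: FeatureTable,
    adulterant_card: IdentityCard,
    authentic_card: IdentityCard,
    tol: ToleranceSpec,
    threshold: float = 50.0,
) -> AdulterationDecision:
    """Flag adulteration when MC vs the adulterant card strictly exceeds
    ``threshold`` (percent).  Both directions are always reported."""
    profile = match_profile(
        sample,
        {adulterant_card.label: adulterant_card, authentic_card.label: authentic_card},
        tol,
    )
    mc = {r.card_label: r.mc for r in profile}
    mc_adu = mc[adulterant_card.label]
    mc_aut = mc[authentic_card.label]
    return AdulterationDecision(
        sample_id=sample.sample_id,
        mc_vs_adulterant_card=mc_adu,
        mc_vs_authentic_card=mc_aut,
        threshold=threshold,
        detected=mc_adu > threshold,
    )


def mixture_series_experiment(
    authentic_batches: list[FeatureTable],
    adulterant_batches: list[FeatureTable],
    proportions: list[float],
    tol: ToleranceSpec | None = None,
    n: int = 100,
    seed: int = 0,
    threshold: float = 50.0,
    detection_floor: float = 5000.0,
    rt_jitter_sd: float = 0.01,
    mz_jitter_sd: float = 0.01,
    blanks: list[FeatureTable] | None = None,
) -> pd.DataFrame:
    """Two-class mixture study: build cards, synthesize mixtures, report MCs.

    Builds the adulterant/authentic card pair with the shared-vs-raw strategy,
    then for each mass proportion p synthesizes a mixture of the first
    authentic and first adulterant batch (authentic intensities scaled by
    1 − p, adulterant by p, fresh coordinate jitter, ions below the detection
    floor dropped) and matches it against both cards.  Reproducible under a
    fixed seed.
    """
    from .synthetic_data import mix_feature_tables  # local import: soft dependency

    if any(p < 0 or p > 1 for p in proportions):
        raise ConfigurationError("proportions must lie in [0, 1]")
    tol = tol or ToleranceSpec()
    authentic_label = authentic_batches[0].origin or "authentic"
    adulterant_label = adulterant_batches[0].origin or "adulterant"
    if authentic_label == adulterant_label:
        raise ConfigurationError("authentic and adulterant batches must carry distinct labels")
    cards = build_cards(
        list(authentic_batches) + list(adulterant_batches),
        blanks=blanks,
        tol=tol,
        n=n,
        strategy="shared_vs_raw",
    )
    rng = np.random.default_rng(seed)
    rows = []
    for p in proportions:
        mixture = mix_feature_tables(
            authentic_batches[0],
            adulterant_batches[0],
            p,
            detection_floor=detection_floor,
            rt_jitter_sd=rt_jitter_sd,
            mz_jitter_sd=mz_jitter_sd,
            rng=rng,
        )
        decision = detect_adulteration(
            mixture, cards[adulterant_label], cards[authentic_label], tol, threshold
        )
        rows.append(
            {
                "proportion": p,
                "mc_vs_adulterant": decision.mc_vs_adulterant_card,
                "mc_vs_authentic": decision.mc_vs_authentic_card,
                "detected": decision.detected,
            }
        )
    return pd.DataFrame(rows)
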