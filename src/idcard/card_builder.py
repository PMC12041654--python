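"""Identity-card construction: shared-ion extraction, deduplication,
unique-ion screening and top-N selection.

The card-building pipeline per origin/class is

1. *Shared-ion extraction* — keep the ions of a designated anchor batch (the
   first batch in input order) that have a tolerance match in every other
   batch of the same origin.  Batch-to-batch instrument drift is what the
   tolerance window absorbs.
2. *Deduplication* — a greedy pass in intensity-descending order removes ions
   that match an already-kept ion, so the shared set is pairwise
   non-matching (adduct/isotope satellites collapse to the strongest one).
3. *Unique-ion screening* — remove every shared ion that matches the contrast
   material.  Two strategies exist: against the other origins' shared sets
   (traceability mode) or against the raw preprocessed tables of the
   contrast class (adulteration mode, stricter).
4. *Top-N selection* — retain the N most intense survivors (default 100) as
   the identity card.

Rebuilding after adding batches is a full re-run of this pipeline; cards are
never mutated incrementally, so the result cannot depend on update history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _join
from .errors import ConfigurationError, EmptyCardError, IdCardWarning
from .feature_model import FeatureTable, IdentityCard, IonFeature, ToleranceSpec
from .preprocessing import DEFAULT_RT_WINDOW, preprocess

__all__ = [
    "SharedIonSet",
    "extract_shared_ions",
    "dedup_similar_ions",
    "screen_unique_vs_shared",
    "screen_unique_vs_raw",
    "select_top_n",
    "build_cards",
]


@dataclass
class SharedIonSet:
    """Ions shared (within tolerance) by all batches of one origin.

    ``batch_support`` holds, per ion, every (sample_id, matching ion) pair
    found across the contributing batches, anchor included.
    """

    label: str
    ions: list[IonFeature]
    batch_support: list[list[tuple[str, IonFeature]]] = field(default_factory=list)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arr = np.array(self.ions, dtype=float).reshape(-1, 3)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def __len__(self) -> int:
        return len(self.ions)

    def subset(self, keep: np.ndarray) -> "SharedIonSet":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return SharedIonSet(
            self.label,
            [self.ions[i] for i in idx],
            [self.batch_support[i] for i in idx] if self.batch_support else [],
        )


def extract_shared_ions(
    batches: list[FeatureTable],
    tol: ToleranceSpec,
    quorum: int | None = None,
) -> SharedIonSet:
    """Extract the ions common to the batches of one origin.

    The first batch is the anchor: an anchor ion is kept when every other
    batch (or at least ``quorum`` batches in total, anchor included, when a
    quorum is given) contains >= 1 matching ion.  The representative keeps
    the anchor's coordinates; its intensity is the arithmetic mean of the
    anchor intensity and, per matching batch, the intensity of the closest
    match (smallest |Δm/z|, ties by |ΔRt|).
    """
    if len(batches) < 2:
        raise ConfigurationError("shared-ion extraction needs at least 2 batches")
    n_required = len(batches) if quorum is None else int(quorum)
    if not 2 <= n_required <= len(batches):
        raise ConfigurationError(
            f"quorum must be between 2 and the number of batches, got {quorum}"
        )
    anchor = batches[0]
    others = batches[1:]
    n = anchor.n_ions
    support_count = np.ones(n, dtype=int)  # the anchor supports its own ions
    # one intensity column per batch so the mean can be summed in a fixed
    # (value-sorted) order, independent of how the batches were listed
    contrib = np.full((len(batches), n), np.nan)
    contrib[0] = anchor.intensity
    all_matches: list[list[tuple[str, IonFeature]]] = [
        [(anchor.sample_id, ion)] for ion in anchor.ions
    ]
    for j, batch in enumerate(others, start=1):
        idx = _join.SortedIndex(batch.rt, batch.mz)
        closest = _join.closest_indices(anchor.rt, anchor.mz, idx, tol.delta_rt, tol.delta_mz)
        hit = closest >= 0
        support_count += hit
        contrib[j, hit] = batch.intensity[closest[hit]]
        for a_i, b_i in _join.pair_indices(anchor.rt, anchor.mz, idx, tol.delta_rt, tol.delta_mz):
            all_matches[a_i].append(
                (batch.sample_id, IonFeature(batch.rt[b_i], batch.mz[b_i], batch.intensity[b_i]))
            )
    keep = support_count >= n_required
    label = anchor.origin or anchor.sample_id
    if not keep.any():
        warnings.warn(
            f"no shared ions for {label!r} under ΔRt<={tol.delta_rt}, Δm/z<={tol.delta_mz}",
            IdCardWarning,
            stacklevel=2,
        )
        return SharedIonSet(label, [], [])
    # NaN-aware mean over contributions sorted by value (NaNs sort last),
    # so the result is bit-identical under any non-anchor batch ordering
    ordered = np.sort(contrib, axis=0)
    mean_intensity = np.nansum(ordered, axis=0) / np.sum(~np.isnan(contrib), axis=0)
    kept = np.flatnonzero(keep)
    ions = [
        IonFeature(anchor.rt[i], anchor.mz[i], float(mean_intensity[i])) for i in kept
    ]
    return SharedIonSet(label, ions, [all_matches[i] for i in kept])


def dedup_similar_ions(shared: SharedIonSet, tol: ToleranceSpec) -> SharedIonSet:
    """Collapse repetitively similar ions.

    Greedy pass in intensity-descending order (ties by m/z then rt ascending):
    an ion is dropped iff it matches an already-kept ion, so the strongest
    representative of each tolerance cluster survives and the output is
    pairwise non-matching.
    """
    if len(shared) == 0:
        return shared
    rt, mz, inten = shared.arrays()
    order = np.lexsort((rt, mz, -inten))
    kept_rt: list[float] = []
    kept_mz: list[float] = []
    kept_idx: list[int] = []
    for i in order:
        if kept_rt:
            krt = np.asarray(kept_rt)
            kmz = np.asarray(kept_mz)
            clash = (np.abs(krt - rt[i]) <= tol.delta_rt + _join.EPS) & (
                np.abs(kmz - mz[i]) <= tol.delta_mz + _join.EPS
            )
            if clash.any():
                continue
        kept_rt.append(rt[i])
        kept_mz.append(mz[i])
        kept_idx.append(int(i))
    return shared.subset(np.asarray(sorted(kept_idx)))


def screen_unique_vs_shared(
    own: SharedIonSet,
    others: list[SharedIonSet],
    tol: ToleranceSpec,
) -> SharedIonSet:
    """Remove own ions matching any ion of any other origin's shared set."""
    if len(own) == 0 or not others:
        return own
    rt, mz, _ = own.arrays()
    remove = np.zeros(len(own), dtype=bool)
    for other in others:
        if len(other) == 0:
            continue
        ort, omz, _ = other.arrays()
        idx = _join.SortedIndex(ort, omz)
        remove |= _join.match_mask(rt, mz, idx, tol.delta_rt, tol.delta_mz)
    return own.subset(~remove)


def screen_unique_vs_raw(
    own: SharedIonSet,
    contrast_tables: list[FeatureTable],
    tol: ToleranceSpec,
) -> SharedIonSet:
    """Remove own ions matching any ion of any contrast raw table.

    Stricter than :func:`screen_unique_vs_shared`: the contrast side is the
    full preprocessed data, not just its shared subset, so ions that appear
    sporadically in the contrast material are also eliminated.
    """
    if len(own) == 0 or not contrast_tables:
        return own
    rt, mz, _ = own.arrays()
    remove = np.zeros(len(own), dtype=bool)
    for tab in contrast_tables:
        idx = _join.SortedIndex(tab.rt, tab.mz)
        remove |= _join.match_mask(rt, mz, idx, tol.delta_rt, tol.delta_mz)
    return own.subset(~remove)


def select_top_n(
    shared: SharedIonSet,
    n: int = 100,
    tolerance: ToleranceSpec | None = None,
    strategy: str = "shared_vs_shared",
    source_sample_ids: list[str] | None = None,
    metadata: dict | None = None,
) -> IdentityCard:
    """Retain the N most intense ions as the identity card.

    Ordering is intensity descending with deterministic tie-breaks (m/z then
    rt ascending).  A card smaller than ``n`` is legal (MC denominators use
    the actual size) and warned about; an empty ion set is an error.
    """
    if n < 1:
        raise ConfigurationError("top_n must be >= 1")
    if len(shared) == 0:
        raise EmptyCardError(f"no ions left to build a card for {shared.label!r}")
    tolerance = tolerance or ToleranceSpec()
    rt, mz, inten = shared.arrays()
    order = np.lexsort((rt, mz, -inten))[:n]
    if len(order) < n:
        warnings.warn(
            f"card {shared.label!r} has only {len(order)} ions (requested top {n}); "
            "MC denominators will use the actual size",
            IdCardWarning,
            stacklevel=2,
        )
    ions = [IonFeature(rt[i], mz[i], inten[i]) for i in order]
    return IdentityCard(
        label=shared.label,
        ions=ions,
        tolerance=tolerance,
        top_n=n,
        source_sample_ids=source_sample_ids or [],
        strategy=strategy,
        metadata=metadata or {},
    )


def build_cards(
    corpus: list[FeatureTable],
    blanks: list[FeatureTable] | None,
    tol: ToleranceSpec | None = None,
    n: int = 100,
    strategy: str = "shared_vs_shared",
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
    blank_first: bool = True,
    quorum: int | None = None,
) -> dict[str, IdentityCard]:
    """Full card-building pipeline over a labelled corpus.

    Groups the corpus by origin label, preprocesses every table, extracts and
    deduplicates each origin's shared ions, screens them for uniqueness per
    ``strategy`` and selects the top N.  Adding batches means re-running this
    function on the extended corpus ("dynamic update" = full rebuild).
    """
    if strategy not in ("shared_vs_shared", "shared_vs_raw"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    tol = tol or ToleranceSpec()
    groups: dict[str, list[FeatureTable]] = {}
    for table in corpus:
        if table.role == "blank":
            continue
        if not table.origin:
            raise ConfigurationError(f"sample {table.sample_id!r} has no origin label")
        groups.setdefault(table.origin, []).append(table)
    if len(groups) < 2:
        raise ConfigurationError("card building needs at least 2 origins/classes")
    for origin, tables in groups.items():
        if len(tables) < 2:
            raise ConfigurationError(
                f"origin {origin!r} has {len(tables)} batch(es); at least 2 are required"
            )
    pre = {
        origin: [preprocess(t, blanks, tol, rt_window, blank_first) for t in tables]
        for origin, tables in groups.items()
    }
    shared = {
        origin: dedup_similar_ions(extract_shared_ions(tables, tol, quorum), tol)
        for origin, tables in pre.items()
    }
    fingerprint = {
        "rt_window": list(rt_window),
        "delta_rt": tol.delta_rt,
        "delta_mz": tol.delta_mz,
        "blank_deducted": bool(blanks),
        "blank_first": blank_first,
        "quorum": quorum,
    }
    cards: dict[str, IdentityCard] = {}
    for origin in groups:
        if strategy == "shared_vs_shared":
            unique = screen_unique_vs_shared(
                shared[origin], [shared[o] for o in groups if o != origin], tol
            )
        else:
            contrast = [t for o in groups if o != origin for t in pre[o]]
            unique = screen_unique_vs_raw(shared[origin], contrast, tol)
        cards[origin] = select_top_n(
            unique,
            n=n,
            tolerance=tol,
            strategy=strategy,
            source_sample_ids=[t.sample_id for t in groups[origin]],
            metadata={"preprocessing": fingerprint},
        )
    return cards
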