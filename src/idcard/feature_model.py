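"""Domain types and file I/O for LC-MS feature tables and identity cards.

A *feature table* is the quantized export of one sample's LC-MS run: a list of
[Rt − m/z − I] units (retention time in minutes, mass-to-charge ratio in
daltons, ion intensity in arbitrary units) produced by peak-picking software.
An *identity card* is the distilled fingerprint of one origin or class: its
top-N intensity-ranked ions that are shared across all batches of that origin
and unique relative to the contrast origins/classes.

Feature tables are plain CSV (default columns ``rt_min``, ``mz``,
``intensity``; the mapping is configurable because peak-picking exports vary).
Identity cards are JSON documents carrying the ion list plus full build
provenance (tolerance, strategy, source samples), which makes cards auditable
and lets them be rebuilt as new batches arrive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _join
from .errors import CardSchemaError, FeatureTableFormatError

__all__ = [
    "IonFeature",
    "ToleranceSpec",
    "FeatureTable",
    "IdentityCard",
    "MatchResult",
    "DEFAULT_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_card",
    "write_card",
]

#: Default CSV column names for feature tables.
DEFAULT_COLUMNS: Mapping[str, str] = {"rt": "rt_min", "mz": "mz", "intensity": "intensity"}

ROLES = ("sample", "blank", "reference")


class IonFeature(NamedTuple):
    """One detected ion: retention time (min), m/z (Da), intensity (a.u.).

    Intensity is unbounded above — no cap is applied anywhere in the package.
    """

    rt: float
    mz: float
    intensity: float


@dataclass(frozen=True)
class ToleranceSpec:
    """Matching window used by every ion comparison.

    Two ions match when |ΔRt| <= ``delta_rt`` AND |Δm/z| <= ``delta_mz``,
    both comparisons inclusive.  Defaults are the instrument-drift bounds
    observed between batches: 0.05 min and 0.05 Da.
    """

    delta_rt: float = 0.05
    delta_mz: float = 0.05

    def __post_init__(self) -> None:
        if self.delta_rt < 0 or self.delta_mz < 0:
            raise ValueError("tolerances must be nonnegative")


class FeatureTable:
    """One sample's ion list plus sample/batch metadata.

    Ions are stored as parallel float arrays; construction validates the
    domain invariants (rt > 0, mz > 0, intensity >= 0) but never merges or
    reorders ions — near-duplicate coordinates (adducts, isotopes) are kept
    as exported.
    """

    def __init__(
        self,
        sample_id: str,
        rt: np.ndarray,
        mz: np.ndarray,
        intensity: np.ndarray,
        origin: str | None = None,
        role: str = "sample",
    ) -> None:
        if not sample_id:
            raise ValueError("sample_id must be a nonempty string")
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        rt = np.atleast_1d(np.asarray(rt, dtype=float))
        mz = np.atleast_1d(np.asarray(mz, dtype=float))
        intensity = np.atleast_1d(np.asarray(intensity, dtype=float))
        if not (rt.shape == mz.shape == intensity.shape) or rt.ndim != 1:
            raise ValueError("rt, mz and intensity must be 1-D arrays of equal length")
        bad = ~(np.isfinite(rt) & np.isfinite(mz) & np.isfinite(intensity))
        bad |= (rt <= 0) | (mz <= 0) | (intensity < 0)
        if bad.any():
            rows = np.flatnonzero(bad)[:10].tolist()
            raise ValueError(
                f"invalid ion values (need rt > 0, mz > 0, intensity >= 0) at rows {rows}"
            )
        self.sample_id = sample_id
        self.origin = origin
        self.role = role
        self.rt = rt
        self.mz = mz
        self.intensity = intensity

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_ions(
        cls,
        sample_id: str,
        ions: Iterable[tuple[float, float, float]],
        origin: str | None = None,
        role: str = "sample",
    ) -> "FeatureTable":
        arr = np.array([(i[0], i[1], i[2]) for i in ions], dtype=float).reshape(-1, 3)
        return cls(sample_id, arr[:, 0], arr[:, 1], arr[:, 2], origin=origin, role=role)

    def replace_ions(
        self, rt: np.ndarray, mz: np.ndarray, intensity: np.ndarray
    ) -> "FeatureTable":
        """New table with the same metadata and a different ion list."""
        return FeatureTable(self.sample_id, rt, mz, intensity, origin=self.origin, role=self.role)

    # -- views -------------------------------------------------------------

    @property
    def n_ions(self) -> int:
        return len(self.rt)

    @property
    def ions(self) -> list[IonFeature]:
        return [IonFeature(*t) for t in zip(self.rt, self.mz, self.intensity)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rt_min": self.rt, "mz": self.mz, "intensity": self.intensity}
        )

    def __len__(self) -> int:
        return self.n_ions

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"FeatureTable(sample_id={self.sample_id!r}, origin={self.origin!r}, "
            f"role={self.role!r}, n_ions={self.n_ions})"
        )


def _card_sort_key(rt: np.ndarray, mz: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Intensity descending, ties by m/z ascending then rt ascending."""
    return np.lexsort((rt, mz, -intensity))


@dataclass
class IdentityCard:
    """An origin's or class's digital identity card.

    ``ions`` are intensity-descending (ties by m/z then rt ascending, so the
    ordering is deterministic across runs); no two card ions match each other
    under ``tolerance``; and the card never exceeds ``top_n`` ions.  When
    fewer than ``top_n`` unique shared ions exist, the card is smaller and
    matching-credibility denominators use the actual size.
    """

    label: str
    ions: list[IonFeature]
    tolerance: ToleranceSpec
    top_n: int
    source_sample_ids: list[str] = field(default_factory=list)
    strategy: str = "shared_vs_shared"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ions = [IonFeature(*i) for i in self.ions]
        self.validate()

    @property
    def size(self) -> int:
        return len(self.ions)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arr = np.array(self.ions, dtype=float).reshape(-1, 3)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def validate(self) -> None:
        if self.strategy not in ("shared_vs_shared", "shared_vs_raw"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if len(self.ions) > self.top_n:
            raise ValueError("card holds more ions than top_n")
        rt, mz, inten = self.arrays()
        order = _card_sort_key(rt, mz, inten)
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("card ions must be sorted by intensity descending "
                             "(ties by m/z then rt ascending)")
        idx = _join.SortedIndex(rt, mz)
        counts = _join.count_pairs(rt, mz, idx, self.tolerance.delta_rt, self.tolerance.delta_mz)
        if len(counts) and (counts > 1).any():  # every ion matches itself once
            raise ValueError("card ions must be pairwise non-matching under tolerance")


@dataclass
class MatchResult:
    """Outcome of matching one sample against one identity card.

    ``matched_pairs`` counts (card ion, sample ion) pairs within tolerance;
    a single card ion matching several sample ions contributes each pair, so
    the matching credibility (MC) can exceed 100%.
    """

    card_label: str
    matched_pairs: int
    card_size: int
    pair_detail: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.card_size < 1:
            raise ValueError("card_size must be >= 1")
        if self.matched_pairs < 0:
            raise ValueError("matched_pairs must be nonnegative")

    @property
    def mc(self) -> float:
        """Matching credibility, percent."""
        return 100.0 * self.matched_pairs / self.card_size

    @property
    def mc_display(self) -> str:
        """MC formatted to two decimals, as reported."""
        return f"{self.mc:.2f}"

    @property
    def multi_match(self) -> bool:
        """True when some card ion matched more than one sample ion."""
        if not self.pair_detail:
            return False
        card_idx = [c for c, _ in self.pair_detail]
        return len(card_idx) != len(set(card_idx))


# ---------------------------------------------------------------------------
# Feature-table CSV I/O


def read_feature_table(
    path: str | Path,
    sample_id: str,
    origin: str | None = None,
    role: str = "sample",
    columns: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read one sample's feature table from CSV.

    ``columns`` maps the logical names ``rt``/``mz``/``intensity`` to the
    CSV header names (defaults: ``rt_min``, ``mz``, ``intensity``).  Rows
    with non-numeric or nonpositive rt/mz raise a format error naming the
    offending rows; ions are returned in file order, unmerged.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    try:
        # round_trip parsing keeps repr-precision writes bit-exact on re-read
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FeatureTableFormatError(f"{path}: file is empty") from None
    if df.empty:
        raise FeatureTableFormatError(f"{path}: table has no ion rows")
    missing = [name for name in cols.values() if name not in df.columns]
    if missing:
        raise FeatureTableFormatError(f"{path}: missing column(s) {missing}")
    data = {}
    for logical, name in cols.items():
        vals = pd.to_numeric(df[name], errors="coerce")
        data[logical] = vals.to_numpy(dtype=float)
    bad = ~np.isfinite(data["rt"]) | ~np.isfinite(data["mz"]) | ~np.isfinite(data["intensity"])
    bad |= (data["rt"] <= 0) | (data["mz"] <= 0) | (data["intensity"] < 0)
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based file rows incl. header
        raise FeatureTableFormatError(
            f"{path}: invalid rt/mz/intensity values at file row(s) {rows[:10]}"
        )
    return FeatureTable(
        sample_id, data["rt"], data["mz"], data["intensity"], origin=origin, role=role
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, columns: Mapping[str, str] | None = None
) -> None:
    """Write a feature table to CSV with full float precision (round-trip exact)."""
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{cols['rt']},{cols['mz']},{cols['intensity']}\n")
        for rt, mz, inten in zip(table.rt, table.mz, table.intensity):
            fh.write(f"{float(rt)!r},{float(mz)!r},{float(inten)!r}\n")


# ---------------------------------------------------------------------------
# Identity-card JSON I/O

_CARD_FORMAT = "idcard.identity_card"
_CARD_VERSION = 1


def write_card(card: IdentityCard, path: str | Path) -> None:
    """Persist an identity card with its full build provenance."""
    doc = {
        "format": _CARD_FORMAT,
        "version": _CARD_VERSION,
        "label": card.label,
        "strategy": card.strategy,
        "top_n": card.top_n,
        "tolerance": {"delta_rt": card.tolerance.delta_rt, "delta_mz": card.tolerance.delta_mz},
        "source_sample_ids": list(card.source_sample_ids),
        "metadata": card.metadata,
        "ions": [[i.rt, i.mz, i.intensity] for i in card.ions],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_card(path: str | Path) -> IdentityCard:
    """Load an identity card, validating schema and invariants."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise CardSchemaError(f"{path}: not a readable card document ({exc})") from None
    if not isinstance(doc, dict) or doc.get("format") != _CARD_FORMAT:
        raise CardSchemaError(f"{path}: not an identity-card document")
    for key in ("label", "strategy", "top_n", "tolerance", "ions"):
        if key not in doc:
            raise CardSchemaError(f"{path}: card document missing {key!r} block")
    tol = doc["tolerance"]
    if not isinstance(tol, dict) or "delta_rt" not in tol or "delta_mz" not in tol:
        raise CardSchemaError(f"{path}: malformed tolerance block")
    try:
        return IdentityCard(
            label=doc["label"],
            ions=[IonFeature(*row) for row in doc["ions"]],
            tolerance=ToleranceSpec(float(tol["delta_rt"]), float(tol["delta_mz"])),
            top_n=int(doc["top_n"]),
            source_sample_ids=list(doc.get("source_sample_ids", [])),
            strategy=doc["strategy"],
            metadata=dict(doc.get("metadata", {})),
        )
    except (TypeError, ValueError) as exc:
        raise CardSchemaError(f"{path}: invalid card content ({exc})") from None
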