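"""Sample preprocessing: retention-time windowing and blank deduction.

Both operations run on every sample before cards are built or matched.
The Rt window discards the injection front and the column-wash tail (the
default window, 1.00–26.00 min, is the usable part of the gradient).  Blank
deduction deletes every sample ion that matches an ion of any solvent-blank
run within tolerance, removing solvent and matrix artifacts that would
otherwise inflate the shared-ion sets of every origin alike.
"""

from __future__ import annotations

import logging

import numpy as np

from . import _join
from .errors import ConfigurationError
from .feature_model import FeatureTable, IonFeature, ToleranceSpec

__all__ = ["ions_match", "filter_rt_window", "deduct_blank", "preprocess"]

logger = logging.getLogger(__name__)

#: Default usable retention-time window, minutes.
DEFAULT_RT_WINDOW = (1.00, 26.00)


def ions_match(a: IonFeature, b: IonFeature, tol: ToleranceSpec) -> bool:
    """True iff |ΔRt| <= delta_rt and |Δm/z| <= delta_mz (inclusive).

    Intensity plays no role in matching; the comparison is symmetric.  A
    guard of 1e-9 absorbs binary float-representation error so that values
    whose printed decimals differ by exactly the tolerance still match.
    """
    return (
        abs(a[0] - b[0]) <= tol.delta_rt + _join.EPS
        and abs(a[1] - b[1]) <= tol.delta_mz + _join.EPS
    )


def filter_rt_window(
    table: FeatureTable,
    rt_min: float = DEFAULT_RT_WINDOW[0],
    rt_max: float = DEFAULT_RT_WINDOW[1],
) -> FeatureTable:
    """Keep exactly the ions with rt_min <= rt <= rt_max (closed interval)."""
    if not rt_min < rt_max:
        raise ConfigurationError(f"rt window is empty: [{rt_min}, {rt_max}]")
    keep = (table.rt >= rt_min) & (table.rt <= rt_max)
    return table.replace_ions(table.rt[keep], table.mz[keep], table.intensity[keep])


def deduct_blank(
    table: FeatureTable,
    blanks: list[FeatureTable],
    tol: ToleranceSpec,
) -> FeatureTable:
    """Remove every sample ion matching any ion of any blank table.

    Multiple blanks are unioned: an ion is deleted if it matches at least one
    ion in at least one blank.  The input table is not modified; the removal
    count is logged.
    """
    if not blanks:
        raise ConfigurationError("deduct_blank requires at least one blank table")
    remove = np.zeros(table.n_ions, dtype=bool)
    for blank in blanks:
        idx = _join.SortedIndex(blank.rt, blank.mz)
        remove |= _join.match_mask(table.rt, table.mz, idx, tol.delta_rt, tol.delta_mz)
    n_removed = int(remove.sum())
    if n_removed:
        logger.info(
            "blank deduction removed %d of %d ions from %s",
            n_removed, table.n_ions, table.sample_id,
        )
    keep = ~remove
    return table.replace_ions(table.rt[keep], table.mz[keep], table.intensity[keep])


def preprocess(
    table: FeatureTable,
    blanks: list[FeatureTable] | None,
    tol: ToleranceSpec,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
    blank_first: bool = True,
) -> FeatureTable:
    """Full preprocessing: blank deduction and Rt windowing.

    ``blank_first`` picks the order of the two steps (blank deduction first
    by default); blanks themselves are Rt-windowed before use so the order
    cannot reintroduce out-of-window contaminants.
    """
    lo, hi = rt_window
    if blanks:
        blanks = [filter_rt_window(b, lo, hi) for b in blanks]
    if blank_first and blanks:
        table = deduct_blank(table, blanks, tol)
    table = filter_rt_window(table, lo, hi)
    if not blank_first and blanks:
        table = deduct_blank(table, blanks, tol)
    return table
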